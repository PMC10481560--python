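"""Plan evaluation and QA.

DVH engine with Dx/Vx/Dmax/Dmean readout, conformity and homogeneity
indices, clinical-goal reports (with the overlap-aware "flagged" status),
plan sums, 3%/2 mm gamma analysis, the VMAT modulation complexity score and
an exact two-sided Wilcoxon signed-rank test for paired cohort comparison.

Conventions
-----------
* Dx — the largest dose received by at least x % of the structure volume
  (linear interpolation between DVH bin edges).
* Vx — structure volume receiving at least x Gy, reported both as % of the
  structure and in cc.
* CI = (TV_PIV)² / (TV × PIV); HI = (D2 − D98) / D_prescription.
* Gamma — global normalisation to the reference maximum; a voxel passes
  when the generalised distance sqrt((Δd/ΔD)² + (Δr/DTA)²) reaches ≤ 1
  somewhere inside the search radius.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import norm, rankdata

from .grid import EmptyMaskError, ROIMask, StructureSet, VoxelGrid, _require_same_geometry
from .dose import ArcPlan

DEFAULT_BIN_WIDTH_GY = 0.05


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

@dataclass
class DVH:
    """Cumulative dose-volume curve of one ROI.

    ``cum_fraction[i]`` is the fraction of the ROI receiving at least
    ``bin_edges_gy[i]``; it starts at 1.0 for 0 Gy, is non-increasing and
    reaches 0 beyond the maximum dose.
    """

    roi: str
    bin_edges_gy: np.ndarray
    cum_fraction: np.ndarray
    total_cc: float

    def __post_init__(self) -> None:
        self.bin_edges_gy = np.asarray(self.bin_edges_gy, dtype=float)
        self.cum_fraction = np.asarray(self.cum_fraction, dtype=float)
        if self.bin_edges_gy.shape != self.cum_fraction.shape:
            raise ValueError("bin edges and fractions must align")
        if self.total_cc <= 0:
            raise ValueError("total volume must be positive")


def cumulative_dvh(dose: VoxelGrid, mask: ROIMask,
                   bin_width_gy: float = DEFAULT_BIN_WIDTH_GY) -> DVH:
    """Exact voxel-counting cumulative DVH of *mask* on *dose*."""
    _require_same_geometry(dose.geometry, mask.geometry, "cumulative_dvh")
    if mask.is_empty:
        raise EmptyMaskError(f"ROI '{mask.name}' is empty")
    vals = np.sort(dose.values[mask.mask].astype(float))
    n = vals.size
    top = float(vals[-1])
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    frac = 1.0 - np.searchsorted(vals, edges, side="left") / n
    return DVH(mask.name, edges, frac, mask.volume_cc())


def dose_at_volume(dvh: DVH, x_pct: float) -> float:
    """Dx in Gy: largest dose with cumulative fraction >= x/100."""
    if not 0 < x_pct <= 100:
        raise ValueError(f"x must lie in (0, 100], got {x_pct}")
    q = x_pct / 100.0
    frac, edges = dvh.cum_fraction, dvh.bin_edges_gy
    above = np.flatnonzero(frac >= q)
    i = int(above[-1])
    if i == len(edges) - 1 or frac[i] == q:
        return float(edges[i])
    # interpolate within the bin where the curve drops through q
    f0, f1 = frac[i], frac[i + 1]
    return float(edges[i] + (f0 - q) / (f0 - f1) * (edges[i + 1] - edges[i]))


def volume_at_dose(dvh: DVH, dose_gy: float) -> Tuple[float, float]:
    """Vx: (percent of ROI, cc) receiving at least *dose_gy*."""
    if dose_gy < 0:
        raise ValueError("dose must be >= 0")
    frac = float(np.interp(dose_gy, dvh.bin_edges_gy, dvh.cum_fraction,
                           left=1.0, right=0.0))
    return 100.0 * frac, frac * dvh.total_cc


def d_max(dose: VoxelGrid, mask: ROIMask) -> float:
    _require_same_geometry(dose.geometry, mask.geometry, "d_max")
    if mask.is_empty:
        raise EmptyMaskError(f"ROI '{mask.name}' is empty")
    return float(dose.values[mask.mask].max())


def d_mean(dose: VoxelGrid, mask: ROIMask) -> float:
    _require_same_geometry(dose.geometry, mask.geometry, "d_mean")
    if mask.is_empty:
        raise EmptyMaskError(f"ROI '{mask.name}' is empty")
    return float(dose.values[mask.mask].mean())


# ---------------------------------------------------------------------------
# Conformity / homogeneity / plan sums
# ---------------------------------------------------------------------------

def conformity_index(dose: VoxelGrid, target: ROIMask, prescription_gy: float) -> float:
    """CI = (TV_PIV)² / (TV × PIV); 1 iff the prescription isodose volume
    coincides with the target.  Returns 0 (with a warning) if nothing
    reaches prescription dose."""
    _require_same_geometry(dose.geometry, target.geometry, "conformity_index")
    if target.is_empty:
        raise EmptyMaskError("target is empty")
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    piv = dose.values >= prescription_gy
    n_piv = int(piv.sum())
    if n_piv == 0:
        warnings.warn("prescription isodose volume is empty; CI defined as 0")
        return 0.0
    n_tv = target.count
    n_cov = int((piv & target.mask).sum())
    return n_cov ** 2 / (n_tv * n_piv)


def homogeneity_index(dvh: DVH, prescription_gy: float) -> float:
    """HI = (D2 − D98) / D_prescription; 0 for a perfectly uniform dose."""
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    return (dose_at_volume(dvh, 2.0) - dose_at_volume(dvh, 98.0)) / prescription_gy


def plan_sum(dose_a: VoxelGrid, dose_b: VoxelGrid) -> VoxelGrid:
    """Voxelwise sum of two dose distributions on one grid."""
    _require_same_geometry(dose_a.geometry, dose_b.geometry, "plan_sum")
    return VoxelGrid(dose_a.geometry, dose_a.values + dose_b.values)


# ---------------------------------------------------------------------------
# Clinical goals
# ---------------------------------------------------------------------------

GOAL_METRICS = ("Dx", "Vx", "Dmax", "Dmean")
GOAL_UNITS = ("pct_rx", "gy", "pct_volume", "cc")
GOAL_SCOPES = ("initial", "boost", "plan_sum", "per_plan")
#: group aliases: a goal ROI that expands to several structures, judged on
#: the worst member
ROI_GROUPS = {"FemoralHeads": ("FemoralHead_L", "FemoralHead_R")}
#: goal ROI names resolved per plan scope
PTV_BY_SCOPE = {"initial": "PTV_initial", "boost": "PTV_boost"}


@dataclass(frozen=True)
class ClinicalGoal:
    """One clinical-goal row: ROI, metric, comparator and threshold.

    ``parameter`` is x in % for Dx and x in Gy for Vx (unused for
    Dmax/Dmean).  ``unit`` gives the threshold's unit; ``scope`` selects the
    dose distribution the goal is judged on (``per_plan`` = evaluated on the
    initial and the boost plan separately).
    """

    roi: str
    metric: str
    parameter: float
    comparator: str
    threshold: float
    unit: str
    scope: str = "plan_sum"

    def __post_init__(self) -> None:
        if self.metric not in GOAL_METRICS:
            raise ValueError(f"unknown goal metric '{self.metric}'")
        if self.unit not in GOAL_UNITS:
            raise ValueError(f"unknown goal unit '{self.unit}'")
        if self.comparator not in ("<", "<=", ">", ">="):
            raise ValueError(f"unknown comparator '{self.comparator}'")
        if self.scope not in GOAL_SCOPES:
            raise ValueError(f"unknown scope '{self.scope}'")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.metric in ("Dx", "Vx") and self.parameter is None:
            raise ValueError(f"{self.metric} goal needs a parameter")
        if self.metric == "Dx" and self.unit in ("pct_volume", "cc"):
            raise ValueError("Dx thresholds are doses, not volumes")
        if self.metric in ("Dmax", "Dmean") and self.unit in ("pct_volume", "cc"):
            raise ValueError(f"{self.metric} thresholds are doses, not volumes")
        if self.metric == "Vx" and self.unit in ("pct_rx", "gy"):
            raise ValueError("Vx thresholds are volumes, not doses")


@dataclass
class GoalResult:
    goal: ClinicalGoal
    scope: str
    roi: str
    achieved: float
    achieved_unit: str
    threshold: float
    status: str  # pass | fail | flagged
    echo: Optional[str] = None  # same value in the companion unit

    @property
    def passed(self) -> bool:
        return self.status == "pass"


@dataclass
class GoalReport:
    results: List[GoalResult]

    @property
    def ok(self) -> bool:
        """True when no goal failed outright (flagged violations allowed)."""
        return all(r.status != "fail" for r in self.results)

    @property
    def n_failed(self) -> int:
        return sum(r.status == "fail" for r in self.results)

    def to_records(self) -> List[dict]:
        return [
            {
                "scope": r.scope, "roi": r.roi, "metric": r.goal.metric,
                "parameter": r.goal.parameter, "comparator": r.goal.comparator,
                "threshold": r.threshold, "unit": r.goal.unit,
                "achieved": r.achieved, "status": r.status, "echo": r.echo,
            }
            for r in self.results
        ]


def _compare(value: float, comparator: str, threshold: float) -> bool:
    return {
        "<": value < threshold,
        "<=": value <= threshold + 1e-12,
        ">": value > threshold,
        ">=": value >= threshold - 1e-12,
    }[comparator]


def evaluate_goals(
    doses: Dict[str, VoxelGrid],
    prescriptions: Dict[str, float],
    structs: StructureSet,
    goals: Sequence[ClinicalGoal],
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
) -> GoalReport:
    """Judge every goal against the supplied dose distributions.

    *doses* maps scope name ('initial', 'boost', 'plan_sum') to a dose grid;
    *prescriptions* gives the reference dose (Gy) per scope for ``pct_rx``
    thresholds.  A violated goal on an OAR that overlaps the PTV is reported
    as ``flagged`` rather than ``fail`` (dose spill into the overlap is
    clinically accepted); everything else that misses its threshold fails.
    """
    results: List[GoalResult] = []
    for goal in goals:
        scopes = ("initial", "boost") if goal.scope == "per_plan" else (goal.scope,)
        for scope in scopes:
            if scope not in doses:
                raise KeyError(f"no dose supplied for scope '{scope}'")
            dose = doses[scope]
            roi_name = goal.roi
            if roi_name == "PTV":
                roi_name = PTV_BY_SCOPE.get(scope, "PTV_initial")
            members = ROI_GROUPS.get(roi_name, (roi_name,))
            worst: Optional[GoalResult] = None
            for member in members:
                if member not in structs:
                    raise KeyError(f"goal ROI '{member}' not in structure set")
                roi = structs[member]
                res = _evaluate_single(goal, scope, roi, dose,
                                       prescriptions.get(scope), structs, bin_width_gy)
                if worst is None or _worse(goal, res, worst):
                    worst = res
            results.append(worst)
    return GoalReport(results)


def _worse(goal: ClinicalGoal, a: GoalResult, b: GoalResult) -> bool:
    if goal.comparator in ("<", "<="):
        return a.achieved > b.achieved
    return a.achieved < b.achieved


def _evaluate_single(goal, scope, roi, dose, rx, structs, bin_width_gy) -> GoalResult:
    dvh = cumulative_dvh(dose, roi, bin_width_gy)
    echo = None
    if goal.metric == "Dx":
        val_gy = dose_at_volume(dvh, goal.parameter)
        achieved = 100.0 * val_gy / rx if goal.unit == "pct_rx" else val_gy
        if goal.unit == "pct_rx":
            echo = f"{val_gy:.2f} Gy"
    elif goal.metric == "Vx":
        pct, cc = volume_at_dose(dvh, goal.parameter)
        achieved = pct if goal.unit == "pct_volume" else cc
        echo = f"{cc:.1f} cc" if goal.unit == "pct_volume" else f"{pct:.1f} %"
    elif goal.metric == "Dmax":
        val_gy = d_max(dose, roi)
        achieved = 100.0 * val_gy / rx if goal.unit == "pct_rx" else val_gy
    else:  # Dmean
        val_gy = d_mean(dose, roi)
        achieved = 100.0 * val_gy / rx if goal.unit == "pct_rx" else val_gy
    ok = _compare(achieved, goal.comparator, goal.threshold)
    status = "pass"
    if not ok:
        status = "flagged" if _overlaps_ptv(roi, structs) else "fail"
    return GoalResult(goal, scope, roi.name, float(achieved), goal.unit,
                      goal.threshold, status, echo)


def _overlaps_ptv(roi: ROIMask, structs: StructureSet) -> bool:
    if roi.name.startswith("PTV"):
        return False
    for ptv_name in ("PTV_initial", "PTV_boost"):
        if ptv_name in structs and (roi.mask & structs[ptv_name].mask).any():
            return True
    return False


# ---------------------------------------------------------------------------
# Gamma analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaCriteria:
    dose_diff_pct: float = 3.0
    dta_mm: float = 2.0
    low_dose_cutoff_fraction: float = 0.1
    normalization: str = "global"
    search_radius_factor: float = 3.0
    step_fraction: float = 0.2  # interpolation step as a fraction of DTA

    def __post_init__(self) -> None:
        if self.dose_diff_pct <= 0 or self.dta_mm <= 0:
            raise ValueError("gamma criteria must be positive")
        if self.normalization != "global":
            raise ValueError("only global normalization is implemented")


@dataclass
class GammaResult:
    pass_rate_pct: float
    n_analyzed: int
    gamma: VoxelGrid  # NaN outside the analyzed region


def gamma_pass_rate(
    reference: VoxelGrid,
    evaluated: VoxelGrid,
    criteria: GammaCriteria = GammaCriteria(),
    mask: Optional[ROIMask] = None,
) -> GammaResult:
    """Global-normalisation gamma between two dose distributions.

    For every reference voxel above the low-dose cutoff the minimum
    generalised distance to the (trilinearly interpolated) evaluated dose is
    searched over a ball of offsets (radius ``search_radius_factor × DTA``,
    step ``step_fraction × DTA``); the pass rate is the percentage of
    analysed voxels with gamma ≤ 1.  The grids must overlap; the evaluated
    distribution may live on a shifted grid.
    """
    ref_max = float(reference.values.max())
    if ref_max <= 0:
        raise ValueError("reference dose is empty")
    _check_grids_overlap(reference, evaluated)
    dd = criteria.dose_diff_pct / 100.0 * ref_max
    dta = criteria.dta_mm
    analyzed = reference.values >= criteria.low_dose_cutoff_fraction * ref_max
    if mask is not None:
        analyzed &= mask.mask
    n = int(analyzed.sum())
    if n == 0:
        raise ValueError("no voxels above the low-dose cutoff")
    ref_vals = reference.values[analyzed].astype(float)
    pos = reference.geometry.voxel_centers(analyzed)
    base_idx = evaluated.geometry.world_to_index(pos).T  # (3, n)
    spacing = np.asarray(evaluated.geometry.spacing_mm)

    step = criteria.step_fraction * dta
    radius = criteria.search_radius_factor * dta
    k = int(np.floor(radius / step + 1e-9))
    axis = step * np.arange(-k, k + 1)  # exact 0.0 at the centre
    offs = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), -1).reshape(-1, 3)
    dist = np.linalg.norm(offs, axis=1)
    keep = dist <= radius + 1e-9
    offs, dist = offs[keep], dist[keep]
    order = np.argsort(dist)
    offs, dist = offs[order], dist[order]

    ev = evaluated.values.astype(float)
    best = np.full(n, np.inf)
    active = np.arange(n)
    for delta, r in zip(offs, dist):
        bound = (r / dta) ** 2
        sel = best[active] > bound
        active = active[sel]
        if active.size == 0:
            break
        idx = base_idx[:, active] + (delta / spacing)[:, None]
        ev_d = map_coordinates(ev, idx, order=1, cval=-1e9)
        g2 = ((ev_d - ref_vals[active]) / dd) ** 2 + bound
        np.minimum.at(best, active, g2)
    gamma_flat = np.sqrt(best)
    pass_rate = 100.0 * float(np.mean(gamma_flat <= 1.0 + 1e-9))
    gmap = np.full(reference.geometry.shape, np.nan)
    gmap[analyzed] = gamma_flat
    return GammaResult(pass_rate, n, VoxelGrid(reference.geometry, gmap))


def _check_grids_overlap(a: VoxelGrid, b: VoxelGrid) -> None:
    for ax in range(3):
        a_lo = a.geometry.origin_mm[ax]
        a_hi = a_lo + (a.geometry.shape[ax] - 1) * a.geometry.spacing_mm[ax]
        b_lo = b.geometry.origin_mm[ax]
        b_hi = b_lo + (b.geometry.shape[ax] - 1) * b.geometry.spacing_mm[ax]
        if a_hi < b_lo or b_hi < a_lo:
            raise ValueError("dose grids do not overlap")


# ---------------------------------------------------------------------------
# Delivery complexity
# ---------------------------------------------------------------------------

def total_mu(plan: ArcPlan) -> float:
    """Sum of control-point meterset weights."""
    return plan.total_mu


def modulation_complexity(plan: ArcPlan) -> float:
    """VMAT modulation complexity score in [0, 1]; lower = more modulated.

    Per control point the aperture-area variability AAV is the summed
    leaf-pair opening normalised by each pair's maximum opening over the
    whole arc, and the leaf-sequence variability LSV measures how much
    adjacent leaves in each bank differ relative to the bank's position
    range (banks multiplied).  Adjacent control-point pairs are averaged and
    weighted by their relative MU.
    """
    if plan.total_mu <= 0:
        raise ValueError("plan has zero total MU")
    openings = np.stack([cp.leaf_right_mm - cp.leaf_left_mm
                         for cp in plan.control_points])  # (n_cp, n_pairs)
    if openings.shape[1] == 0:
        raise ValueError("plan has no leaf pairs")
    pair_max = openings.max(axis=0)
    denom = pair_max.sum()
    aav = openings.sum(axis=1) / denom if denom > 0 else np.zeros(plan.n_cp)

    def lsv_bank(pos: np.ndarray, open_sel: np.ndarray) -> float:
        p = pos[open_sel]
        if p.size <= 1:
            return 1.0
        pos_max = float(p.max() - p.min())
        if pos_max <= 1e-9:
            return 1.0
        diffs = np.abs(np.diff(p))
        return float(np.mean((pos_max - diffs) / pos_max))

    lsv = np.empty(plan.n_cp)
    for i, cp in enumerate(plan.control_points):
        open_sel = openings[i] > 1e-9
        lsv[i] = (lsv_bank(cp.leaf_left_mm, open_sel)
                  * lsv_bank(cp.leaf_right_mm, open_sel))

    mus = np.array([cp.mu for cp in plan.control_points])
    pair_mu = (mus[:-1] + mus[1:]) / 2.0
    if pair_mu.sum() <= 0:
        raise ValueError("plan has zero total MU")
    rel = pair_mu / pair_mu.sum()
    aav_pair = (aav[:-1] + aav[1:]) / 2.0
    lsv_pair = (lsv[:-1] + lsv[1:]) / 2.0
    return float(np.sum(aav_pair * lsv_pair * rel))


# ---------------------------------------------------------------------------
# Paired statistics
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank_exact(
    pairs: Iterable[Tuple[float, float]],
    exact_max_n: int = 25,
) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped (classical treatment); ties receive
    midranks.  The statistic is W⁺, the sum of ranks of positive
    differences.  For n ≤ *exact_max_n* the p-value is exact — computed from
    the distribution of W⁺ over all 2ⁿ sign assignments of the observed
    ranks — otherwise a normal approximation with tie-corrected variance
    and continuity correction is used.
    """
    diffs = np.array([a - b for a, b in pairs], dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise ValueError("all differences are zero; p undefined")
    ranks = rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    if n <= exact_max_n:
        # DP over doubled ranks (midranks × 2 are integers)
        r2 = np.round(2 * ranks).astype(int)
        total = int(r2.sum())
        pmf = np.zeros(total + 1)
        pmf[0] = 1.0
        for r in r2:  # multiply the generating polynomial by (1 + x^r)
            shifted = np.zeros_like(pmf)
            shifted[r:] = pmf[: total + 1 - r]
            pmf = pmf + shifted
        pmf /= pmf.sum()
        w2 = int(round(2 * w_plus))
        p_low = float(pmf[: w2 + 1].sum())
        p_high = float(pmf[w2:].sum())
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mean = ranks.sum() / 2.0
        var = float(np.sum(ranks ** 2)) / 4.0
        shift = w_plus - mean
        z = (shift - 0.5 * np.sign(shift)) / math.sqrt(var) if var > 0 else 0.0
        p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return w_plus, p
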