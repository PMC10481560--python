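"""The automated planning workflow.

Given a density grid, contoured structures and a clinical-goal list, the
planner runs the staged pipeline for the initial (45 Gy) and boost (5.4 Gy)
plans: ROI-name check → density mapping → virtual couch → derived
optimization ROIs → isocentre at the PTV centre → automatic objective
construction (with a dose fall-off objective per organ at risk) → two
optimization passes → hotspot extraction and three correction passes →
PTV-coverage constraint escalation and a final optimization → leaf
sequencing → goal evaluation on the individual plans and their sum.

Every stage is appended to an ordered log; the whole pipeline is a pure
function of its inputs (no hidden randomness).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.optimize import minimize

from .dose import (
    ArcPlan,
    BeamModel,
    DoseInfluence,
    FluenceGrid,
    aperture_weights,
    build_arc,
    calibrate_output,
    compute_dose,
    fluence_grid_for_target,
    influence_matrix,
    rescale_plan_mu,
    sequence_leaves,
)
from .grid import ROIMask, StructureSet, VoxelGrid
from .metrics import (
    ClinicalGoal,
    GammaCriteria,
    GoalReport,
    conformity_index,
    cumulative_dvh,
    dose_at_volume,
    evaluate_goals,
    gamma_pass_rate,
    homogeneity_index,
    modulation_complexity,
    plan_sum,
)
from .phantom import CouchConfig, insert_virtual_couch
from .structures import (
    ANTERIOR_SHELL,
    BLADDER_OPT,
    NORMAL_TISSUE,
    SMALLBOWEL_OPT,
    DerivedRoiConfig,
    check_roi_names,
    derive_optimization_rois,
)

HOTSPOT_ROI = "z_Hotspot"


class AutoPlanError(RuntimeError):
    pass


class OptimizationError(AutoPlanError):
    pass


@dataclass
class Objective:
    """One optimization penalty term.

    ``dose_falloff`` penalises dose above a target that ramps linearly from
    ``high_gy`` at the ROI's PTV-facing boundary down to ``low_gy`` at
    ``distance_mm`` from the PTV.
    """

    kind: str  # min_dose | max_dose | max_dvh | uniform | dose_falloff
    roi: str
    dose_gy: float = 0.0
    volume_pct: Optional[float] = None
    high_gy: Optional[float] = None
    low_gy: Optional[float] = None
    distance_mm: Optional[float] = None
    weight: float = 1.0
    is_constraint: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("min_dose", "max_dose", "max_dvh", "uniform", "dose_falloff"):
            raise ValueError(f"unknown objective kind '{self.kind}'")
        if self.weight <= 0:
            raise ValueError("objective weight must be positive")
        if self.dose_gy < 0:
            raise ValueError("dose level must be >= 0")
        if self.kind == "dose_falloff":
            if self.high_gy is None or self.low_gy is None or self.distance_mm is None:
                raise ValueError("dose_falloff needs high_gy, low_gy and distance_mm")
            if not self.high_gy > self.low_gy:
                raise ValueError("dose_falloff needs high_gy > low_gy")
            if self.distance_mm <= 0:
                raise ValueError("dose_falloff needs distance_mm > 0")
        if self.kind == "max_dvh" and self.volume_pct is None:
            raise ValueError("max_dvh needs volume_pct")


@dataclass(frozen=True)
class AutoPlanConfig:
    """Tunables of the automated workflow (defaults are the shipped study
    conditions; pass counts mirror the scripted two-pass / three-pass
    scheme)."""

    prescription_initial_gy: float = 45.0
    prescription_boost_gy: float = 5.4
    n_cp: int = 72
    collimator_deg: float = 355.0
    hotspot_threshold_fraction: float = 1.05
    initial_opts: int = 2
    hotspot_opts: int = 3
    inner_iterations: int = 30
    escalation_factor: float = 10.0
    max_escalations: int = 5
    falloff_low_fraction: float = 0.3
    falloff_distance_mm: float = 20.0
    ptv_min_dose_fraction: float = 0.995
    ptv_max_dose_fraction: float = 1.05
    ptv_min_weight: float = 60.0
    ptv_uniform_weight: float = 3.0
    ptv_max_weight: float = 15.0
    oar_falloff_weight: float = 2.0
    normal_falloff_weight: float = 1.0
    hotspot_weight: float = 30.0
    sequencer_threshold: float = 0.5
    sequencer_row_gate: float = 0.35
    sequencer_refine_sweeps: int = 10
    sequencer_mu_refit: bool = True
    smoothing_weight: float = 0.02
    ray_step_mm: float = 2.5
    couch: CouchConfig = CouchConfig()
    derived_rois: DerivedRoiConfig = DerivedRoiConfig()
    machine: BeamModel = BeamModel()
    d93_goal_pct: float = 98.0

    def __post_init__(self) -> None:
        if self.hotspot_threshold_fraction <= 1.0:
            raise ValueError("hotspot threshold must exceed 1.0")
        if self.initial_opts < 0 or self.hotspot_opts < 0:
            raise ValueError("pass counts must be >= 0")
        if self.escalation_factor <= 1.0:
            raise ValueError("escalation factor must exceed 1.0")


@dataclass
class StageRecord:
    plan: str  # "initial" | "boost" | "common"
    stage: str
    seconds: float
    info: dict = field(default_factory=dict)


@dataclass
class PlanArtifacts:
    """Everything produced for one plan (initial or boost)."""

    plan: ArcPlan
    dose: VoxelGrid
    weights: np.ndarray
    fluence_grid: FluenceGrid
    influence: Optional[DoseInfluence]
    objectives: List[Objective]
    escalation_rounds: int
    sequenced_gamma_pct: float
    metrics: dict
    structs_derived: Optional[StructureSet] = None


@dataclass
class AutoPlanResult:
    plan_initial: ArcPlan
    plan_boost: ArcPlan
    dose_initial: VoxelGrid
    dose_boost: VoxelGrid
    dose_sum: VoxelGrid
    goal_report: GoalReport
    log: List[StageRecord]
    structs: StructureSet
    artifacts: Dict[str, PlanArtifacts]
    density_planning: VoxelGrid


# ---------------------------------------------------------------------------
# Objective construction
# ---------------------------------------------------------------------------

_GOAL_TO_OPT_ROI = {
    "Bladder": (BLADDER_OPT,),
    "SmallBowel": (SMALLBOWEL_OPT,),
    "FemoralHeads": ("FemoralHead_L", "FemoralHead_R"),
    "FemoralHead_L": ("FemoralHead_L",),
    "FemoralHead_R": ("FemoralHead_R",),
}


def build_objectives(
    structs: StructureSet,
    prescription_gy: float,
    config: AutoPlanConfig = AutoPlanConfig(),
    ptv_name: str = "PTV_initial",
    goals: Sequence[ClinicalGoal] = (),
) -> List[Objective]:
    """Automatic objective list for one plan.

    The PTV receives a uniform-dose objective, a minimum-dose objective near
    prescription and a maximum-dose cap derived from the near-maximum goal.
    Every organ at risk referenced by the goals receives exactly one dose
    fall-off objective (high = prescription at the PTV-facing boundary, low
    = ``falloff_low_fraction`` × prescription at ``falloff_distance_mm``),
    as do the derived dose-shape structures (abdominal-direction shell and
    normal-tissue ring).  With an empty goal list only the PTV objectives
    are returned.
    """
    if ptv_name not in structs:
        raise KeyError(f"PTV '{ptv_name}' not in structure set")
    rx = prescription_gy
    objs: List[Objective] = [
        Objective("uniform", ptv_name, dose_gy=rx, weight=config.ptv_uniform_weight),
        Objective("min_dose", ptv_name, dose_gy=config.ptv_min_dose_fraction * rx,
                  weight=config.ptv_min_weight),
        Objective("max_dose", ptv_name, dose_gy=config.ptv_max_dose_fraction * rx,
                  weight=config.ptv_max_weight),
    ]
    if not goals:
        return objs

    falloff = dict(high_gy=rx, low_gy=config.falloff_low_fraction * rx,
                   distance_mm=config.falloff_distance_mm)
    oar_rois: List[str] = []
    for goal in goals:
        for roi in _GOAL_TO_OPT_ROI.get(goal.roi, ()):
            if roi not in oar_rois:
                oar_rois.append(roi)
    for roi in oar_rois:
        if roi not in structs:
            raise KeyError(f"objective ROI '{roi}' not in structure set")
        objs.append(Objective("dose_falloff", roi, weight=config.oar_falloff_weight,
                              **falloff))
    for roi, weight in ((ANTERIOR_SHELL, config.oar_falloff_weight),
                        (NORMAL_TISSUE, config.normal_falloff_weight)):
        if roi in structs and not structs[roi].is_empty:
            objs.append(Objective("dose_falloff", roi, weight=weight, **falloff))
    return objs


# ---------------------------------------------------------------------------
# Penalty model + solver
# ---------------------------------------------------------------------------

class _PenaltyModel:
    """Weighted one-sided quadratic penalties over influence points."""

    def __init__(self, influence: DoseInfluence, objectives: Sequence[Objective],
                 structs: StructureSet, ptv_name: str):
        if not objectives:
            raise ValueError("objective list is empty")
        self.influence = influence
        geo = influence.geometry
        lookup = np.full(int(np.prod(geo.shape)), -1, dtype=np.int64)
        lookup[influence.voxel_idx] = np.arange(influence.n_points)
        ptv_dist: Optional[np.ndarray] = None
        self.terms = []
        for obj in objectives:
            roi = structs[obj.roi]
            pos = lookup[np.flatnonzero(roi.mask.ravel())]
            pos = pos[pos >= 0]
            if pos.size == 0:
                continue
            target: np.ndarray | float
            if obj.kind == "dose_falloff":
                if ptv_dist is None:
                    ptv_dist = distance_transform_edt(
                        ~structs[ptv_name].mask, sampling=geo.spacing_mm
                    ).ravel()[influence.voxel_idx]
                d = np.minimum(ptv_dist[pos], obj.distance_mm) / obj.distance_mm
                target = obj.high_gy - (obj.high_gy - obj.low_gy) * d
            else:
                target = obj.dose_gy
            self.terms.append((obj, pos, target))
        if not self.terms:
            raise ValueError("no objective overlaps the influence region")

    def value_and_residual(self, dose_pts: np.ndarray):
        f = 0.0
        resid = np.zeros_like(dose_pts)
        for obj, pos, target in self.terms:
            d = dose_pts[pos]
            scale = obj.weight / pos.size
            if obj.kind in ("max_dose", "dose_falloff"):
                exc = np.maximum(d - target, 0.0)
            elif obj.kind == "min_dose":
                exc = -np.maximum(target - d, 0.0)
            elif obj.kind == "uniform":
                exc = d - target
            else:  # max_dvh
                exc = np.zeros_like(d)
                over = d > target
                n_allowed = int(obj.volume_pct / 100.0 * pos.size)
                n_over = int(over.sum())
                if n_over > n_allowed:
                    dv = np.partition(d, pos.size - n_allowed - 1)[pos.size - n_allowed - 1] \
                        if n_allowed > 0 else np.inf
                    sel = over & (d <= dv) if np.isfinite(dv) else over
                    exc[sel] = d[sel] - target
            f += scale * float(np.sum(exc ** 2))
            np.add.at(resid, pos, 2.0 * scale * exc)
        return f, resid


def _smoothness(w: np.ndarray, lam: float):
    """Quadratic penalty on fluence roughness within each control point."""
    if lam <= 0:
        return 0.0, np.zeros_like(w)
    du = np.diff(w, axis=2)
    dv = np.diff(w, axis=1)
    scale = lam / w.size
    f = scale * (float(np.sum(du ** 2)) + float(np.sum(dv ** 2)))
    grad = np.zeros_like(w)
    grad[:, :, :-1] -= 2 * scale * du
    grad[:, :, 1:] += 2 * scale * du
    grad[:, :-1, :] -= 2 * scale * dv
    grad[:, 1:, :] += 2 * scale * dv
    return f, grad


def optimize(
    influence: DoseInfluence,
    objectives: Sequence[Objective],
    structs: StructureSet,
    start_weights: Optional[np.ndarray] = None,
    n_iter: int = 30,
    ptv_name: str = "PTV_initial",
    smoothing_weight: float = 0.0,
) -> Tuple[np.ndarray, List[float]]:
    """Bound-constrained descent on the weighted penalty sum.

    Minimises over non-negative beamlet weights with projected quasi-Newton
    steps (L-BFGS-B); returns the optimized weights and the objective trace
    at accepted iterates (non-increasing).  Warm-startable through
    *start_weights*; raises :class:`OptimizationError` if the final
    objective exceeds the starting one.  A small fluence-roughness penalty
    (``smoothing_weight``) keeps the optimum deliverable by a single
    aperture per control point.
    """
    model = _PenaltyModel(influence, objectives, structs, ptv_name)
    shape = influence.weights_shape()
    x0 = (np.zeros(shape) if start_weights is None else
          np.asarray(start_weights, dtype=float)).ravel()
    if np.any(x0 < 0):
        raise ValueError("start weights must be non-negative")
    trace: List[float] = []
    last_f = [np.inf]

    def fun_and_grad(x):
        w = x.reshape(shape)
        dose_pts = influence.dose(w)
        f, resid = model.value_and_residual(dose_pts)
        grad = influence.adjoint(resid.astype(np.float32))
        fs, gs = _smoothness(w, smoothing_weight)
        f += fs
        grad = (grad + gs).ravel()
        last_f[0] = f
        return f, grad

    f0, _ = fun_and_grad(x0)
    trace.append(f0)
    res = minimize(
        fun_and_grad, x0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * x0.size,
        options={"maxiter": n_iter, "maxfun": 4 * n_iter + 20, "ftol": 1e-12,
                 "gtol": 1e-12},
        callback=lambda xk: trace.append(last_f[0]),
    )
    if res.fun > f0 + 1e-9 * max(1.0, f0):
        raise OptimizationError(f"objective increased: {f0} -> {res.fun}")
    w = res.x.reshape(shape)
    w[w < 0] = 0.0
    return w, trace


# ---------------------------------------------------------------------------
# Hotspots / escalation
# ---------------------------------------------------------------------------

def extract_hotspots(
    dose: VoxelGrid,
    prescription_gy: float,
    threshold_fraction: float,
    external: ROIMask,
) -> ROIMask:
    """Voxels (inside the body) at or above threshold × prescription."""
    if threshold_fraction <= 1.0:
        raise ValueError("hotspot threshold must exceed 1.0 (would flag the target)")
    mask = (dose.values >= threshold_fraction * prescription_gy) & external.mask
    return ROIMask(HOTSPOT_ROI, dose.geometry, mask, derived=True)


def escalate_ptv_constraints(
    objectives: Sequence[Objective],
    d93_gy: float,
    goal_d93_gy: float,
    config: AutoPlanConfig,
) -> Tuple[List[Objective], bool]:
    """One escalation round: if coverage misses the goal, raise the PTV
    minimum-dose weight by the escalation factor and mark it a constraint.
    Returns (objectives, escalated?)."""
    if d93_gy >= goal_d93_gy:
        return list(objectives), False
    out = []
    for obj in objectives:
        if obj.kind == "min_dose" and obj.roi.startswith("PTV"):
            out.append(replace(obj, weight=obj.weight * config.escalation_factor,
                               is_constraint=True))
        else:
            out.append(obj)
    return out, True


# ---------------------------------------------------------------------------
# Full workflow
# ---------------------------------------------------------------------------

def run_autoplan(
    density: VoxelGrid,
    structs: StructureSet,
    goals: Sequence[ClinicalGoal],
    config: AutoPlanConfig = AutoPlanConfig(),
    progress: Optional[Callable[[str], None]] = None,
) -> AutoPlanResult:
    """Execute the full automated workflow for initial and boost plans."""
    log: List[StageRecord] = []

    def stage(plan_label: str, name: str, t0: float, **info):
        log.append(StageRecord(plan_label, name, time.perf_counter() - t0, info))
        if progress:
            progress(f"[{plan_label}] {name} {info or ''}")

    t0 = time.perf_counter()
    report = check_roi_names(structs)
    if not report.ok:
        raise AutoPlanError(
            f"ROI name check failed: missing {report.missing}, "
            f"duplicates {report.duplicates}"
        )
    stage("common", "roi_name_check", t0, extra=report.extra)

    # density mapping: inputs are already relative electron density
    t0 = time.perf_counter()
    planning_density = density
    stage("common", "density_mapping", t0, mapping="identity (relative electron density)")

    t0 = time.perf_counter()
    planning_density = insert_virtual_couch(planning_density, config.couch)
    stage("common", "virtual_couch", t0, thickness_mm=config.couch.thickness_mm,
          density=config.couch.density)

    artifacts: Dict[str, PlanArtifacts] = {}
    for label, ptv_name, rx in (
        ("initial", "PTV_initial", config.prescription_initial_gy),
        ("boost", "PTV_boost", config.prescription_boost_gy),
    ):
        artifacts[label] = _plan_one(
            label, ptv_name, rx, planning_density, structs, goals, config, stage
        )

    t0 = time.perf_counter()
    dose_init = artifacts["initial"].dose
    dose_boost = artifacts["boost"].dose
    dose_total = plan_sum(dose_init, dose_boost)
    eval_structs = artifacts["initial"].structs_derived
    goal_report = evaluate_goals(
        {"initial": dose_init, "boost": dose_boost, "plan_sum": dose_total},
        {"initial": config.prescription_initial_gy,
         "boost": config.prescription_boost_gy,
         "plan_sum": config.prescription_initial_gy + config.prescription_boost_gy},
        eval_structs, goals,
    )
    stage("common", "evaluate_goals", t0, ok=goal_report.ok,
          n_failed=goal_report.n_failed)

    return AutoPlanResult(
        plan_initial=artifacts["initial"].plan,
        plan_boost=artifacts["boost"].plan,
        dose_initial=dose_init,
        dose_boost=dose_boost,
        dose_sum=dose_total,
        goal_report=goal_report,
        log=log,
        structs=eval_structs,
        artifacts=artifacts,
        density_planning=planning_density,
    )


def _plan_one(label, ptv_name, rx, density, structs, goals, config, stage) -> PlanArtifacts:
    t0 = time.perf_counter()
    work = derive_optimization_rois(structs, config.derived_rois, ptv_name=ptv_name)
    stage(label, "derive_optimization_rois", t0,
          added=[BLADDER_OPT, SMALLBOWEL_OPT, ANTERIOR_SHELL, NORMAL_TISSUE])

    t0 = time.perf_counter()
    ptv = work[ptv_name]
    iso = tuple(ptv.centroid_mm())
    machine = calibrate_output(config.machine, density, iso)
    plan = build_arc(iso, config.n_cp, config.collimator_deg, machine, rx)
    fgrid = fluence_grid_for_target(plan, ptv)
    stage(label, "set_isocenter_and_arc", t0, isocenter_mm=list(np.round(iso, 2)),
          n_cp=config.n_cp, collimator_deg=config.collimator_deg)

    t0 = time.perf_counter()
    external = work["External"]
    influence = influence_matrix(plan, density, external, fgrid,
                                 ray_step_mm=config.ray_step_mm)
    stage(label, "influence_matrix", t0, n_points=influence.n_points,
          n_beamlets=fgrid.n_beamlets)

    t0 = time.perf_counter()
    objectives = build_objectives(work, rx, config, ptv_name, goals)
    stage(label, "build_objectives", t0, n_objectives=len(objectives))

    weights = influence.zero_weights()
    for i in range(config.initial_opts):
        t0 = time.perf_counter()
        weights, trace = optimize(influence, objectives, work, weights,
                                  config.inner_iterations, ptv_name,
                                  config.smoothing_weight)
        stage(label, "optimize_pass", t0, pass_index=i + 1, objective=trace[-1])

    hotspot_cc: List[float] = []
    if config.hotspot_opts > 0:
        t0 = time.perf_counter()
        dose = compute_dose(plan, influence, weights)
        hs = extract_hotspots(dose, rx, config.hotspot_threshold_fraction, external)
        vv = dose.geometry.voxel_volume_cc
        hotspot_cc.append(hs.count * vv)
        work.add(hs, replace=True)
        stage(label, "extract_hotspots", t0,
              threshold=config.hotspot_threshold_fraction, volume_cc=hotspot_cc[0])
        hot_objectives = list(objectives)
        if not hs.is_empty:
            hot_objectives.append(Objective("max_dose", HOTSPOT_ROI, dose_gy=rx,
                                            weight=config.hotspot_weight))
        for i in range(config.hotspot_opts):
            t0 = time.perf_counter()
            weights, trace = optimize(influence, hot_objectives, work, weights,
                                      config.inner_iterations, ptv_name,
                                      config.smoothing_weight)
            dose = compute_dose(plan, influence, weights)
            vol = float(((dose.values >= config.hotspot_threshold_fraction * rx)
                         & external.mask).sum()) * vv
            hotspot_cc.append(vol)
            stage(label, "hotspot_correction_pass", t0, pass_index=i + 1,
                  objective=trace[-1], hotspot_cc=vol)
        objectives = hot_objectives

    # PTV-coverage escalation + final optimization
    ptv_pos = _roi_positions(influence, ptv)
    goal_gy = config.d93_goal_pct / 100.0 * rx
    rounds = 0
    t0 = time.perf_counter()
    d93 = _d93(influence, weights, ptv_pos)
    while rounds < config.max_escalations:
        objectives, escalated = escalate_ptv_constraints(objectives, d93, goal_gy, config)
        if not escalated:
            break
        rounds += 1
        weights, _ = optimize(influence, objectives, work, weights,
                              config.inner_iterations, ptv_name,
                              config.smoothing_weight)
        d93 = _d93(influence, weights, ptv_pos)
    stage(label, "ptv_constraint_escalation", t0, rounds=rounds,
          d93_pct=100.0 * d93 / rx)
    t0 = time.perf_counter()
    weights, trace = optimize(influence, objectives, work, weights,
                              config.inner_iterations, ptv_name,
                              config.smoothing_weight)
    d93 = _d93(influence, weights, ptv_pos)
    stage(label, "final_optimization", t0, objective=trace[-1],
          d93_pct=100.0 * d93 / rx)

    t0 = time.perf_counter()
    plan = sequence_leaves(plan, weights, fgrid, config.sequencer_threshold,
                           config.sequencer_row_gate)
    dose_opt_pts = influence.dose(weights)
    if config.sequencer_mu_refit:
        plan, dose_seq_pts = _refine_sequenced_plan(
            plan, influence, fgrid, dose_opt_pts, fluence=weights,
            max_sweeps=config.sequencer_refine_sweeps)
    else:
        seq_w = aperture_weights(plan, fgrid)
        dose_seq_pts = influence.dose(seq_w)
        scale = (float(dose_opt_pts[ptv_pos].mean())
                 / max(float(dose_seq_pts[ptv_pos].mean()), 1e-12))
        plan = rescale_plan_mu(plan, scale)
        dose_seq_pts = dose_seq_pts * scale
    dose = compute_dose(plan, influence, weights)
    seq_dose = VoxelGrid(dose.geometry, np.zeros(dose.geometry.shape))
    seq_dose.values.ravel()[influence.voxel_idx] = dose_seq_pts
    seq_gamma = gamma_pass_rate(dose, seq_dose, GammaCriteria()).pass_rate_pct
    stage(label, "sequence_leaves", t0, total_mu=plan.total_mu,
          sequenced_gamma_pct=seq_gamma)

    t0 = time.perf_counter()
    dvh = cumulative_dvh(dose, ptv)
    metrics = {
        "rx_gy": rx,
        "D93_pct": 100.0 * dose_at_volume(dvh, 93.0) / rx,
        "D98_pct": 100.0 * dose_at_volume(dvh, 98.0) / rx,
        "D2_pct": 100.0 * dose_at_volume(dvh, 2.0) / rx,
        "CI": conformity_index(dose, ptv, rx),
        "HI": homogeneity_index(dvh, rx),
        "total_MU": plan.total_mu,
        "MCS": modulation_complexity(plan),
        "hotspot_cc_trace": hotspot_cc,
    }
    stage(label, "plan_metrics", t0,
          **{k: round(v, 3) for k, v in metrics.items()
             if isinstance(v, (int, float))})

    return PlanArtifacts(plan, dose, weights, fgrid, influence, list(objectives),
                         rounds, seq_gamma, metrics, structs_derived=work)


def _roi_positions(influence: DoseInfluence, roi: ROIMask) -> np.ndarray:
    lookup = np.full(int(np.prod(influence.geometry.shape)), -1, dtype=np.int64)
    lookup[influence.voxel_idx] = np.arange(influence.n_points)
    pos = lookup[np.flatnonzero(roi.mask.ravel())]
    return pos[pos >= 0]


def _d93(influence: DoseInfluence, weights: np.ndarray, ptv_pos: np.ndarray) -> float:
    d = influence.dose(weights)[ptv_pos]
    return float(np.percentile(d, 7.0))


def _refine_sequenced_plan(
    plan: ArcPlan, influence: DoseInfluence, fgrid: FluenceGrid,
    dose_opt_pts: np.ndarray, fluence: Optional[np.ndarray] = None,
    max_sweeps: int = 10, max_points: int = 50000,
) -> Tuple[ArcPlan, np.ndarray]:
    """Refine a threshold-sequenced plan toward the fluence-optimal dose.

    Aperture shapes and metersets start from the threshold sequencer's
    construction; the refinement then alternates (a) a non-negative
    least-squares fit of the per-control-point metersets to the optimal
    dose and (b) greedy leaf-edge coordinate descent (open/close one
    beamlet at a time, plus opening closed rows at their fluence peak) on
    the squared dose error.  Beamlet dose columns are cached sparsely, so
    later sweeps are cheap; the loop stops early once few moves remain.
    Returns the refined plan and its dose at the influence points.
    """
    from scipy.optimize import nnls

    from .dose import ControlPoint

    n_cp = plan.n_cp
    nv, nu = fgrid.nv, fgrid.nu
    u = fgrid.u_centers()
    half = fgrid.pitch_mm / 2.0

    # aperture index representation (inclusive; hi < lo = closed row)
    lo = np.zeros((n_cp, nv), int)
    hi = np.full((n_cp, nv), -1, int)
    for c, cp in enumerate(plan.control_points):
        for j in range(min(nv, cp.leaf_left_mm.size)):
            if cp.leaf_right_mm[j] > cp.leaf_left_mm[j]:
                lo[c, j] = int(np.searchsorted(u, cp.leaf_left_mm[j]))
                hi[c, j] = int(np.searchsorted(u, cp.leaf_right_mm[j])) - 1

    cache: dict = {}

    def beamlet_col(c: int, j: int, i: int):
        key = (c, j, i)
        if key not in cache:
            wv = np.zeros((n_cp, nv, nu), dtype=np.float32)
            wv[c, j, i] = 1.0
            dense = influence.dose(wv)
            top = dense.max()
            nz = np.flatnonzero(dense > 1e-6 * top) if top > 0 else np.zeros(0, int)
            cache[key] = (nz, dense[nz])
        return cache[key]

    def unit_cols() -> np.ndarray:
        cols = np.zeros((influence.n_points, n_cp), dtype=np.float32)
        wv = np.zeros((n_cp, nv, nu))
        for c in range(n_cp):
            wv[:] = 0.0
            for j in range(nv):
                if hi[c, j] >= lo[c, j]:
                    wv[c, j, lo[c, j]:hi[c, j] + 1] = 1.0
            if np.any(wv[c]):
                cols[:, c] = influence.dose(wv)
        return cols

    stride = max(1, influence.n_points // max_points)
    sel = slice(None, None, stride)
    cols = unit_cols()
    mu, _ = nnls(cols[sel].astype(float), dose_opt_pts[sel])
    resid = cols.astype(float) @ mu - dose_opt_pts

    n_open = max(1, int((hi >= lo).sum()))
    for _ in range(max_sweeps):
        moved = 0
        for c in range(n_cp):
            m = mu[c]
            if m <= 0:
                continue
            for j in range(nv):
                if hi[c, j] < lo[c, j]:
                    # closed row: try opening it at the fluence peak
                    if fluence is None or fluence[c, j].max() <= 0:
                        continue
                    i = int(np.argmax(fluence[c, j]))
                    nz, vals = beamlet_col(c, j, i)
                    dv = m * vals
                    dsse = 2.0 * float(resid[nz] @ dv) + float(dv @ dv)
                    if dsse < -1e-9:
                        resid[nz] += dv
                        lo[c, j] = hi[c, j] = i
                        moved += 1
                    continue
                for edge, dirn in ((0, -1), (0, +1), (1, +1), (1, -1)):
                    if hi[c, j] < lo[c, j]:
                        break
                    if edge == 0:
                        i = lo[c, j] - 1 if dirn == -1 else lo[c, j]
                        sign = +1 if dirn == -1 else -1
                    else:
                        i = hi[c, j] + 1 if dirn == +1 else hi[c, j]
                        sign = +1 if dirn == +1 else -1
                    if i < 0 or i >= nu:
                        continue
                    nz, vals = beamlet_col(c, j, i)
                    dv = sign * m * vals
                    dsse = 2.0 * float(resid[nz] @ dv) + float(dv @ dv)
                    if dsse < -1e-9:
                        resid[nz] += dv
                        moved += 1
                        if edge == 0:
                            lo[c, j] += -1 if dirn == -1 else 1
                        else:
                            hi[c, j] += 1 if dirn == +1 else -1
        cols = unit_cols()
        mu, _ = nnls(cols[sel].astype(float), dose_opt_pts[sel])
        resid = cols.astype(float) @ mu - dose_opt_pts
        if moved < 0.02 * n_open:
            break

    new_cps = []
    for c, cp in enumerate(plan.control_points):
        left = np.zeros(nv)
        right = np.zeros(nv)
        for j in range(nv):
            if hi[c, j] >= lo[c, j] and mu[c] > 0:
                left[j] = u[lo[c, j]] - half
                right[j] = u[hi[c, j]] + half
        new_cps.append(ControlPoint(cp.gantry_deg, float(mu[c]), left, right))
    new_plan = ArcPlan(new_cps, plan.collimator_deg, plan.isocenter_mm,
                       plan.prescription_gy, plan.machine)
    return new_plan, cols.astype(float) @ mu
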