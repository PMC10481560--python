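"""Simplified single-arc dose engine.

A linear, deterministic pencil-beam model: per control point, primary photon
beamlets attenuate exponentially with radiological depth, diverge with
inverse-square distance from the source, and spread laterally with a
Gaussian penumbra in the beam's-eye view (BEV).  Dose is linear in beamlet
weight (MU), which is what every downstream algorithm (objective descent,
DVH evaluation, gamma QA) relies on.  No buildup, scatter kernels or
machine-dynamics constraints are modelled.

Geometry: the arc is coplanar around the CC axis.  At gantry 0° the source
sits anterior; the beam travels toward +AP.  BEV coordinates (u, v) are at
the isocentre plane, u along the (collimator-rotated) leaf-travel direction
and v across leaf pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates

from .grid import GridGeometry, ROIMask, VoxelGrid

try:  # JIT gather/scatter kernels; pure-numpy fallback keeps results identical
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

if _HAVE_NUMBA:

    @_njit(cache=True, fastmath=False)
    def _gather_kernel(i0, j0, au, gv, wpad, nu4, out):
        n = i0.shape[0]
        for p in range(n):
            base = (j0[p] + 2) * nu4 + (i0[p] + 2)
            acc = 0.0
            for dj in range(-1, 2):
                g = gv[p, dj + 1]
                row = base + dj * nu4
                for di in range(-1, 2):
                    acc += au[p, di + 1] * g * wpad[row + di]
            out[p] += acc

    @_njit(cache=True, fastmath=False)
    def _scatter_kernel(i0, j0, au, gv, r, nu4, acc):
        n = i0.shape[0]
        for p in range(n):
            base = (j0[p] + 2) * nu4 + (i0[p] + 2)
            rp = r[p]
            for dj in range(-1, 2):
                g = rp * gv[p, dj + 1]
                row = base + dj * nu4
                for di in range(-1, 2):
                    acc[row + di] += au[p, di + 1] * g


@dataclass(frozen=True)
class BeamModel:
    """Parameters of the simplified 10-MV-like photon beam."""

    mu_water_per_cm: float = 0.04
    penumbra_sigma_mm: float = 3.0
    sad_mm: float = 1000.0
    beamlet_width_mm: float = 5.0
    output_gy_per_mu: float = 1.0

    def __post_init__(self) -> None:
        for f, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"BeamModel.{f} must be positive, got {v}")


@dataclass
class ControlPoint:
    """One gantry-angle sample of the arc: aperture and meterset weight."""

    gantry_deg: float
    mu: float = 0.0
    leaf_left_mm: np.ndarray = field(default_factory=lambda: np.zeros(0))
    leaf_right_mm: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.leaf_left_mm = np.asarray(self.leaf_left_mm, dtype=float)
        self.leaf_right_mm = np.asarray(self.leaf_right_mm, dtype=float)
        if self.mu < 0:
            raise ValueError("control-point MU must be >= 0")
        if self.leaf_left_mm.shape != self.leaf_right_mm.shape:
            raise ValueError("leaf bank arrays must have equal length")
        if np.any(self.leaf_left_mm > self.leaf_right_mm + 1e-9):
            raise ValueError("leaf_left must not exceed leaf_right")


@dataclass
class ArcPlan:
    """A single full-rotation coplanar VMAT arc."""

    control_points: List[ControlPoint]
    collimator_deg: float
    isocenter_mm: Tuple[float, float, float]
    prescription_gy: float
    machine: BeamModel

    def __post_init__(self) -> None:
        if len(self.control_points) < 2:
            raise ValueError("an arc needs at least 2 control points")
        angles = [cp.gantry_deg for cp in self.control_points]
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("gantry angles must be strictly increasing")
        if not (0 <= angles[0] and angles[-1] < 360):
            raise ValueError("gantry angles must lie in [0, 360)")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")

    @property
    def n_cp(self) -> int:
        return len(self.control_points)

    @property
    def gantry_angles_deg(self) -> np.ndarray:
        return np.array([cp.gantry_deg for cp in self.control_points])

    @property
    def total_mu(self) -> float:
        return float(sum(cp.mu for cp in self.control_points))


def build_arc(
    isocenter_mm: Sequence[float],
    n_cp: int = 72,
    collimator_deg: float = 355.0,
    machine: BeamModel = BeamModel(),
    prescription_gy: float = 45.0,
) -> ArcPlan:
    """Uniformly spaced full arc starting at gantry 0°, zero MU, leaves closed."""
    if n_cp < 8:
        raise ValueError(f"need at least 8 control points, got {n_cp}")
    spacing = 360.0 / n_cp
    cps = [ControlPoint(gantry_deg=i * spacing) for i in range(n_cp)]
    return ArcPlan(cps, collimator_deg, tuple(float(c) for c in isocenter_mm),
                   prescription_gy, machine)


def _cp_basis(gantry_deg: float, collimator_deg: float):
    """Beam direction and collimator-rotated BEV basis vectors."""
    th = math.radians(gantry_deg)
    beam = np.array([-math.sin(th), math.cos(th), 0.0])
    e_u = np.array([math.cos(th), math.sin(th), 0.0])
    e_v = np.array([0.0, 0.0, 1.0])
    c = math.radians(collimator_deg)
    u_c = math.cos(c) * e_u + math.sin(c) * e_v
    v_c = -math.sin(c) * e_u + math.cos(c) * e_v
    return beam, u_c, v_c


def source_position(plan: ArcPlan, gantry_deg: float) -> np.ndarray:
    beam, _, _ = _cp_basis(gantry_deg, plan.collimator_deg)
    return np.asarray(plan.isocenter_mm) - plan.machine.sad_mm * beam


def radiological_depth(
    density: VoxelGrid,
    source: Sequence[float],
    target: Sequence[float],
    step_mm: float = 1.0,
) -> float:
    """Water-equivalent depth (cm): line integral of density source→target.

    Uniform midpoint sampling with trilinear interpolation; zero through
    vacuum and outside the grid.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    length = float(np.linalg.norm(target - source))
    if length == 0:
        return 0.0
    n = max(1, int(math.ceil(length / step_mm)))
    t = (np.arange(n) + 0.5) / n
    pts = source[None, :] + t[:, None] * (target - source)[None, :]
    idx = density.geometry.world_to_index(pts)
    rho = map_coordinates(density.values.astype(np.float64), idx.T, order=1, cval=0.0)
    return float(rho.sum() * (length / n) / 10.0)


@dataclass(frozen=True)
class FluenceGrid:
    """Beamlet lattice at the isocentre plane, shared by all control points.

    Beamlet centres are ``u0 + i*pitch`` (i < nu, leaf travel) and
    ``v0 + j*pitch`` (j < nv, across leaf pairs).  Weight arrays have shape
    ``(n_cp, nv, nu)``.
    """

    u0: float
    v0: float
    pitch_mm: float
    nu: int
    nv: int

    @property
    def n_beamlets(self) -> int:
        return self.nu * self.nv

    def u_centers(self) -> np.ndarray:
        return self.u0 + self.pitch_mm * np.arange(self.nu)

    def v_centers(self) -> np.ndarray:
        return self.v0 + self.pitch_mm * np.arange(self.nv)

    @classmethod
    def from_extents(cls, u_min, u_max, v_min, v_max, pitch_mm) -> "FluenceGrid":
        nu = int(math.ceil((u_max - u_min) / pitch_mm)) + 1
        nv = int(math.ceil((v_max - v_min) / pitch_mm)) + 1
        return cls(float(u_min), float(v_min), float(pitch_mm), nu, nv)


def fluence_grid_for_target(
    plan: ArcPlan, target: ROIMask, margin_mm: float = 12.5
) -> FluenceGrid:
    """Fluence lattice sized to cover the target's BEV footprint at every
    control point, padded by *margin_mm*."""
    pts = target.geometry.voxel_centers(target.mask)
    sad = plan.machine.sad_mm
    u_lo = v_lo = np.inf
    u_hi = v_hi = -np.inf
    for cp in plan.control_points:
        beam, u_c, v_c = _cp_basis(cp.gantry_deg, plan.collimator_deg)
        src = np.asarray(plan.isocenter_mm) - sad * beam
        q = pts - src
        w = q @ beam
        u = sad * (q @ u_c) / w
        v = sad * (q @ v_c) / w
        u_lo, u_hi = min(u_lo, u.min()), max(u_hi, u.max())
        v_lo, v_hi = min(v_lo, v.min()), max(v_hi, v.max())
    return FluenceGrid.from_extents(
        u_lo - margin_mm, u_hi + margin_mm, v_lo - margin_mm, v_hi + margin_mm,
        plan.machine.beamlet_width_mm,
    )


class DoseInfluence:
    """Sparse mapping (control point, beamlet) → dose per unit MU at points.

    Per-unit-weight dose at a point with BEV coordinates (u, v, w) from the
    beamlet centred at (u_b, v_b):

        output · exp(−μ · d_rad) · (SAD/w)² · G(u−u_b) · G(v−v_b)

    with G a Gaussian of the penumbra sigma, truncated at 1.5 beamlet
    pitches (only the 3×3 nearest beamlets contribute).  Stored matrix-free
    as separable per-control-point factors; :meth:`to_sparse` materialises
    the identical explicit matrix for small problems.
    """

    def __init__(
        self,
        plan: ArcPlan,
        density: VoxelGrid,
        points: np.ndarray,
        grid: FluenceGrid,
        ray_step_mm: float = 2.5,
        voxel_idx: Optional[np.ndarray] = None,
        geometry: Optional[GridGeometry] = None,
    ):
        if len(points) == 0:
            raise ValueError("influence matrix needs at least one target point")
        self.plan = plan
        self.grid = grid
        self.n_points = len(points)
        self.voxel_idx = voxel_idx
        self.geometry = geometry
        self.ray_step_mm = float(ray_step_mm)
        machine = plan.machine
        sad = machine.sad_mm
        sigma = machine.penumbra_sigma_mm
        inv2s2 = 1.0 / (2.0 * sigma * sigma)
        pitch = grid.pitch_mm
        pts = np.asarray(points, dtype=np.float64)

        # w-range of the ray-trace table: cover the whole density grid
        geo = density.geometry
        corners = np.array([
            [geo.origin_mm[a] + (geo.shape[a] - 1) * geo.spacing_mm[a] * bit
             for a, bit in enumerate(bits)]
            for bits in np.ndindex(2, 2, 2)
        ])
        r_max = float(np.max(np.linalg.norm(
            corners - np.asarray(plan.isocenter_mm), axis=1))) + max(geo.spacing_mm)
        w_start = sad - r_max
        nw = int(math.ceil(2.0 * r_max / self.ray_step_mm)) + 1
        dens = density.values.astype(np.float32)

        self._cp_data = []
        for cp in plan.control_points:
            beam, u_c, v_c = _cp_basis(cp.gantry_deg, plan.collimator_deg)
            src = np.asarray(plan.isocenter_mm) - sad * beam
            q = pts - src
            w = q @ beam
            u = sad * (q @ u_c) / w
            v = sad * (q @ v_c) / w

            # divergent-ray depth table on a coarse BEV lattice
            ray_pitch = pitch
            ur0 = math.floor(u.min() / ray_pitch) * ray_pitch - ray_pitch
            vr0 = math.floor(v.min() / ray_pitch) * ray_pitch - ray_pitch
            nur = int(math.ceil((u.max() - ur0) / ray_pitch)) + 2
            nvr = int(math.ceil((v.max() - vr0) / ray_pitch)) + 2
            ur = ur0 + ray_pitch * np.arange(nur)
            vr = vr0 + ray_pitch * np.arange(nvr)
            wk = w_start + self.ray_step_mm * (np.arange(nw) + 0.5)
            dirs = (
                beam[None, None, :]
                + (ur[:, None, None] / sad) * u_c[None, None, :]
                + (vr[None, :, None] / sad) * v_c[None, None, :]
            )  # (nur, nvr, 3)
            dl = np.linalg.norm(dirs, axis=-1) * self.ray_step_mm  # mm per step
            sample = src[None, None, None, :] + dirs[:, :, None, :] * wk[None, None, :, None]
            idx = geo.world_to_index(sample.reshape(-1, 3))
            rho = map_coordinates(dens, idx.T, order=1, cval=0.0).reshape(nur, nvr, nw)
            depth_mid = np.cumsum(rho * dl[:, :, None], axis=2) / 10.0  # cm at wk+step/2
            table = np.concatenate(
                [np.zeros((nur, nvr, 1), dtype=depth_mid.dtype), depth_mid], axis=2
            )  # depth at w_start + k*step

            ti = (u - ur0) / ray_pitch
            tj = (v - vr0) / ray_pitch
            tk = (w - w_start) / self.ray_step_mm
            d_rad = map_coordinates(table, np.stack([ti, tj, tk]), order=1, mode="nearest")
            depthfac = (
                machine.output_gy_per_mu
                * np.exp(-machine.mu_water_per_cm * d_rad)
                * (sad / w) ** 2
            ).astype(np.float32)

            # nearest beamlet, clipped to one step outside the lattice; for
            # clipped points the Gaussian factors below are computed from the
            # true (large) offset and vanish numerically
            i0 = np.clip(np.round((u - grid.u0) / pitch), -1, grid.nu).astype(np.int32)
            j0 = np.clip(np.round((v - grid.v0) / pitch), -1, grid.nv).astype(np.int32)
            du = u - (grid.u0 + i0 * pitch)
            dv = v - (grid.v0 + j0 * pitch)
            au = np.empty((self.n_points, 3), dtype=np.float32)
            gv = np.empty((self.n_points, 3), dtype=np.float32)
            for k, off in enumerate((-1, 0, 1)):
                au[:, k] = depthfac * np.exp(-((du - off * pitch) ** 2) * inv2s2)
                gv[:, k] = np.exp(-((dv - off * pitch) ** 2) * inv2s2)
            self._cp_data.append((i0, j0, au, gv))

    @property
    def n_cp(self) -> int:
        return self.plan.n_cp

    def weights_shape(self) -> Tuple[int, int, int]:
        return (self.n_cp, self.grid.nv, self.grid.nu)

    def zero_weights(self) -> np.ndarray:
        return np.zeros(self.weights_shape(), dtype=np.float64)

    def dose(self, weights: np.ndarray) -> np.ndarray:
        """A·w — dose (Gy) at every influence point; linear, non-negative."""
        weights = np.asarray(weights)
        if weights.shape != self.weights_shape():
            raise ValueError(f"weights shape {weights.shape} != {self.weights_shape()}")
        nu, nv = self.grid.nu, self.grid.nv
        out = np.zeros(self.n_points, dtype=np.float32)
        wpad = np.zeros((nv + 4, nu + 4), dtype=np.float32)
        for cp_idx, (i0, j0, au, gv) in enumerate(self._cp_data):
            wcp = weights[cp_idx]
            if not np.any(wcp):
                continue
            wpad[2:nv + 2, 2:nu + 2] = wcp
            wflat = wpad.ravel()
            if _HAVE_NUMBA:
                _gather_kernel(i0, j0, au, gv, wflat, nu + 4, out)
            else:
                fp0 = (j0 + 2) * (nu + 4) + (i0 + 2)
                for dj in (-1, 0, 1):
                    gj = gv[:, dj + 1]
                    for di in (-1, 0, 1):
                        out += (au[:, di + 1] * gj) * wflat[fp0 + (dj * (nu + 4) + di)]
        return out.astype(np.float64)

    def adjoint(self, point_values: np.ndarray) -> np.ndarray:
        """Aᵀ·r — gradient back-projection onto beamlet weights."""
        r = np.asarray(point_values, dtype=np.float32)
        if r.shape != (self.n_points,):
            raise ValueError("point_values must be 1-D over influence points")
        nu, nv = self.grid.nu, self.grid.nv
        npad = (nv + 4) * (nu + 4)
        grad = np.zeros(self.weights_shape(), dtype=np.float64)
        for cp_idx, (i0, j0, au, gv) in enumerate(self._cp_data):
            if _HAVE_NUMBA:
                acc = np.zeros(npad, dtype=np.float32)
                _scatter_kernel(i0, j0, au, gv, r, nu + 4, acc)
                acc = acc.astype(np.float64)
            else:
                fp0 = (j0 + 2) * (nu + 4) + (i0 + 2)
                acc = np.zeros(npad)
                for dj in (-1, 0, 1):
                    gj = gv[:, dj + 1]
                    for di in (-1, 0, 1):
                        acc += np.bincount(fp0 + (dj * (nu + 4) + di),
                                           weights=r * au[:, di + 1] * gj,
                                           minlength=npad)
            grad[cp_idx] = acc.reshape(nv + 4, nu + 4)[2:nv + 2, 2:nu + 2]
        return grad

    def to_sparse(self) -> sparse.csr_matrix:
        """Explicit CSR matrix (n_points × n_cp·n_beamlets); identical entries
        to the matrix-free path."""
        nu, nv = self.grid.nu, self.grid.nv
        rows, cols, data = [], [], []
        ridx = np.arange(self.n_points)
        for cp_idx, (i0, j0, au, gv) in enumerate(self._cp_data):
            for dj in (-1, 0, 1):
                j = j0 + dj
                for di in (-1, 0, 1):
                    i = i0 + di
                    valid = (j >= 0) & (j < nv) & (i >= 0) & (i < nu)
                    g = (au[:, di + 1] * gv[:, dj + 1])[valid]
                    rows.append(ridx[valid])
                    cols.append(cp_idx * nv * nu + j[valid] * nu + i[valid])
                    data.append(g)
        mat = sparse.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_points, self.n_cp * nv * nu),
        )
        return mat.tocsr()


def influence_matrix(
    plan: ArcPlan,
    density: VoxelGrid,
    roi_bounding: ROIMask,
    grid: Optional[FluenceGrid] = None,
    ray_step_mm: float = 2.5,
) -> DoseInfluence:
    """Influence of all (control point, beamlet) pairs on voxels of
    *roi_bounding* (typically External); voxels elsewhere receive no dose."""
    if roi_bounding.is_empty:
        raise ValueError("bounding ROI is empty")
    if grid is None:
        grid = fluence_grid_for_target(plan, roi_bounding)
    pts = roi_bounding.geometry.voxel_centers(roi_bounding.mask)
    flat_idx = np.flatnonzero(roi_bounding.mask.ravel())
    return DoseInfluence(plan, density, pts, grid, ray_step_mm,
                         voxel_idx=flat_idx, geometry=roi_bounding.geometry)


def compute_dose(plan: ArcPlan, influence: DoseInfluence, weights: np.ndarray) -> VoxelGrid:
    """Full-grid dose (Gy) for beamlet weights; zero outside the bounding ROI."""
    weights = np.asarray(weights)
    if np.any(weights < 0):
        raise ValueError("beamlet weights must be non-negative")
    if influence.voxel_idx is None or influence.geometry is None:
        raise ValueError("influence was not built on a voxel grid")
    vals = np.zeros(influence.geometry.shape, dtype=np.float64)
    vals.ravel()[influence.voxel_idx] = influence.dose(weights)
    return VoxelGrid(influence.geometry, vals)


def calibrate_output(machine: BeamModel, density: VoxelGrid,
                     isocenter_mm: Sequence[float],
                     gy_per_mu_at_iso: float = 0.01) -> BeamModel:
    """Set the output factor so one MU delivers ``gy_per_mu_at_iso`` Gy on
    the central axis at isocentre depth (gantry 0°)."""
    beam, _, _ = _cp_basis(0.0, 0.0)
    src = np.asarray(isocenter_mm) - machine.sad_mm * beam
    d = radiological_depth(density, src, isocenter_mm)
    out = gy_per_mu_at_iso * math.exp(machine.mu_water_per_cm * d)
    return replace(machine, output_gy_per_mu=out)


def sequence_leaves(
    plan: ArcPlan,
    weights: np.ndarray,
    grid: FluenceGrid,
    threshold_fraction: float = 0.5,
    row_gate_fraction: float = 0.35,
) -> ArcPlan:
    """Convert optimized fluence to one MLC aperture + MU per control point.

    Per leaf pair (fluence row), the aperture is the longest contiguous run
    of beamlets at or above *threshold_fraction* of the row's own maximum
    (concave rows thus open one lobe; neighbouring control points cover the
    other); the control point's MU is the mean in-aperture fluence.  Rows
    whose maximum falls below *row_gate_fraction* of the control point's
    overall maximum stay closed — a single meterset per control point would
    otherwise grossly overdose their weakly-irradiated slabs.  Raises if
    the fluence is zero everywhere.
    """
    weights = np.asarray(weights, dtype=float)
    n_cp, nv, nu = weights.shape
    if n_cp != plan.n_cp:
        raise ValueError("weights do not match the plan's control points")
    if not np.any(weights > 0):
        raise ValueError("all-zero fluence: nothing to sequence")
    u = grid.u_centers()
    half = grid.pitch_mm / 2.0
    new_cps: List[ControlPoint] = []
    for cp, w in zip(plan.control_points, weights):
        left = np.zeros(nv)
        right = np.zeros(nv)
        open_vals: List[float] = []
        cp_max = w.max()
        for j in range(nv):
            row = w[j]
            rmax = row.max()
            if rmax <= 0 or rmax < row_gate_fraction * cp_max:
                continue
            above = row >= threshold_fraction * rmax
            edges = np.diff(np.concatenate(([0], above.astype(int), [0])))
            starts = np.flatnonzero(edges == 1)
            ends = np.flatnonzero(edges == -1)  # exclusive
            k = int(np.argmax(ends - starts))
            i_first, i_last = int(starts[k]), int(ends[k]) - 1
            left[j] = u[i_first] - half
            right[j] = u[i_last] + half
            open_vals.extend(row[i_first:i_last + 1])
        mu = float(np.mean(open_vals)) if open_vals else 0.0
        new_cps.append(ControlPoint(cp.gantry_deg, mu, left, right))
    return ArcPlan(new_cps, plan.collimator_deg, plan.isocenter_mm,
                   plan.prescription_gy, plan.machine)


def aperture_weights(plan: ArcPlan, grid: FluenceGrid) -> np.ndarray:
    """Effective beamlet weights of a sequenced plan: MU over open beamlets.

    Used to recompute the deliverable dose through the same influence."""
    u = grid.u_centers()
    out = np.zeros((plan.n_cp, grid.nv, grid.nu))
    for k, cp in enumerate(plan.control_points):
        if cp.leaf_left_mm.size == 0 or cp.mu == 0:
            continue
        for j in range(min(grid.nv, cp.leaf_left_mm.size)):
            lo, hi = cp.leaf_left_mm[j], cp.leaf_right_mm[j]
            if hi > lo:
                out[k, j, (u > lo) & (u < hi)] = cp.mu
    return out


def rescale_plan_mu(plan: ArcPlan, factor: float) -> ArcPlan:
    cps = [ControlPoint(cp.gantry_deg, cp.mu * factor,
                        cp.leaf_left_mm.copy(), cp.leaf_right_mm.copy())
           for cp in plan.control_points]
    return ArcPlan(cps, plan.collimator_deg, plan.isocenter_mm,
                   plan.prescription_gy, plan.machine)


def recompute_dose_independent(
    plan: ArcPlan,
    density: VoxelGrid,
    weights: np.ndarray,
    grid: FluenceGrid,
    bounding: ROIMask,
    base_influence_step_mm: float = 2.5,
) -> VoxelGrid:
    """Independent dose accumulation for self-QA.

    Recomputes the same plan with the ray-trace step halved on a dose grid
    shifted by half a voxel.  The result is returned on its own (shifted)
    geometry; the gamma comparison resamples it trilinearly onto the
    reference grid during evaluation, so the recomputation is interpolated
    exactly once.  Differences from the primary computation reflect the
    engine's discretisation, not the plan.
    """
    geo = bounding.geometry
    shift = np.asarray(geo.spacing_mm) / 2.0
    pts = geo.voxel_centers(bounding.mask) + shift
    infl = DoseInfluence(plan, density, pts, grid,
                         ray_step_mm=base_influence_step_mm / 2.0)
    shifted = np.zeros(geo.shape, dtype=np.float64)
    shifted.ravel()[np.flatnonzero(bounding.mask.ravel())] = infl.dose(weights)
    shifted_geo = GridGeometry(geo.shape, geo.spacing_mm,
                               tuple(np.asarray(geo.origin_mm) + shift))
    return VoxelGrid(shifted_geo, shifted)


def resample_to(dose: VoxelGrid, geometry: GridGeometry) -> VoxelGrid:
    """Trilinear resampling of a dose grid onto another geometry (zero
    outside the source grid)."""
    idx = np.stack(np.meshgrid(*(np.arange(n, dtype=float) for n in geometry.shape),
                               indexing="ij"), axis=0)
    world = (np.asarray(geometry.origin_mm)[:, None, None, None]
             + idx * np.asarray(geometry.spacing_mm)[:, None, None, None])
    src_idx = ((world - np.asarray(dose.origin_mm)[:, None, None, None])
               / np.asarray(dose.spacing_mm)[:, None, None, None])
    vals = map_coordinates(dose.values, src_idx, order=1, cval=0.0)
    return VoxelGrid(geometry, vals)
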