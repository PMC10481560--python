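"""Seeded synthetic pelvic phantom: density grid plus structure set.

The phantom emulates the anatomy the auto-planner assumes for locally
advanced rectal cancer: an elliptical water-equivalent body on air, a large
concave initial target volume wrapping posteriorly around an anterior
bladder / small-bowel compartment, a smaller interior boost target, a full
bladder abutting (optionally overlapping) the target anteriorly, small bowel
anterior–superior, and two lateral femoral heads.

Construction is purely geometric (parameterised superellipsoids with a
small seeded perturbation); the target's horseshoe concavity is realised by
carving an anterior "bowel compartment" lobe out of the gross tumour region
before the clinical (CTV) and setup (PTV) margins are applied.  Densities
are relative electron density (water = 1.0, air = 0.0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .grid import GridGeometry, ROIMask, StructureSet, VoxelGrid
from .structures import Margins, boolean_op, erode_voxels, expand_mask

# fixed world extents (mm) of the phantom grid along (RL, AP, CC); the grid
# is centred at x=z=0 with extra posterior room for the virtual couch
_EXTENT_MM = (210.0, 190.0, 170.0)
_BODY_CENTER = (0.0, -15.0, 0.0)

# margin prescription: 5 mm AP/RL and 20 mm CC for the CTV, then 5 mm
# isotropic for the PTV
CTV_MARGINS = Margins(anterior_mm=5.0, posterior_mm=5.0, left_mm=5.0,
                      right_mm=5.0, cranial_mm=20.0, caudal_mm=20.0)
PTV_MARGIN_MM = 5.0


class InfeasibleGeometryError(ValueError):
    """An organ would exceed the body outline."""


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of a synthetic phantom (pure function input).

    ``target_scale`` scales the gross tumour region's linear dimensions by
    ``target_scale ** (1/3)`` so the target volume scales linearly;
    ``oar_overlap_fraction`` slides the bladder posteriorly toward/into the
    anterior face of the target (0 = guaranteed disjoint).
    """

    seed: int = 42
    spacing_mm: Tuple[float, float, float] = (2.5, 2.5, 2.5)
    body_semiaxes_mm: Tuple[float, float, float] = (92.0, 55.0, 85.0)
    tumor_center_offset_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_scale: float = 1.0
    oar_overlap_fraction: float = 0.4

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.target_scale <= 0:
            raise ValueError("target_scale must be positive")
        if not 0.0 <= self.oar_overlap_fraction <= 1.0:
            raise ValueError("oar_overlap_fraction must lie in [0, 1]")

    def geometry(self) -> GridGeometry:
        shape = tuple(int(np.ceil(e / s)) for e, s in zip(_EXTENT_MM, self.spacing_mm))
        return GridGeometry.centered(shape, self.spacing_mm)


@dataclass(frozen=True)
class CouchConfig:
    thickness_mm: float = 50.0
    density: float = 0.3
    gap_mm: float = 5.0


def _superellipsoid(coords, center, semiaxes, exponents) -> np.ndarray:
    """Boolean mask of sum_i |(u_i-c_i)/a_i|^{p_i} <= 1 on the coord grid."""
    x, y, z = coords
    total = np.zeros(np.broadcast_shapes(x.shape, y.shape, z.shape))
    for u, c, a, p in zip((x, y, z), center, semiaxes, exponents):
        total = total + np.abs((u - c) / a) ** p
    return total <= 1.0


def _grid_coords(geom: GridGeometry):
    xs = geom.axis_coords(0)[:, None, None]
    ys = geom.axis_coords(1)[None, :, None]
    zs = geom.axis_coords(2)[None, None, :]
    return xs, ys, zs


def build_targets(
    gtv: ROIMask,
    node_masks: list,
    external: ROIMask,
    ctv_margins: Margins = CTV_MARGINS,
    ptv_margin_mm: float = PTV_MARGIN_MM,
    ptv_name: str = "PTV",
) -> StructureSet:
    """Derive CTV and PTV from a gross tumour volume.

    CTV = (gtv expanded by the anisotropic clinical margin) ∪ unexpanded
    nodal masks; PTV = CTV expanded isotropically by the setup margin; both
    clipped to the body outline.  Returns a structure set holding ``CTV``
    and *ptv_name*.
    """
    if gtv.is_empty:
        raise ValueError("GTV is empty")
    inner = erode_voxels(external, 1)
    ctv = expand_mask(gtv, ctv_margins, name="CTV")
    for node in node_masks:
        ctv = boolean_op(ctv, node, "union", name="CTV")
    ctv = ctv.with_mask(ctv.mask & inner.mask, name="CTV")
    ptv = expand_mask(ctv, Margins.isotropic(ptv_margin_mm), name=ptv_name)
    ptv = ptv.with_mask(ptv.mask & inner.mask, name=ptv_name)
    out = StructureSet(gtv.geometry)
    out.add(ctv)
    out.add(ptv)
    return out


def generate_phantom(
    spec: PhantomSpec, include_intermediates: bool = False
) -> Tuple[VoxelGrid, StructureSet]:
    """Deterministically generate the phantom for *spec*.

    Returns a water-equivalent body (1.0) on air (0.0) and a structure set
    with exactly the canonical ROI names (plus ``z_GTV_core`` /
    ``z_CTV_initial`` when *include_intermediates* is set).
    """
    geom = spec.geometry()
    coords = _grid_coords(geom)
    rng = np.random.default_rng(spec.seed)

    def jitter_center(c):
        return tuple(np.asarray(c) + np.clip(rng.normal(0.0, 1.5, 3), -3.0, 3.0))

    def jitter_semi(a):
        return tuple(np.asarray(a) * np.clip(rng.normal(1.0, 0.02, 3), 0.95, 1.05))

    a, b, c = spec.body_semiaxes_mm
    body = _superellipsoid(coords, _BODY_CENTER, (a, b, c), (2, 2, 8))
    external = ROIMask("External", geom, body)
    inner = erode_voxels(external, 1)

    # anterior bladder/bowel compartment, extruded in CC; the target region
    # is carved away from it (with enough clearance that the CTV and PTV
    # margins cannot re-enter it), which produces the horseshoe concavity
    comp_center = (0.0, -26.0)
    comp_semi = (32.0, 30.0)
    carve_mm = 12.5  # > 5 (CTV in-plane) + 5 (PTV), so PTV stays out
    xs, ys, _ = coords
    comp2d = ((xs - comp_center[0]) / comp_semi[0]) ** 2 + (
        (ys - comp_center[1]) / comp_semi[1]
    ) ** 2 <= 1.0
    carve2d = ((xs - comp_center[0]) / (comp_semi[0] + carve_mm)) ** 2 + (
        (ys - comp_center[1]) / (comp_semi[1] + carve_mm)
    ) ** 2 <= 1.0
    comp = np.broadcast_to(comp2d, geom.shape)
    carve = np.broadcast_to(carve2d, geom.shape)

    u = spec.target_scale ** (1.0 / 3.0)
    gtv_center = tuple(
        np.asarray((0.0, 10.0, 0.0)) + np.asarray(spec.tumor_center_offset_mm)
        + np.clip(rng.normal(0.0, 1.5, 3), -3.0, 3.0)
    )
    gtv_semi = jitter_semi((52.0 * u, 50.0 * u, 46.0 * u))
    # exponent 4 widens the lateral horns that wrap the compartment
    gtv_region = _superellipsoid(coords, gtv_center, gtv_semi, (4, 4, 4))
    gtv_region &= ~carve
    gtv_region &= inner.mask
    gtv0 = ROIMask("z_GTV_region", geom, gtv_region, derived=True)
    if gtv0.is_empty:
        raise InfeasibleGeometryError("gross tumour region lies outside the body")

    targets = build_targets(gtv0, [], external, ptv_name="PTV_initial")
    ctv = targets["CTV"]
    ptv_initial = targets["PTV_initial"]

    gtv_boost_center = jitter_center((0.0, 18.0, -6.0))
    gtv_boost_semi = jitter_semi((30.0 * u, 22.0 * u, 24.0 * u))
    gtv_boost = _superellipsoid(coords, gtv_boost_center, gtv_boost_semi, (2, 2, 2))
    gtv_boost &= gtv0.mask  # tumour core stays inside the gross region
    core = ROIMask("z_GTV_core", geom, gtv_boost, derived=True)
    if core.is_empty:
        raise InfeasibleGeometryError("boost tumour core lies outside the gross region")
    boost_targets = build_targets(core, [], external, ptv_name="PTV_boost")
    ptv_boost = boost_targets["PTV_boost"].with_mask(
        boost_targets["PTV_boost"].mask & ptv_initial.mask, name="PTV_boost"
    )

    bladder_shift = 40.0 * spec.oar_overlap_fraction
    bladder_center = jitter_center((0.0, -30.0 + bladder_shift, -10.0))
    bladder_semi = jitter_semi((30.0, 26.0, 36.0))
    bladder = _superellipsoid(coords, bladder_center, bladder_semi, (2, 2, 2))
    if spec.oar_overlap_fraction == 0.0:
        bladder &= comp  # compartment containment guarantees disjointness from PTV

    bowel_center = jitter_center((0.0, -30.0, 40.0))
    bowel_semi = jitter_semi((46.0, 26.0, 30.0))
    bowel = _superellipsoid(coords, bowel_center, bowel_semi, (2, 2, 2))
    bowel &= ~bladder

    # femoral heads abut the lateral PTV but stay clear of it: as for real
    # nodal targets (which pass medial to the hips) a small avoidance gap is
    # enforced by carving the expanded target out of the spheres
    fem_r = 21.0
    fem_gap = expand_mask(ptv_initial, Margins.isotropic(4.0)).mask
    fem_l = _superellipsoid(coords, jitter_center((64.0, -16.0, -18.0)),
                            jitter_semi((fem_r, fem_r, fem_r)), (2, 2, 2))
    fem_rgt = _superellipsoid(coords, jitter_center((-64.0, -16.0, -18.0)),
                              jitter_semi((fem_r, fem_r, fem_r)), (2, 2, 2))
    fem_l &= ~fem_gap
    fem_rgt &= ~fem_gap

    structs = StructureSet(geom)
    structs.add(external)
    structs.add(ptv_initial)
    structs.add(ptv_boost)
    for name, mask in (
        ("Bladder", bladder),
        ("SmallBowel", bowel),
        ("FemoralHead_L", fem_l),
        ("FemoralHead_R", fem_rgt),
    ):
        roi = ROIMask(name, geom, mask)
        if roi.is_empty:
            raise InfeasibleGeometryError(f"{name} lies outside the grid")
        if (roi.mask & ~inner.mask).any():
            raise InfeasibleGeometryError(f"{name} would exceed the body outline")
        structs.add(roi)

    if include_intermediates:
        structs.add(core)
        structs.add(ctv.with_mask(ctv.mask, name="z_CTV_initial", derived=True))

    density = VoxelGrid(geom, body.astype(np.float32))
    return density, structs


def insert_virtual_couch(
    density: VoxelGrid, config: CouchConfig = CouchConfig()
) -> VoxelGrid:
    """Add a posterior carbon-fibre-like slab to the density grid.

    The slab spans the full RL/CC extent, starts ``gap_mm`` behind the
    posterior-most body voxel and is ``thickness_mm`` thick.  Voxels inside
    the body are untouched; zero thickness returns an identical copy.
    """
    if config.thickness_mm == 0:
        return density.copy()
    body = density.values > 0
    if not body.any():
        raise ValueError("density grid contains no body")
    jmax = int(np.max(np.nonzero(body.any(axis=(0, 2)))[0]))
    sy = density.spacing_mm[1]
    j0 = jmax + 1 + int(np.round(config.gap_mm / sy))
    j1 = j0 + int(np.round(config.thickness_mm / sy))
    if j1 > density.shape[1]:
        raise ValueError("virtual couch does not fit posterior to the body")
    slab = np.zeros(density.shape, dtype=bool)
    slab[:, j0:j1, :] = True
    if (slab & body).any():
        raise ValueError("virtual couch would overlap the body")
    out = density.values.copy()
    out[slab] = config.density
    return density.with_values(out)
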