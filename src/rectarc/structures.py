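"""ROI mask algebra: anisotropic margin expansion, boolean operations and
automatic derivation of the optimization helper structures.

Margin semantics
----------------
A margin is given per patient direction (anterior/posterior, left/right,
cranial/caudal).  A voxel belongs to the expanded mask iff its centre lies
within the *anisotropically scaled* Euclidean distance of some source voxel
centre: with displacement Δ = target − source (mm) and the margin m_i picked
per axis by the sign of Δ_i,

    sum_i (Δ_i / m_i)^2  <=  1        (Δ_i = 0 contributes 0; m_i = 0 forces Δ_i = 0)

This is dilation by a piecewise-ellipsoidal structuring element — the
observable behaviour of treatment-planning-system margin tools.  It is
realised by an exact binary convolution with the explicit structuring
element (FFT), which matches a brute-force distance scan voxel for voxel.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.signal import fftconvolve

from .grid import (
    EmptyMaskError,
    ROIMask,
    StructureSet,
    _require_same_geometry,
)

# canonical ROI names the planner expects from contouring
CANONICAL_ROI_NAMES: List[str] = [
    "External",
    "PTV_initial",
    "PTV_boost",
    "Bladder",
    "SmallBowel",
    "FemoralHead_L",
    "FemoralHead_R",
]

# names of derived optimization helper structures ("z_" mirrors
# planner-generated helper ROIs)
BLADDER_OPT = "z_Bladder_opt"
SMALLBOWEL_OPT = "z_SmallBowel_opt"
ANTERIOR_SHELL = "z_AnteriorShell"
NORMAL_TISSUE = "z_NormalTissue"


@dataclass(frozen=True)
class Margins:
    """Per-direction expansion margins in mm (all >= 0).

    Directions follow the package axis convention: left/right along RL,
    anterior/posterior along AP (+AP = posterior), cranial/caudal along CC.
    """

    anterior_mm: float = 0.0
    posterior_mm: float = 0.0
    left_mm: float = 0.0
    right_mm: float = 0.0
    cranial_mm: float = 0.0
    caudal_mm: float = 0.0

    def __post_init__(self) -> None:
        for f, v in self.__dict__.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"margin {f} must be finite and >= 0, got {v}")

    @classmethod
    def isotropic(cls, mm: float) -> "Margins":
        return cls(mm, mm, mm, mm, mm, mm)

    # margins per (array axis, sign of displacement): axis 0 +x = left,
    # axis 1 +y = posterior, axis 2 +z = cranial
    def for_axis_sign(self, axis: int, positive: bool) -> float:
        table = (
            (self.right_mm, self.left_mm),
            (self.anterior_mm, self.posterior_mm),
            (self.caudal_mm, self.cranial_mm),
        )
        return table[axis][1 if positive else 0]

    @property
    def max_mm(self) -> float:
        return max(self.__dict__.values())


def structuring_element(margins: Margins, spacing_mm: Sequence[float]) -> np.ndarray:
    """Explicit boolean structuring element for the margin inequality.

    Centred, odd-sized along each axis; entry (i,j,k) is True iff the voxel
    offset lies inside the per-direction scaled ellipsoid.
    """
    half = [
        int(np.floor(max(margins.for_axis_sign(ax, True),
                         margins.for_axis_sign(ax, False)) / spacing_mm[ax] + 1e-9))
        for ax in range(3)
    ]
    offs = [np.arange(-h, h + 1) * spacing_mm[ax] for ax, h in enumerate(half)]
    dx, dy, dz = np.meshgrid(*offs, indexing="ij")
    total = np.zeros(dx.shape)
    for ax, d in enumerate((dx, dy, dz)):
        m_pos = margins.for_axis_sign(ax, True)
        m_neg = margins.for_axis_sign(ax, False)
        term = np.zeros_like(d)
        pos = d > 0
        neg = d < 0
        term[pos] = (d[pos] / m_pos) ** 2 if m_pos > 0 else np.inf
        term[neg] = (d[neg] / m_neg) ** 2 if m_neg > 0 else np.inf
        total = total + term
    return total <= 1.0 + 1e-9


def expand_mask(mask: ROIMask, margins: Margins, name: Optional[str] = None) -> ROIMask:
    """Anisotropic per-direction Euclidean expansion of an ROI.

    Extensive (result ⊇ input) and monotone in every margin.  Raises
    :class:`EmptyMaskError` for an empty input.
    """
    if mask.is_empty:
        raise EmptyMaskError(f"cannot expand empty ROI '{mask.name}'")
    se = structuring_element(margins, mask.geometry.spacing_mm)
    if se.size == 1:
        out = mask.mask.copy()
    else:
        conv = fftconvolve(mask.mask.astype(np.float64), se.astype(np.float64), mode="same")
        out = conv > 0.5
        out |= mask.mask  # guard against FFT rounding ever dropping a source voxel
    return mask.with_mask(out, name=name or f"{mask.name}_expanded")


def boolean_op(a: ROIMask, b: ROIMask, op: str, name: Optional[str] = None) -> ROIMask:
    """Voxelwise union / intersection / difference of two ROIs on one grid."""
    _require_same_geometry(a.geometry, b.geometry, f"boolean_op({a.name}, {b.name})")
    if op == "union":
        out, sym = a.mask | b.mask, "|"
    elif op == "intersection":
        out, sym = a.mask & b.mask, "&"
    elif op == "difference":
        out, sym = a.mask & ~b.mask, "-"
    else:
        raise ValueError(f"unknown boolean op '{op}'")
    return ROIMask(name or f"({a.name}{sym}{b.name})", a.geometry, out,
                   derived=a.derived or b.derived)


def volume_cc(mask: ROIMask) -> float:
    """Volume in cm³ = voxel count × voxel volume."""
    return mask.volume_cc()


def centroid_mm(mask: ROIMask) -> np.ndarray:
    """Mean of set voxel centres, in mm."""
    return mask.centroid_mm()


@dataclass
class RoiNameReport:
    ok: bool
    missing: List[str]
    extra: List[str]
    duplicates: List[str]
    suggestions: Dict[str, str]


def check_roi_names(names: Iterable[str] | StructureSet) -> RoiNameReport:
    """Check contoured ROI names against the canonical planning schema.

    Report-only: lists missing and unrecognised names (with a nearest-name
    suggestion) and duplicates.  ``ok`` requires every canonical name present
    exactly once; extra names do not fail the check but are listed.
    """
    if isinstance(names, StructureSet):
        names = names.names
    names = list(names)
    canonical = set(CANONICAL_ROI_NAMES)
    seen: Dict[str, int] = {}
    for n in names:
        seen[n] = seen.get(n, 0) + 1
    missing = [n for n in CANONICAL_ROI_NAMES if n not in seen]
    extra = [n for n in names if n not in canonical]
    duplicates = sorted(n for n, c in seen.items() if c > 1)
    suggestions = {}
    for n in extra:
        close = difflib.get_close_matches(n, CANONICAL_ROI_NAMES, n=1, cutoff=0.6)
        if close:
            suggestions[n] = close[0]
    ok = not missing and not duplicates
    return RoiNameReport(ok, missing, extra, duplicates, suggestions)


@dataclass(frozen=True)
class DerivedRoiConfig:
    """Parameters of the automatically derived optimization structures.

    ``anterior_mm``/``gap_mm`` shape the abdominal-direction control shell
    (a bowel-bag-like structure anterior to the PTV); ``normal_ring_mm``
    bounds the general normal-tissue fall-off ring around the PTV.
    """

    anterior_mm: float = 30.0
    gap_mm: float = 3.0
    normal_ring_mm: float = 40.0
    normal_gap_mm: float = 2.0


def derive_optimization_rois(
    structs: StructureSet,
    config: DerivedRoiConfig = DerivedRoiConfig(),
    ptv_name: str = "PTV_initial",
) -> StructureSet:
    """Add the planner's derived optimization ROIs to a structure set.

    * ``z_Bladder_opt``    = Bladder − PTV
    * ``z_SmallBowel_opt`` = SmallBowel − PTV
    * ``z_AnteriorShell``  = (PTV ⊕ anterior margin) − (PTV ⊕ isotropic gap),
      clipped to External — the abdominal-direction dose-shape control
      structure ("bowel bag"-like);
    * ``z_NormalTissue``   = (PTV ⊕ ring) − (PTV ⊕ small gap), clipped to
      External — general conformity / fall-off ring.

    All additions carry ``derived=True``.  Missing canonical ROIs raise a
    KeyError naming the first absent structure.
    """
    for required in ("External", ptv_name, "Bladder", "SmallBowel"):
        if required not in structs:
            raise KeyError(f"missing canonical ROI '{required}'")
    out = structs.copy()
    ptv = structs[ptv_name]
    external = structs["External"]

    bl = boolean_op(structs["Bladder"], ptv, "difference", name=BLADDER_OPT)
    sb = boolean_op(structs["SmallBowel"], ptv, "difference", name=SMALLBOWEL_OPT)

    ant = expand_mask(ptv, Margins(anterior_mm=config.anterior_mm))
    gap = expand_mask(ptv, Margins.isotropic(config.gap_mm))
    shell = ant.mask & ~gap.mask & external.mask
    shell_roi = ROIMask(ANTERIOR_SHELL, structs.geometry, shell, derived=True)

    ring_out = expand_mask(ptv, Margins.isotropic(config.normal_ring_mm))
    ring_in = expand_mask(ptv, Margins.isotropic(config.normal_gap_mm))
    ring = ring_out.mask & ~ring_in.mask & external.mask
    ring_roi = ROIMask(NORMAL_TISSUE, structs.geometry, ring, derived=True)

    for roi in (bl, sb, shell_roi, ring_roi):
        roi.derived = True
        out.add(roi, replace=True)
    return out


def erode_voxels(mask: ROIMask, n: int = 1, name: Optional[str] = None) -> ROIMask:
    """Erode by n voxels (6-connected); helper for "strictly inside" clipping."""
    out = binary_erosion(mask.mask, iterations=n) if n > 0 else mask.mask.copy()
    return mask.with_mask(out, name=name or mask.name)
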