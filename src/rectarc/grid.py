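"""Voxel grids, ROI masks and structure sets.

Coordinate convention, used everywhere in this package and documented only
here:

* array axis 0 — RL, +x points to the patient's **left**;
* array axis 1 — AP, +y points **posterior** (toward the couch);
* array axis 2 — CC, +z points **cranial**.

World coordinates are millimetres at voxel centres::

    world = origin_mm + index * spacing_mm

Grids are axis-aligned; there is no direction matrix beyond the diagonal
spacing.  All volumes are reported in cm³ (cc).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

#: canonical patient-axis labels in array-axis order
AXES: Tuple[str, str, str] = ("RL", "AP", "CC")


class GridMismatchError(ValueError):
    """Two objects that must share one grid geometry do not."""


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and origin of an axis-aligned voxel grid."""

    shape: Tuple[int, int, int]
    spacing_mm: Tuple[float, float, float]
    origin_mm: Tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError("grid must be 3-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @classmethod
    def centered(
        cls,
        shape: Sequence[int],
        spacing_mm: Sequence[float],
        center_mm: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "GridGeometry":
        """Geometry whose voxel-centre bounding box is centred on *center_mm*."""
        shape = tuple(int(s) for s in shape)
        spacing = tuple(float(s) for s in spacing_mm)
        origin = tuple(
            c - 0.5 * (n - 1) * s for c, n, s in zip(center_mm, shape, spacing)
        )
        return cls(shape, spacing, origin)

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one array axis."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.shape[axis])

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points (mm)."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def voxel_centers(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """(N, 3) world coordinates of all (or masked) voxel centres."""
        if mask is None:
            idx = np.stack(
                np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"), axis=-1
            ).reshape(-1, 3)
        else:
            idx = np.argwhere(mask)
        return self.index_to_world(idx)

    def matches(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
        )


def _require_same_geometry(a: GridGeometry, b: GridGeometry, what: str) -> None:
    if not a.matches(b):
        raise GridMismatchError(f"{what}: grid geometries differ ({a} vs {b})")


@dataclass
class VoxelGrid:
    """A scalar field (relative electron density, or dose in Gy) on a grid."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )

    @classmethod
    def zeros(cls, geometry: GridGeometry, dtype=np.float32) -> "VoxelGrid":
        return cls(geometry, np.zeros(geometry.shape, dtype=dtype))

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(self.geometry, values)

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.geometry, self.values.copy())

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.geometry.shape

    @property
    def spacing_mm(self) -> Tuple[float, float, float]:
        return self.geometry.spacing_mm

    @property
    def origin_mm(self) -> Tuple[float, float, float]:
        return self.geometry.origin_mm


class EmptyMaskError(ValueError):
    """An operation that requires a non-empty ROI received an empty one."""


@dataclass
class ROIMask:
    """A named binary region of interest sharing a grid geometry.

    ``derived=True`` marks planner-generated helper structures (their names
    carry a ``z_`` prefix by convention).
    """

    name: str
    geometry: GridGeometry
    mask: np.ndarray
    derived: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    def volume_cc(self) -> float:
        if self.is_empty:
            raise EmptyMaskError(f"ROI '{self.name}' is empty")
        return self.count * self.geometry.voxel_volume_cc

    def centroid_mm(self) -> np.ndarray:
        if self.is_empty:
            raise EmptyMaskError(f"ROI '{self.name}' is empty")
        idx = np.argwhere(self.mask)
        return self.geometry.index_to_world(idx.mean(axis=0))

    def with_mask(self, mask: np.ndarray, name: Optional[str] = None,
                  derived: Optional[bool] = None) -> "ROIMask":
        return ROIMask(
            name if name is not None else self.name,
            self.geometry,
            mask,
            self.derived if derived is None else derived,
        )


class StructureSet:
    """An ordered collection of ROI masks on one grid."""

    def __init__(self, geometry: GridGeometry):
        self.geometry = geometry
        self._rois: Dict[str, ROIMask] = {}

    def add(self, roi: ROIMask, replace: bool = False) -> None:
        _require_same_geometry(self.geometry, roi.geometry, f"add ROI '{roi.name}'")
        if roi.name in self._rois and not replace:
            raise ValueError(f"ROI '{roi.name}' already present")
        self._rois[roi.name] = roi

    def __getitem__(self, name: str) -> ROIMask:
        try:
            return self._rois[name]
        except KeyError:
            raise KeyError(f"ROI '{name}' not in structure set "
                           f"(have: {', '.join(self._rois)})") from None

    def __contains__(self, name: str) -> bool:
        return name in self._rois

    def __iter__(self) -> Iterator[ROIMask]:
        return iter(self._rois.values())

    def __len__(self) -> int:
        return len(self._rois)

    @property
    def names(self) -> List[str]:
        return list(self._rois)

    def copy(self) -> "StructureSet":
        out = StructureSet(self.geometry)
        for roi in self:
            out.add(ROIMask(roi.name, roi.geometry, roi.mask.copy(), roi.derived))
        return out
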