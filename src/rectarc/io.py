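"""File I/O: NRRD volumes, structure-set label maps, goal and config JSON.

Volumes are written as NRRD (detached nothing, raw little-endian encoding,
diagonal space directions) — self-describing and desk-friendly.  A structure
set is stored as one unsigned-integer NRRD in which each ROI occupies one
bit (ROIs may overlap: the boost target sits inside the initial target, the
bladder may overlap it), with a JSON side-car mapping names to bit labels.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .grid import GridGeometry, ROIMask, StructureSet, VoxelGrid
from .metrics import ClinicalGoal

_NRRD_MAGIC = "NRRD0004"
_DTYPES = {
    "float": np.float32, "float32": np.float32, "double": np.float64,
    "float64": np.float64, "uint8": np.uint8, "uint16": np.uint16,
    "uint32": np.uint32, "int16": np.int16, "int32": np.int32,
}
_TYPE_NAMES = {np.dtype(np.float32): "float", np.dtype(np.float64): "double",
               np.dtype(np.uint8): "uint8", np.dtype(np.uint16): "uint16",
               np.dtype(np.uint32): "uint32", np.dtype(np.int16): "int16",
               np.dtype(np.int32): "int32"}


class NrrdError(ValueError):
    pass


def write_volume(grid: VoxelGrid, path: Union[str, Path]) -> None:
    """Write a 3-D scalar grid as raw little-endian NRRD."""
    path = Path(path)
    arr = np.asarray(grid.values)
    dtype = arr.dtype if np.dtype(arr.dtype) in _TYPE_NAMES else np.float32
    arr = np.ascontiguousarray(arr.astype(dtype))
    sx, sy, sz = grid.spacing_mm
    ox, oy, oz = grid.origin_mm
    header = [
        _NRRD_MAGIC,
        f"type: {_TYPE_NAMES[np.dtype(dtype)]}",
        "dimension: 3",
        f"sizes: {arr.shape[0]} {arr.shape[1]} {arr.shape[2]}",
        "space: left-posterior-superior",
        f"space directions: ({sx!r},0,0) (0,{sy!r},0) (0,0,{sz!r})",
        f"space origin: ({ox!r},{oy!r},{oz!r})",
        "kinds: domain domain domain",
        "endian: little",
        "encoding: raw",
    ]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n\n").encode("ascii"))
        # NRRD raw data: first listed axis fastest
        fh.write(arr.ravel(order="F").astype(dtype.newbyteorder("<") if
                                             np.dtype(dtype).byteorder == ">"
                                             else dtype).tobytes())


def _parse_vector(text: str) -> Tuple[float, ...]:
    return tuple(float(t) for t in text.strip().lstrip("(").rstrip(")").split(","))


def read_volume(path: Union[str, Path]) -> VoxelGrid:
    """Read a 3-D raw-encoded NRRD volume written by :func:`write_volume`
    (or any compatible axis-aligned file)."""
    path = Path(path)
    with open(path, "rb") as fh:
        data = fh.read()
    head_end = data.find(b"\n\n")
    if head_end < 0:
        raise NrrdError(f"{path}: no header/data separator found")
    lines = data[:head_end].decode("ascii", errors="replace").splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise NrrdError(f"{path}: not an NRRD file")
    fields: Dict[str, str] = {}
    for line in lines[1:]:
        if line.startswith("#") or not line.strip():
            continue
        key, _, val = line.partition(":")
        fields[key.strip().lower()] = val.strip()
    try:
        dim = int(fields["dimension"])
    except KeyError:
        raise NrrdError(f"{path}: missing 'dimension' field") from None
    if dim != 3:
        raise NrrdError(f"{path}: expected 3-D data, got dimension {dim}")
    if fields.get("encoding", "raw") != "raw":
        raise NrrdError(f"{path}: unsupported encoding '{fields.get('encoding')}'")
    if fields.get("endian", "little") != "little":
        raise NrrdError(f"{path}: unsupported endian '{fields.get('endian')}'")
    try:
        dtype = _DTYPES[fields["type"]]
    except KeyError:
        raise NrrdError(f"{path}: unsupported type '{fields.get('type')}'") from None
    sizes = tuple(int(t) for t in fields["sizes"].split())
    if len(sizes) != 3:
        raise NrrdError(f"{path}: 'sizes' must have 3 entries")
    dirs = [_parse_vector(t) for t in fields["space directions"].split(") ")]
    spacing = []
    for ax, vec in enumerate(dirs):
        for other in range(3):
            if other != ax and abs(vec[other]) > 1e-9:
                raise NrrdError(f"{path}: non-axis-aligned space directions")
        spacing.append(vec[ax])
    origin = _parse_vector(fields.get("space origin", "(0,0,0)"))
    raw = np.frombuffer(data[head_end + 2:], dtype=np.dtype(dtype).newbyteorder("<"))
    expected = sizes[0] * sizes[1] * sizes[2]
    if raw.size != expected:
        raise NrrdError(f"{path}: data length {raw.size} != sizes product {expected}")
    arr = raw.reshape(sizes, order="F")
    geom = GridGeometry(sizes, tuple(spacing), tuple(origin))
    return VoxelGrid(geom, np.ascontiguousarray(arr))


# ---------------------------------------------------------------------------
# Structure sets
# ---------------------------------------------------------------------------

def write_structures(structs: StructureSet, nrrd_path: Union[str, Path],
                     json_path: Union[str, Path]) -> None:
    """Write a structure set as a bit-labelled uint32 NRRD + JSON name table."""
    if len(structs) > 32:
        raise ValueError("bit-label map supports at most 32 ROIs")
    labels = np.zeros(structs.geometry.shape, dtype=np.uint32)
    table = []
    for bit, roi in enumerate(structs):
        labels |= np.uint32(1 << bit) * roi.mask.astype(np.uint32)
        table.append({"name": roi.name, "bit": bit, "derived": roi.derived})
    write_volume(VoxelGrid(structs.geometry, labels), nrrd_path)
    with open(json_path, "w") as fh:
        json.dump({"encoding": "bitmask", "rois": table}, fh, indent=1)


def read_structures(nrrd_path: Union[str, Path],
                    json_path: Union[str, Path]) -> StructureSet:
    vol = read_volume(nrrd_path)
    labels = vol.values.astype(np.uint32)
    with open(json_path) as fh:
        meta = json.load(fh)
    out = StructureSet(vol.geometry)
    for entry in meta["rois"]:
        mask = (labels >> np.uint32(entry["bit"])) & np.uint32(1) > 0
        out.add(ROIMask(entry["name"], vol.geometry, mask,
                        derived=bool(entry.get("derived", False))))
    return out


# ---------------------------------------------------------------------------
# Clinical goals
# ---------------------------------------------------------------------------

def read_goals(path: Union[str, Path]) -> List[ClinicalGoal]:
    """Read a clinical-goal list from JSON; raises citing the offending goal."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    if isinstance(raw, dict):
        raw = raw.get("goals", raw)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: goal file must hold a list of goals")
    goals = []
    for i, entry in enumerate(raw):
        try:
            goals.append(ClinicalGoal(
                roi=entry["roi"], metric=entry["metric"],
                parameter=float(entry.get("parameter", 0.0)),
                comparator=entry["comparator"], threshold=float(entry["threshold"]),
                unit=entry["unit"], scope=entry.get("scope", "plan_sum"),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: goal #{i} ({entry!r}): {exc}") from exc
    return goals


def write_goals(goals: Sequence[ClinicalGoal], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(g) for g in goals], fh, indent=1)


def default_goals_path() -> Path:
    """The packaged clinical-goal list (coverage, near-max dose and the
    small-bowel / bladder / femoral-head volume limits)."""
    return Path(__file__).parent / "data" / "goals_default.json"


def default_goals() -> List[ClinicalGoal]:
    return read_goals(default_goals_path())
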