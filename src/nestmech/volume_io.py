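"""Volumetric image and mesh I/O with explicit spacing metadata.

Everything downstream works in a single axis convention, fixed once for the
whole package:

* axis 0 — U-D (up-down; gravity acts toward decreasing axis-0 coordinate),
* axis 1 — B-F (back-front; the wall/anchor plane sits at the axis-1 = 0 face),
* axis 2 — R-L (right-left).

Voxels are 0-based and the physical center of voxel ``(i, j, k)`` is
``((i+0.5), (j+0.5), (k+0.5)) * spacing``.  The canonical internal unit is
millimetres, which combines with Newtons and MPa into a consistent unit
system for the finite-element stage.

Supported formats: multipage TIFF and numbered TIFF/BMP slice stacks (read),
multipage TIFF and slice stacks (write), MetaImage ``.mhd/.raw`` via
SimpleITK, legacy ASCII VTK unstructured grids and an Abaqus ``.inp`` subset
(nodes, C3D8 hexahedra, node sets) for meshes.  Spacing travels in a YAML
sidecar for formats whose headers cannot carry it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
import yaml

AXES = ("U-D", "B-F", "R-L")

_AXIS_ALIASES = {
    "u-d": 0, "ud": 0, "0": 0,
    "b-f": 1, "bf": 1, "1": 1,
    "r-l": 2, "rl": 2, "2": 2,
}

_UNIT_TO_MM = {"mm": 1.0, "um": 1e-3, "μm": 1e-3, "micron": 1e-3, "m": 1e3}


def axis_index(axis) -> int:
    """Resolve an axis id (``'B-F'``, ``'bf'``, ``1``, ...) to an array axis."""
    if isinstance(axis, (int, np.integer)):
        if axis in (0, 1, 2):
            return int(axis)
        raise ValueError(f"axis index out of range: {axis}")
    key = str(axis).strip().lower()
    if key in _AXIS_ALIASES:
        return _AXIS_ALIASES[key]
    raise ValueError(f"unknown axis id: {axis!r} (expected one of {AXES})")


def spacing_to_mm(value: float, unit: str = "mm") -> float:
    """Convert a spacing given in ``unit`` (mm, um, m) to millimetres."""
    u = unit.strip().lower()
    if u not in _UNIT_TO_MM:
        raise ValueError(f"unknown spacing unit {unit!r}")
    return float(value) * _UNIT_TO_MM[u]


class VolumeError(ValueError):
    """Raised for malformed volumes or unreadable/unsupported volume files."""


def _check_geometry(data: np.ndarray, spacing: float) -> None:
    if data.ndim != 3:
        raise VolumeError(f"expected a 3D array, got shape {data.shape}")
    if min(data.shape) < 1:
        raise VolumeError(f"degenerate volume shape {data.shape}")
    if not (np.isfinite(spacing) and spacing > 0):
        raise VolumeError(f"spacing must be a positive finite length, got {spacing}")


@dataclass
class VoxelVolume:
    """Grayscale 3D image with 8-bit semantics and isotropic spacing (mm)."""

    data: np.ndarray
    spacing: float
    axes: tuple = AXES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        _check_geometry(self.data, self.spacing)
        if self.data.dtype != np.uint8:
            if not np.isfinite(self.data).all():
                raise VolumeError("volume intensities must be finite")
            if self.data.min() < 0 or self.data.max() > 255:
                raise VolumeError("intensities outside 8-bit range [0, 255]")
            self.data = self.data.astype(np.uint8)
        self.spacing = float(self.spacing)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class MaskVolume:
    """Binary material mask sharing the grid of its parent volume."""

    data: np.ndarray
    spacing: float
    axes: tuple = AXES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        _check_geometry(self.data, self.spacing)
        if self.data.dtype != bool:
            uniq = np.unique(self.data)
            if not np.isin(uniq, (0, 1)).all():
                raise VolumeError("mask values must be in {0, 1}")
            self.data = self.data.astype(bool)
        self.spacing = float(self.spacing)

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


def _smallest_uint(n: int):
    for dt in (np.uint8, np.uint16, np.uint32, np.uint64):
        if n <= np.iinfo(dt).max:
            return dt
    raise VolumeError("label count too large")


@dataclass
class LabelVolume:
    """Non-negative integer label field; 0 is background, labels are 1..N.

    Stored at the smallest unsigned width that holds ``label_count`` so that
    large pore populations never silently clip on write.
    """

    data: np.ndarray
    spacing: float
    axes: tuple = AXES
    label_count: int = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        _check_geometry(self.data, self.spacing)
        if self.data.min() < 0:
            raise VolumeError("labels must be non-negative")
        present = np.unique(self.data)
        present = present[present > 0]
        n = int(present.max()) if present.size else 0
        if self.label_count is None:
            self.label_count = n
        if self.label_count != n or (present.size and present.size != n):
            raise VolumeError(
                f"labels must be contiguous 1..label_count (declared {self.label_count}, "
                f"found {present.size} distinct labels with max {n})"
            )
        self.data = self.data.astype(_smallest_uint(max(1, self.label_count)))
        self.spacing = float(self.spacing)

    @property
    def shape(self):
        return self.data.shape


# ---------------------------------------------------------------------------
# volume reading / writing
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(path: Path):
    # "slice2.tif" sorts before "slice10.tif"
    parts = _NUM_RE.split(path.name)
    return [int(p) if p.isdigit() else p for p in parts]


def sorted_slice_paths(paths: Iterable) -> list:
    return sorted((Path(p) for p in paths), key=_numeric_key)


def _sidecar_path(target: Path) -> Path:
    if target.is_dir():
        return target / "volume.meta.yaml"
    return target.with_suffix(target.suffix + ".meta.yaml")


def _read_sidecar(target: Path) -> dict:
    p = _sidecar_path(target)
    if p.exists():
        with open(p) as fh:
            return yaml.safe_load(fh) or {}
    return {}


def _write_sidecar(target: Path, meta: dict) -> Path:
    p = _sidecar_path(target)
    with open(p, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return p


def _read_slice(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # RGB(A) bitmap: collapse identical channels
            arr = arr[..., 0]
    if arr.ndim != 2:
        raise VolumeError(f"slice file {path} is not a single 2D image")
    return arr


def read_stack(source, spacing=None, unit: str = "mm") -> VoxelVolume:
    """Read a grayscale volume from slice files, a multipage TIFF, or MetaImage.

    Parameters
    ----------
    source:
        A directory of slice files, an explicit ordered list of slice paths,
        a multipage TIFF path, or a ``.mhd`` MetaImage header.
    spacing, unit:
        Isotropic voxel spacing. Required unless the format header
        (MetaImage) or a YAML sidecar supplies it; a missing spacing is an
        error, never a silent default.
    """
    if isinstance(source, (list, tuple)):
        paths = [Path(p) for p in source]
        if not paths:
            raise VolumeError("empty slice list")
        return _stack_slices(paths, _resolve_spacing(paths[0].parent, spacing, unit))

    source = Path(source)
    if not source.exists():
        raise VolumeError(f"no such file or directory: {source}")

    if source.is_dir():
        paths = sorted_slice_paths(
            p for p in source.iterdir()
            if p.suffix.lower() in (".tif", ".tiff", ".bmp", ".png")
        )
        if not paths:
            raise VolumeError(f"no slice files found in {source}")
        return _stack_slices(paths, _resolve_spacing(source, spacing, unit))

    if source.suffix.lower() == ".mhd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(source))
        data = sitk.GetArrayFromImage(img)
        sp = img.GetSpacing()
        if max(sp) - min(sp) > 1e-9 * max(sp):
            raise VolumeError(f"anisotropic spacing {sp} not supported")
        return VoxelVolume(np.clip(data, 0, 255).astype(np.uint8), float(sp[0]))

    if source.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(source)
        if data.ndim == 2:
            data = data[None]
        return VoxelVolume(data, _resolve_spacing(source, spacing, unit))

    raise VolumeError(f"unsupported volume file: {source}")


def _resolve_spacing(target: Path, spacing, unit: str) -> float:
    if spacing is not None:
        return spacing_to_mm(spacing, unit)
    meta = _read_sidecar(Path(target))
    if "spacing_mm" in meta:
        return float(meta["spacing_mm"])
    raise VolumeError(
        f"voxel spacing not supplied and no sidecar found for {target}; "
        "pass spacing= explicitly (spacing is never defaulted silently)"
    )


def _stack_slices(paths: Sequence[Path], spacing_mm: float) -> VoxelVolume:
    slices = []
    shape = None
    for p in paths:
        arr = _read_slice(p)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise VolumeError(
                f"slice shape mismatch: {p} has {arr.shape}, expected {shape}"
            )
        slices.append(arr)
    data = np.stack(slices, axis=0)
    if data.dtype != np.uint8:
        data = np.clip(data, 0, 255).astype(np.uint8)
    return VoxelVolume(data, spacing_mm)


_KIND_BY_TYPE = {VoxelVolume: "grayscale", MaskVolume: "mask", LabelVolume: "labels"}


def write_volume(vol, target, format: str = "tiff") -> list:
    """Write a volume; ``read_volume`` round-trips data and spacing exactly.

    ``format`` is one of ``tiff`` (multipage), ``stack`` (numbered TIFF
    slices in a directory) or ``mhd`` (MetaImage). Masks are stored as 0/255
    uint8; labels at the smallest unsigned width that fits.
    """
    target = Path(target)
    kind = _KIND_BY_TYPE.get(type(vol))
    if kind is None:
        raise VolumeError(f"cannot write object of type {type(vol)}")
    if kind == "mask":
        data = vol.data.astype(np.uint8) * 255
    else:
        data = vol.data
    meta = {"spacing_mm": vol.spacing, "axes": list(vol.axes), "kind": kind}
    if kind == "labels":
        meta["label_count"] = int(vol.label_count)

    if format == "tiff":
        target.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(target, data)
        side = _write_sidecar(target, meta)
        return [target, side]
    if format == "stack":
        target.mkdir(parents=True, exist_ok=True)
        out = []
        for i in range(data.shape[0]):
            p = target / f"slice_{i:04d}.tif"
            tifffile.imwrite(p, data[i])
            out.append(p)
        out.append(_write_sidecar(target, meta))
        return out
    if format == "mhd":
        import SimpleITK as sitk

        target.parent.mkdir(parents=True, exist_ok=True)
        img = sitk.GetImageFromArray(np.ascontiguousarray(data))
        img.SetSpacing((vol.spacing,) * 3)
        sitk.WriteImage(img, str(target))
        _write_sidecar(target, meta)
        return [target]
    raise VolumeError(f"unsupported volume format: {format!r}")


def read_volume(target, spacing=None, unit: str = "mm"):
    """Read a volume written by :func:`write_volume`, restoring its type."""
    target = Path(target)
    meta = _read_sidecar(target)
    kind = meta.get("kind", "grayscale")

    if target.suffix.lower() == ".mhd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(target))
        data = sitk.GetArrayFromImage(img)
        sp = float(img.GetSpacing()[0])
    elif target.is_dir():
        paths = sorted_slice_paths(p for p in target.iterdir()
                                   if p.suffix.lower() in (".tif", ".tiff"))
        data = np.stack([tifffile.imread(p) for p in paths], axis=0)
        sp = _resolve_spacing(target, spacing, unit)
    else:
        data = tifffile.imread(target)
        if data.ndim == 2:
            data = data[None]
        sp = _resolve_spacing(target, spacing, unit)

    if kind == "mask":
        return MaskVolume(data > 0, sp)
    if kind == "labels":
        return LabelVolume(data, sp, label_count=meta.get("label_count"))
    return VoxelVolume(data, sp)


# ---------------------------------------------------------------------------
# mesh export (legacy VTK and Abaqus .inp subset)
# ---------------------------------------------------------------------------

def export_mesh(model, target, format: str = "vtk", cell_fields: dict | None = None):
    """Export an FE model's hexahedral mesh with named node sets.

    ``format='vtk'`` writes a legacy ASCII unstructured grid (hexahedron
    cells, optional per-element scalar fields); ``format='inp'`` writes an
    Abaqus-style deck with ``*NODE``, ``*ELEMENT, TYPE=C3D8`` and one
    ``*NSET`` per named set (1-based ids). Node coordinates are emitted in mm.
    """
    target = Path(target)
    nodes = np.asarray(model.nodes, dtype=float)
    elems = np.asarray(model.elements, dtype=np.int64)
    if elems.size == 0:
        raise VolumeError("refusing to export an empty mesh")
    nsets = dict(model.node_sets())

    target.parent.mkdir(parents=True, exist_ok=True)
    if format == "vtk":
        _write_vtk(target, nodes, elems, nsets, cell_fields or {})
    elif format == "inp":
        _write_inp(target, nodes, elems, nsets)
    else:
        raise VolumeError(f"unsupported mesh format: {format!r}")
    return target


def _write_vtk(path, nodes, elems, nsets, cell_fields):
    n_nodes, n_elems = len(nodes), len(elems)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("nestmech voxel mesh; node sets: "
                 + ",".join(f"{k}={len(v)}" for k, v in nsets.items()) + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n_nodes} float\n")
        np.savetxt(fh, nodes, fmt="%.9g")
        fh.write(f"CELLS {n_elems} {n_elems * 9}\n")
        cells = np.column_stack([np.full(n_elems, 8, dtype=np.int64), elems])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {n_elems}\n")
        np.savetxt(fh, np.full(n_elems, 12, dtype=np.int64), fmt="%d")
        # node sets as point data flags so they survive visualisation round trips
        fh.write(f"POINT_DATA {n_nodes}\n")
        for name, ids in nsets.items():
            flag = np.zeros(n_nodes, dtype=np.int8)
            flag[np.asarray(ids, dtype=np.int64)] = 1
            fh.write(f"SCALARS nset_{name} int 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, flag, fmt="%d")
        if cell_fields:
            fh.write(f"CELL_DATA {n_elems}\n")
            for name, values in cell_fields.items():
                values = np.asarray(values, dtype=float)
                if values.shape != (n_elems,):
                    raise VolumeError(f"cell field {name!r} has wrong length")
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, values, fmt="%.9g")


def _write_inp(path, nodes, elems, nsets):
    with open(path, "w") as fh:
        fh.write("*HEADING\nnestmech voxel hexahedral mesh (mm, N, MPa)\n")
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(nodes, start=1):
            fh.write(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}\n")
        fh.write("*ELEMENT, TYPE=C3D8\n")
        for i, conn in enumerate(elems, start=1):
            fh.write(str(i) + ", " + ", ".join(str(c + 1) for c in conn) + "\n")
        for name, ids in nsets.items():
            fh.write(f"*NSET, NSET={name}\n")
            ids = np.asarray(ids, dtype=np.int64) + 1
            for start in range(0, len(ids), 12):
                fh.write(", ".join(map(str, ids[start:start + 12])) + "\n")


def read_vtk_mesh(path):
    """Parse a legacy VTK file written by :func:`export_mesh`.

    Intentionally minimal — only the subset this package emits — and used to
    verify round trips.
    Returns ``(nodes, elements, node_sets, cell_fields)``.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0
    nodes = elems = None
    nsets, cfields = {}, {}
    n_nodes = n_cells = 0
    section = None
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n_nodes = int(line.split()[1])
            nodes = np.loadtxt(tokens[i + 1:i + 1 + n_nodes])
            i += n_nodes
        elif line.startswith("CELLS"):
            n_cells = int(line.split()[1])
            raw = np.loadtxt(tokens[i + 1:i + 1 + n_cells], dtype=np.int64, ndmin=2)
            elems = raw[:, 1:]
            i += n_cells
        elif line.startswith("POINT_DATA"):
            section = "point"
        elif line.startswith("CELL_DATA"):
            section = "cell"
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            count = n_nodes if section == "point" else n_cells
            vals = np.loadtxt(tokens[i + 2:i + 2 + count])
            if section == "point" and name.startswith("nset_"):
                nsets[name[5:]] = np.flatnonzero(vals.astype(int))
            elif section == "cell":
                cfields[name] = vals
            i += count + 1
        i += 1
    return nodes, elems, nsets, cfields


def read_inp_nsets(path) -> dict:
    """Parse ``*NSET`` blocks from an Abaqus deck written by this package."""
    nsets = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.upper().startswith("*NSET"):
                name = dict(
                    kv.split("=") for kv in line.split(",")[1:] if "=" in kv
                ).get("NSET") or line.split("=")[-1]
                current = nsets.setdefault(name.strip(), [])
            elif line.startswith("*"):
                current = None
            elif current is not None and line:
                current.extend(int(t) - 1 for t in line.split(",") if t.strip())
    return {k: np.asarray(v, dtype=np.int64) for k, v in nsets.items()}
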