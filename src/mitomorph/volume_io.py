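"""I/O for segmented label volumes, traced contours, meshes and metric tables.

The unit of 3D data is a :class:`LabelVolume`: a ``(nz, ny, nx)`` grid of
non-negative integers (0 = background, one positive label per mitochondrion)
plus an anisotropic :class:`VoxelSpacing`.  Serial block-face SEM stacks are
acquired with much finer in-plane than axial resolution, so the spacing is
carried explicitly everywhere rather than assumed isotropic.

Conventions
-----------
* axis order is ``(z, y, x)``; indices are 0-based
* the center of voxel ``(k, j, i)`` sits at physical ``(k*dz, j*dy, i*dx)`` nm
* spacing is stored in a JSON sidecar (keys ``dx_nm``, ``dy_nm``, ``dz_nm``),
  never in TIFF tags — resolution metadata written by segmentation tools is
  unreliable
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import BoundsError, FormatError, MissingLabelError, ValidationError

__all__ = [
    "VoxelSpacing",
    "LabelVolume",
    "Contour",
    "ContourStack",
    "read_label_stack",
    "write_label_stack",
    "read_spacing_sidecar",
    "write_spacing_sidecar",
    "rasterize_contours",
    "write_metrics_csv",
    "read_metrics_csv",
    "export_mesh",
]

#: nm per µm, cubed where needed
NM_PER_UM = 1000.0


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel pitch in nanometers.

    Defaults match a typical SBF-SEM acquisition: 10 nm in-plane and a
    50 nm sectioning step.
    """

    dx: float = 10.0
    dy: float = 10.0
    dz: float = 50.0

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"spacing {name} must be finite and > 0, got {v!r}")

    @property
    def zyx(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)

    @property
    def voxel_volume_nm3(self) -> float:
        return self.dx * self.dy * self.dz

    def to_dict(self) -> dict[str, float]:
        return {"dx_nm": self.dx, "dy_nm": self.dy, "dz_nm": self.dz}

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelSpacing":
        return cls(dx=float(d["dx_nm"]), dy=float(d["dy_nm"]), dz=float(d["dz_nm"]))


@dataclass
class LabelVolume:
    """A 3D integer label grid with physical spacing.

    ``labels`` has shape ``(nz, ny, nx)``; 0 is background and every positive
    value identifies one segmented object (normally one mitochondrion).
    """

    labels: np.ndarray
    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)
    provenance: str = ""

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3 or labels.size == 0:
            raise ValidationError(f"labels must be a non-empty 3D grid, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValidationError(f"labels must be integer-typed, got {labels.dtype}")
        if labels.min() < 0:
            raise ValidationError("labels must be non-negative (0 = background)")
        self.labels = labels

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_values(self) -> np.ndarray:
        """Sorted positive labels present in the volume."""
        vals = np.unique(self.labels)
        return vals[vals > 0]

    def mask(self, label: int) -> np.ndarray:
        m = self.labels == label
        if not m.any():
            raise MissingLabelError(label)
        return m


@dataclass
class Contour:
    """One closed polygon traced on a single slice.

    ``vertices`` is an ``(n, 2)`` array of in-plane pixel coordinates in
    ``(y, x)`` order (matching array indexing). The polygon is implicitly
    closed; the first vertex need not be repeated.
    """

    label: int
    slice_index: int
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError(
                f"contour needs >=3 (y, x) vertices, got array of shape {v.shape}"
            )
        if self.label <= 0:
            raise ValidationError(f"contour label must be positive, got {self.label}")
        self.vertices = v


@dataclass
class ContourStack:
    """Ordered list of traced contours; later contours win on overlap."""

    contours: list[Contour]

    def __iter__(self):
        return iter(self.contours)

    def __len__(self) -> int:
        return len(self.contours)


# ---------------------------------------------------------------------------
# label stacks


def read_label_stack(path: str | Path, spacing: VoxelSpacing | None = None) -> LabelVolume:
    """Read a multi-page TIFF of integer labels into a :class:`LabelVolume`.

    If ``spacing`` is None, a JSON sidecar named ``<path>.json`` is consulted;
    absent that, the default spacing applies.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises various subclasses
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a stack of 2D pages, got ndim={arr.ndim}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: label pixels must be integer, got {arr.dtype}")
    if spacing is None:
        sidecar = path.with_name(path.name + ".json")
        spacing = read_spacing_sidecar(sidecar) if sidecar.exists() else VoxelSpacing()
    return LabelVolume(labels=arr, spacing=spacing, provenance=str(path))


def write_label_stack(volume: LabelVolume, path: str | Path, sidecar: bool = True) -> Path:
    """Write a label volume as an unsigned-integer multi-page TIFF.

    The smallest unsigned dtype that holds the label range is used; a spacing
    sidecar ``<path>.json`` is written alongside unless ``sidecar=False``.
    """
    path = Path(path)
    vmax = int(volume.labels.max(initial=0))
    for dt in (np.uint8, np.uint16, np.uint32):
        if vmax <= np.iinfo(dt).max:
            out = volume.labels.astype(dt)
            break
    else:
        raise ValidationError(f"label values exceed uint32 range (max {vmax})")
    tifffile.imwrite(path, out)
    if sidecar:
        write_spacing_sidecar(volume.spacing, path.with_name(path.name + ".json"))
    return path


def read_spacing_sidecar(path: str | Path) -> VoxelSpacing:
    with open(path) as fh:
        d = json.load(fh)
    try:
        return VoxelSpacing.from_dict(d)
    except KeyError as exc:
        raise FormatError(f"{path}: spacing sidecar missing key {exc}") from exc


def write_spacing_sidecar(spacing: VoxelSpacing, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(spacing.to_dict(), fh, indent=2)
    return path


# ---------------------------------------------------------------------------
# contour rasterization


def _points_in_polygon(ys: np.ndarray, xs: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) test for pixel centers, vectorized.

    Centers lying exactly on a polygon edge are excluded when the edge is
    vertical in the casting direction; ties are broken deterministically by
    the strict inequality below. Works for non-convex and self-intersecting
    polygons under the even-odd rule.
    """
    y0, x0 = poly[:, 0], poly[:, 1]
    y1, x1 = np.roll(y0, -1), np.roll(x0, -1)
    inside = np.zeros(ys.shape, dtype=bool)
    for a_y, a_x, b_y, b_x in zip(y0, x0, y1, x1):
        if a_y == b_y:
            continue  # horizontal edge never crosses a horizontal ray's y-level test
        crosses = (a_y > ys) != (b_y > ys)
        with np.errstate(invalid="ignore"):
            x_at = a_x + (ys - a_y) * (b_x - a_x) / (b_y - a_y)
        inside ^= crosses & (xs < x_at)
    return inside


def rasterize_contours(
    contours: ContourStack | Sequence[Contour],
    shape: tuple[int, int, int],
    spacing: VoxelSpacing | None = None,
) -> LabelVolume:
    """Stack traced per-slice polygons into a label volume.

    A pixel receives a polygon's label iff its center is strictly inside under
    the even-odd rule; contours later in the list overwrite earlier ones.
    """
    nz, ny, nx = shape
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    for c in contours:
        if not (0 <= c.slice_index < nz):
            raise BoundsError(
                f"contour slice index {c.slice_index} outside stack depth {nz}"
            )
        v = c.vertices
        if (v[:, 0].min() < -0.5 or v[:, 0].max() > ny - 0.5
                or v[:, 1].min() < -0.5 or v[:, 1].max() > nx - 0.5):
            raise BoundsError(
                f"contour (label {c.label}, slice {c.slice_index}) extends outside "
                f"the {ny}x{nx} in-plane grid"
            )
        inside = _points_in_polygon(yy, xx, v)
        labels[c.slice_index][inside] = c.label
    return LabelVolume(labels=labels, spacing=spacing or VoxelSpacing(), provenance="contours")


# ---------------------------------------------------------------------------
# metric tables


def write_metrics_csv(records: Sequence, path: str | Path, schema: type | None = None) -> Path:
    """Write a homogeneous list of metric dataclass records to CSV.

    One row per object, header row first, columns in dataclass field order,
    floats at full round-trip precision. For an empty list the record type
    must be supplied via ``schema`` so a header-only file can be written.
    """
    records = list(records)
    if records:
        types = {type(r) for r in records}
        if len(types) > 1:
            raise ValidationError(f"mixed record schemas: {sorted(t.__name__ for t in types)}")
        schema = type(records[0])
    if schema is None or not dataclasses.is_dataclass(schema):
        raise ValidationError("empty record list requires an explicit dataclass schema")
    cols = [f.name for f in dataclasses.fields(schema)]
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# mesh export


def export_mesh(volume: LabelVolume, label: int, path: str | Path) -> Path:
    """Export one object's isosurface as an OBJ or PLY triangle mesh.

    Vertex coordinates are physical nanometers in ``(x, y, z)`` order, so the
    mesh honors the anisotropic spacing. The surface is the same anti-aliased
    marching-cubes isosurface used for surface-area measurement.
    """
    import trimesh

    from ._mesh import isosurface_mesh

    mask = volume.mask(label)  # raises MissingLabelError if absent
    verts_zyx, faces = isosurface_mesh(mask, volume.spacing)
    verts_xyz = verts_zyx[:, ::-1]
    mesh = trimesh.Trimesh(vertices=verts_xyz, faces=faces, process=False)
    path = Path(path)
    if path.suffix.lower() not in {".obj", ".ply"}:
        raise ValidationError(f"mesh export supports .obj/.ply, got {path.suffix!r}")
    mesh.export(path)
    return path
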