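"""Body-only centre of mass from labelled voxel volumes and triangle meshes.

The CoM tracked in jump videos is defined anatomically from micro-CT
scans: the segmented body (cephalothorax + abdomen) is assumed homogeneous
and solid, the legs carry a separate label and are excluded, and the CoM
is the uniform-density centroid of the included volume.  Both the voxel
route (centroid of labelled voxel centres) and the mesh route (signed
tetrahedron decomposition of a watertight surface mesh) are provided; on
consistent inputs they agree to within a voxel.

Volumes are read/written as NIfTI (via nibabel) or as a plain-text grid
format for small fixtures; meshes as STL (via trimesh).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import MeshIntegrityError

log = logging.getLogger(__name__)

__all__ = [
    "LabelledVolume",
    "TriMesh",
    "MeshComResult",
    "voxel_com",
    "mesh_com",
    "binning_downsample",
    "check_watertight",
    "read_nifti_volume",
    "write_nifti_volume",
    "read_raw_volume",
    "write_raw_volume",
    "read_stl",
    "write_stl",
]


@dataclass
class LabelledVolume:
    """3-D integer label grid with per-axis voxel spacing (mm).

    Voxel (i, j, k) is centred at (i, j, k) * spacing.  Label 0 is
    background by convention; ``labels`` maps label values to names
    (e.g. 1 = body, 2 = legs).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("label grid must be 3-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("label grid must be integer-valued")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 positive values")
        if not (self.grid != 0).any():
            raise ValueError("volume has no nonzero voxels")


def voxel_com(
    volume: LabelledVolume, include_labels: Iterable[int]
) -> np.ndarray:
    """Uniform-density centroid (mm) of the voxels with the included labels.

    With the body and legs under different labels, passing only the body
    label reproduces a body-only CoM (legs excluded).
    """
    include = list(include_labels)
    mask = np.isin(volume.grid, include)
    if not mask.any():
        raise ValueError(f"no voxels with labels {include}")
    idx = np.argwhere(mask).astype(float)
    return idx.mean(axis=0) * np.asarray(volume.spacing)


@dataclass
class TriMesh:
    """A triangle surface mesh: vertex coordinates (mm) and index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3) vertex-index triples")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise ValueError("face indices out of range")


@dataclass
class MeshComResult:
    com: np.ndarray
    volume: float


def check_watertight(mesh: TriMesh) -> None:
    """Verify the mesh bounds a volume: every edge is shared by exactly two
    triangles with opposite orientation.  Raises MeshIntegrityError with a
    defect report otherwise."""
    directed: dict[tuple[int, int], int] = {}
    for tri in mesh.faces:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (int(a), int(b))
            directed[key] = directed.get(key, 0) + 1
    defects = []
    for (a, b), count in directed.items():
        if count != 1:
            defects.append(f"edge ({a},{b}) used {count} times in one orientation")
        elif directed.get((b, a), 0) != 1:
            defects.append(f"edge ({a},{b}) has no opposite-orientation partner")
        if len(defects) >= 5:
            break
    if defects:
        raise MeshIntegrityError(
            "mesh is not watertight/consistently oriented: " + "; ".join(defects)
        )


def mesh_com(mesh: TriMesh) -> MeshComResult:
    """Uniform-density centroid and volume via signed tetrahedra.

    Each triangle forms a signed tetrahedron with the origin; summing
    their volumes and first moments gives the enclosed volume and its
    centroid.  The result is independent of the reference point for a
    closed, consistently oriented mesh (checked before integrating).
    """
    check_watertight(mesh)
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    signed = np.einsum("ij,ij->i", v0, np.cross(v1, v2)) / 6.0
    volume = float(signed.sum())
    if abs(volume) < 1e-12:
        raise MeshIntegrityError("mesh encloses zero volume")
    moments = signed[:, None] * (v0 + v1 + v2) / 4.0
    com = moments.sum(axis=0) / volume
    if volume < 0:  # inward orientation; report positive volume
        volume = -volume
    return MeshComResult(com=com, volume=volume)


def binning_downsample(volume: LabelledVolume, factor: int = 2) -> LabelledVolume:
    """Halve (or 1/factor) the grid resolution by majority-label binning.

    Each factor^3 block maps to its most frequent label, ties resolving
    to the lowest label value; the voxel spacing is multiplied by the
    factor.  Grids whose dimensions are not divisible by the factor are
    zero-padded with a warning.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    grid = volume.grid
    pad = [(-d) % factor for d in grid.shape]
    if any(pad):
        log.warning(
            "grid shape %s not divisible by %d; padding with background", grid.shape, factor
        )
        grid = np.pad(grid, [(0, p) for p in pad], constant_values=0)
    nz, ny, nx = (d // factor for d in grid.shape)
    blocks = grid.reshape(nz, factor, ny, factor, nx, factor)
    blocks = blocks.transpose(0, 2, 4, 1, 3, 5).reshape(-1, factor**3)
    nlab = int(grid.max()) + 1
    counts = np.zeros((blocks.shape[0], nlab), dtype=np.int32)
    np.add.at(counts, (np.arange(blocks.shape[0])[:, None], blocks.astype(np.int64)), 1)
    # argmax returns the lowest label on ties
    out = counts.argmax(axis=1).reshape(nz, ny, nx).astype(volume.grid.dtype)
    return LabelledVolume(
        grid=out,
        spacing=tuple(s * factor for s in volume.spacing),
        labels=dict(volume.labels),
    )


# ---------------------------------------------------------------------------
# I/O


def read_nifti_volume(
    path: str | Path, labels: Mapping[int, str] | None = None
) -> LabelledVolume:
    import nibabel as nib

    img = nib.load(str(path))
    grid = np.asarray(img.dataobj).astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelledVolume(grid=grid, spacing=spacing, labels=dict(labels or {}))


def write_nifti_volume(volume: LabelledVolume, path: str | Path) -> Path:
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.grid.astype(np.int32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return Path(path)


def write_raw_volume(volume: LabelledVolume, path: str | Path) -> Path:
    """Plain-text grid format for small fixtures (one slice per block)."""
    path = Path(path)
    lines = [
        "# saltijump labelled volume",
        "shape " + " ".join(str(d) for d in volume.grid.shape),
        "spacing " + " ".join(f"{s:.10g}" for s in volume.spacing),
        "labels " + " ".join(f"{k}={v}" for k, v in sorted(volume.labels.items())),
    ]
    for sl in volume.grid:
        lines.append("")
        for row in sl:
            lines.append(" ".join(str(int(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_raw_volume(path: str | Path) -> LabelledVolume:
    path = Path(path)
    header: dict[str, str] = {}
    values: list[int] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key = line.split()[0]
        if key in ("shape", "spacing", "labels") and key not in header:
            header[key] = line[len(key):].strip()
        else:
            values.extend(int(tok) for tok in line.split())
    shape = tuple(int(t) for t in header["shape"].split())
    spacing = tuple(float(t) for t in header["spacing"].split())
    labels = {}
    for tok in header.get("labels", "").split():
        k, _, name = tok.partition("=")
        labels[int(k)] = name
    grid = np.array(values, dtype=np.int32).reshape(shape)
    return LabelledVolume(grid=grid, spacing=spacing, labels=labels)


def read_stl(path: str | Path) -> TriMesh:
    import trimesh

    tm = trimesh.load(str(path), force="mesh")
    return TriMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


def write_stl(mesh: TriMesh, path: str | Path) -> Path:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))
    return Path(path)
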