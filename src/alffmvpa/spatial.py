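"""Voxel-grid geometry, NIfTI I/O, searchlight spheres and cluster labeling.

Shared spatial primitives: a :class:`VolumeGrid` describes the voxel lattice
and its affine into MNI millimetres; :func:`sphere_offsets` enumerates the
integer offsets of a searchlight sphere; :func:`label_clusters` partitions a
binary map into connected components with deterministic ordering.

Voxel indices are 0-based throughout; reported coordinates are MNI mm via
the grid affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .exceptions import InvalidArgumentError, VolumeFormatError

__all__ = [
    "VolumeGrid",
    "Mask",
    "Cluster",
    "ClusterSet",
    "Bold4D",
    "sphere_offsets",
    "label_clusters",
    "voxel_to_mni",
    "mni_to_voxel",
    "read_volume",
    "write_volume",
    "connectivity_structure",
]


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3D voxel lattice.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along each axis; all >= 1.
    voxel_size : tuple of float
        Voxel edge length in mm along each axis; all > 0.
    affine : ndarray (4, 4)
        Homogeneous transform mapping voxel indices to MNI mm. Must be
        invertible.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise InvalidArgumentError(f"dims must be 3 positive integers, got {self.dims}")
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise InvalidArgumentError(f"voxel sizes must be > 0, got {self.voxel_size}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise InvalidArgumentError("affine must be 4x4")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise InvalidArgumentError("affine must be invertible")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "affine", aff)

    @classmethod
    def from_affine(cls, dims: Sequence[int], affine: np.ndarray) -> "VolumeGrid":
        affine = np.asarray(affine, dtype=float)
        vs = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
        return cls(tuple(dims), vs, affine)

    @classmethod
    def isotropic(cls, dims: Sequence[int], voxel_mm: float = 3.0,
                  origin_mm: Sequence[float] | None = None) -> "VolumeGrid":
        """Axis-aligned grid with isotropic voxels, centred on the origin by default."""
        dims = tuple(int(d) for d in dims)
        if origin_mm is None:
            origin_mm = [-voxel_mm * (d - 1) / 2.0 for d in dims]
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        aff[:3, 3] = origin_mm
        return cls(dims, (voxel_mm,) * 3, aff)

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(self.affine, other.affine, atol=atol)


@dataclass
class Mask:
    """A set of in-grid voxels, stored as a boolean volume."""

    grid: VolumeGrid
    data: np.ndarray  # boolean, shape == grid.dims

    def __post_init__(self):
        data = np.asarray(self.data, dtype=bool)
        if data.shape != self.grid.dims:
            raise InvalidArgumentError(
                f"mask shape {data.shape} does not match grid dims {self.grid.dims}")
        self.data = data

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def indices(self) -> np.ndarray:
        """(n, 3) integer array of in-mask voxel indices, C order."""
        return np.argwhere(self.data)

    def require_nonempty(self):
        if self.n_voxels == 0:
            raise InvalidArgumentError("mask is empty")


@dataclass
class Cluster:
    """One connected component of a thresholded map."""

    voxel_indices: np.ndarray  # (size, 3) int
    size: int
    peak_index: tuple[int, int, int]
    peak_mni: tuple[float, float, float]
    peak_value: float

    def to_mask(self, grid: VolumeGrid) -> Mask:
        data = np.zeros(grid.dims, dtype=bool)
        data[tuple(self.voxel_indices.T)] = True
        return Mask(grid, data)


@dataclass
class ClusterSet:
    """Pairwise-disjoint clusters, ordered by descending size then peak index."""

    grid: VolumeGrid
    clusters: list[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def __getitem__(self, i) -> Cluster:
        return self.clusters[i]

    @property
    def total_voxels(self) -> int:
        return sum(c.size for c in self.clusters)

    def union_mask(self) -> Mask:
        data = np.zeros(self.grid.dims, dtype=bool)
        for c in self.clusters:
            data[tuple(c.voxel_indices.T)] = True
        return Mask(self.grid, data)

    def to_table(self):
        """Cluster report mirroring the usual size / peak-XYZ / peak-value layout."""
        import pandas as pd

        rows = [
            {
                "cluster": i + 1,
                "size_voxels": c.size,
                "peak_x_mm": c.peak_mni[0],
                "peak_y_mm": c.peak_mni[1],
                "peak_z_mm": c.peak_mni[2],
                "peak_value": c.peak_value,
            }
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(rows)


@dataclass
class Bold4D:
    """One subject's 4D BOLD series with its grid and repetition time."""

    grid: VolumeGrid
    data: np.ndarray  # (x, y, z, t) float
    tr: float  # seconds

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise VolumeFormatError(f"BOLD data must be 4D, got ndim={data.ndim}")
        if data.shape[:3] != self.grid.dims:
            raise VolumeFormatError(
                f"spatial shape {data.shape[:3]} does not match grid {self.grid.dims}")
        if self.tr <= 0:
            raise InvalidArgumentError("repetition time must be positive")
        self.data = data

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


def sphere_offsets(radius_mm: float, voxel_size_mm: Sequence[float]) -> np.ndarray:
    """Integer voxel offsets within a sphere of ``radius_mm``.

    Every integer offset whose centre-to-centre Euclidean distance (per-axis
    scaled by voxel size) is <= radius_mm. Always contains (0, 0, 0) and is
    symmetric under negation.

    Returns
    -------
    ndarray (n, 3) of int, lexicographically sorted.
    """
    vs = np.asarray(voxel_size_mm, dtype=float)
    if vs.shape != (3,) or np.any(vs <= 0):
        raise InvalidArgumentError(f"voxel sizes must be 3 positive values, got {voxel_size_mm}")
    if radius_mm < 0:
        raise InvalidArgumentError("radius must be >= 0")
    reach = np.floor(radius_mm / vs).astype(int)
    ax = [np.arange(-r, r + 1) for r in reach]
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    offs = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    d2 = ((offs * vs) ** 2).sum(axis=1)
    offs = offs[d2 <= radius_mm**2 + 1e-9]
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))
    return offs[order]


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        return _STRUCTURES[int(connectivity)]
    except (KeyError, TypeError):
        raise InvalidArgumentError(
            f"connectivity must be one of 6, 18, 26; got {connectivity!r}") from None


def label_clusters(binary_map: np.ndarray, grid: VolumeGrid,
                   values: np.ndarray | None = None,
                   connectivity: int = 26) -> ClusterSet:
    """Connected components of a boolean 3D map.

    Components are maximal under the chosen neighbourhood (6 faces,
    18 faces+edges, or 26 faces+edges+corners). The peak of each cluster is
    the member voxel maximising ``values`` (the binary map itself if absent),
    ties broken by smallest lexicographic index. Clusters are ordered by
    descending size, then lexicographic peak index.
    """
    binary_map = np.asarray(binary_map, dtype=bool)
    if binary_map.shape != grid.dims:
        raise InvalidArgumentError("map shape does not match grid")
    structure = connectivity_structure(connectivity)
    if values is None:
        values = binary_map.astype(float)
    else:
        values = np.asarray(values, dtype=float)
        if values.shape != grid.dims:
            raise InvalidArgumentError("values shape does not match grid")

    labels, n = ndimage.label(binary_map, structure=structure)
    clusters: list[Cluster] = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)  # argwhere is lexicographically sorted
        vals = values[tuple(idx.T)]
        # peak: max value, ties -> smallest lexicographic index (first occurrence)
        peak_pos = int(np.argmax(vals))
        peak_index = tuple(int(v) for v in idx[peak_pos])
        clusters.append(
            Cluster(
                voxel_indices=idx,
                size=len(idx),
                peak_index=peak_index,
                peak_mni=voxel_to_mni(peak_index, grid),
                peak_value=float(vals[peak_pos]),
            )
        )
    clusters.sort(key=lambda c: (-c.size, c.peak_index))
    return ClusterSet(grid=grid, clusters=clusters)


def voxel_to_mni(index: Sequence[int], grid: VolumeGrid) -> tuple[float, float, float]:
    """Map a voxel index to MNI mm through the grid affine."""
    idx = np.asarray(index, dtype=float)
    if idx.shape != (3,):
        raise InvalidArgumentError("index must be a triple")
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.dims)):
        raise InvalidArgumentError(f"index {tuple(index)} outside grid dims {grid.dims}")
    mm = grid.affine @ np.append(idx, 1.0)
    return (float(mm[0]), float(mm[1]), float(mm[2]))


def mni_to_voxel(mm: Sequence[float], grid: VolumeGrid) -> tuple[float, float, float]:
    """Inverse of :func:`voxel_to_mni` (continuous voxel coordinates)."""
    out = np.linalg.inv(grid.affine) @ np.append(np.asarray(mm, dtype=float), 1.0)
    return (float(out[0]), float(out[1]), float(out[2]))


def read_volume(path, expected_grid: VolumeGrid | None = None, tr: float | None = None):
    """Read a NIfTI volume.

    Returns a ``(data, grid)`` pair for 3D files and a :class:`Bold4D` for 4D
    files (repetition time from the header unless ``tr`` is given).
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim not in (3, 4):
        raise VolumeFormatError(f"{path}: expected 3 or 4 dimensions, got {data.ndim}")
    grid = VolumeGrid.from_affine(data.shape[:3], img.affine)
    if expected_grid is not None and not grid.matches(expected_grid):
        raise VolumeFormatError(f"{path}: grid does not match the expected geometry")
    if data.ndim == 3:
        return data, grid
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if tr <= 0:
            raise VolumeFormatError(f"{path}: repetition time missing from header; pass tr=")
    return Bold4D(grid=grid, data=data, tr=tr)


def write_volume(path, data: np.ndarray, grid: VolumeGrid, tr: float | None = None) -> None:
    """Write a 3D map or 4D series as NIfTI-1 with the grid affine."""
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise VolumeFormatError(f"can only write 3D or 4D volumes, got ndim={data.ndim}")
    if data.shape[:3] != grid.dims:
        raise VolumeFormatError("data spatial shape does not match grid")
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), grid.affine)
    if data.ndim == 4 and tr is not None:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
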