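"""Single-subject gray-matter similarity networks.

Nodes are non-overlapping 3x3x3-voxel cubes tiling the gray-matter volume on
a fixed lattice; a cube joins the network when a majority of its voxels
(>= 14 of 27 by default) exceed a gray-matter density threshold.  Edges are
Pearson correlations between the cubes' 27 paired density values, optionally
maximized over the 48 right-angle rotations/reflections of one cube.  Nodal
results are aggregated to atlas regions by the parcel label at each cube's
center voxel, giving a per-region structural clustering profile comparable
with the functional one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .functional import ConnectivityMatrix
from .graphs import BinaryGraph, clustering_coefficients

__all__ = [
    "GrayMatterMap",
    "CubeSet",
    "NodalClustering",
    "extract_cubes",
    "cube_similarity",
    "build_similarity_matrix",
    "nodal_clustering_by_label",
    "CUBE_INCLUSION_MIN_VOXELS",
]

CUBE_SIDE = 3
CUBE_VOXELS = CUBE_SIDE**3
#: a cube is a node iff at least this many of its 27 voxels are gray matter
CUBE_INCLUSION_MIN_VOXELS = 14


@dataclass
class GrayMatterMap:
    """One subject's gray-matter density volume with an analysis mask."""

    subject_id: str
    volume: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        if self.volume.ndim != 3:
            raise ValueError("volume must be 3-D")
        if self.volume.min() < 0 or self.volume.max() > 1:
            raise ValueError("densities must lie in [0, 1]")
        if self.mask is None:
            self.mask = np.ones(self.volume.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.volume.shape:
                raise ValueError("mask and volume must share a shape")


@dataclass
class CubeSet:
    """Cubes retained as network nodes for one subject.

    ``values`` is (n_nodes, 27) with the 27 densities in x-fastest raster
    order (flat index = x + 3 y + 9 z within the cube); ``centers`` holds the
    center-voxel coordinate of each cube (anchor + (1, 1, 1), 0-based).
    """

    subject_id: str
    values: np.ndarray
    centers: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.centers = np.asarray(self.centers, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != CUBE_VOXELS:
            raise ValueError("values must be (n_nodes, 27)")
        if self.centers.shape != (self.values.shape[0], 3):
            raise ValueError("centers must be (n_nodes, 3)")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def select(self, index: np.ndarray) -> "CubeSet":
        return CubeSet(self.subject_id, self.values[index], self.centers[index])


@dataclass
class NodalClustering:
    """Mean cube-level clustering coefficient per atlas label.

    ``values[label]`` is NaN for labels present in the parcellation but with
    no cubes (missing, not zero).
    """

    subject_id: str
    values: dict[int, float]
    label_names: dict[int, str] = field(default_factory=dict)
    modality: str = "structural"


def extract_cubes(gm: GrayMatterMap, gm_threshold: float = 0.1) -> CubeSet:
    """Tile the masked volume with non-overlapping 3x3x3 cubes.

    The lattice is anchored at the volume origin (0-based indices); trailing
    voxels on axes not divisible by 3 are dropped.  A cube becomes a node iff
    at least ``CUBE_INCLUSION_MIN_VOXELS`` of its 27 voxels are inside the
    mask with density above ``gm_threshold``.
    """
    if min(gm.volume.shape) < CUBE_SIDE:
        raise ValueError("volume must be at least 3 voxels along every axis")
    vol = np.where(gm.mask, gm.volume, 0.0)
    nx, ny, nz = (s // CUBE_SIDE for s in vol.shape)
    trimmed = vol[: nx * 3, : ny * 3, : nz * 3]
    gray = (trimmed > gm_threshold) & gm.mask[: nx * 3, : ny * 3, : nz * 3]
    # (cube_x, x_in, cube_y, y_in, cube_z, z_in) -> (n_cubes, 27) x-fastest
    blocks = trimmed.reshape(nx, 3, ny, 3, nz, 3)
    counts = gray.reshape(nx, 3, ny, 3, nz, 3).transpose(0, 2, 4, 1, 3, 5)
    counts = counts.reshape(-1, CUBE_VOXELS).sum(axis=1)
    values = blocks.transpose(0, 2, 4, 5, 3, 1).reshape(-1, CUBE_VOXELS)
    keep = counts >= CUBE_INCLUSION_MIN_VOXELS
    if not keep.any():
        raise ValueError("no gray-matter cubes")
    anchors = np.stack(
        np.meshgrid(
            np.arange(nx) * 3, np.arange(ny) * 3, np.arange(nz) * 3, indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    return CubeSet(
        subject_id=gm.subject_id,
        values=values[keep],
        centers=anchors[keep] + 1,
    )


def _rotation_permutations() -> np.ndarray:
    """Flat-index permutations for the 48 orthogonal symmetries of a cube."""
    coords = np.array(
        [(x, y, z) for z in range(3) for y in range(3) for x in range(3)]
    )  # x-fastest raster order
    centered = coords - 1
    perms = []
    seen = set()
    from itertools import permutations, product

    for axes in permutations(range(3)):
        for signs in product((1, -1), repeat=3):
            moved = centered[:, axes] * np.array(signs) + 1
            flat = moved[:, 0] + 3 * moved[:, 1] + 9 * moved[:, 2]
            key = tuple(flat)
            if key not in seen:
                seen.add(key)
                perms.append(flat)
    return np.array(perms)


_ROTATIONS = _rotation_permutations()


def cube_similarity(a: np.ndarray, b: np.ndarray, use_rotations: bool = False) -> float:
    """Pearson correlation of two cubes' 27 paired density values.

    With ``use_rotations`` the maximum over the 48 right-angle re-orderings of
    cube ``b`` is returned.  Zero-variance cubes have no defined similarity.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != CUBE_VOXELS or b.size != CUBE_VOXELS:
        raise ValueError("cubes must have 27 values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance cube: similarity undefined")
    sa, sb = a.std(), b.std()
    da = (a - a.mean()) / sa
    db = (b - b.mean()) / sb
    if not use_rotations:
        return float(da @ db / CUBE_VOXELS)
    return float(np.max(db[_ROTATIONS] @ da) / CUBE_VOXELS)


def build_similarity_matrix(
    cubes: CubeSet, use_rotations: bool = False, block_size: int = 512
) -> tuple[ConnectivityMatrix, CubeSet]:
    """Pairwise cube similarities as a symmetric connectivity matrix.

    Zero-variance cubes are dropped (their similarity is undefined); the
    returned CubeSet holds the retained cubes, aligned with the matrix rows.
    The rotation-maximized variant streams row blocks to bound memory at
    ``block_size * n_nodes`` per symmetry.
    """
    kept_idx = np.flatnonzero(np.ptp(cubes.values, axis=1) > 0)  # exact-constant cubes
    if kept_idx.size < 2:
        raise ValueError("need at least 2 cubes with nonzero variance")
    kept = cubes.select(kept_idx)
    v = kept.values
    z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)
    n = z.shape[0]
    if not use_rotations:
        sim = (z @ z.T) / CUBE_VOXELS
    else:
        sim = np.full((n, n), -np.inf)
        for start in range(0, n, block_size):
            blk = slice(start, min(start + block_size, n))
            best = np.full((blk.stop - blk.start, n), -np.inf)
            for perm in _ROTATIONS:
                np.maximum(best, (z[blk][:, perm] @ z.T) / CUBE_VOXELS, out=best)
            sim[blk] = best
        sim = np.maximum(sim, sim.T)
    np.clip(sim, -1.0, 1.0, out=sim)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 0.0)
    matrix = ConnectivityMatrix(
        subject_id=cubes.subject_id,
        weights=sim,
        modality="structural",
        node_labels=[f"cube_{i}" for i in kept_idx],
    )
    return matrix, kept


def nodal_clustering_by_label(
    graph: BinaryGraph,
    cube_centers: np.ndarray,
    parcellation: np.ndarray,
    label_names: dict[int, str] | None = None,
) -> NodalClustering:
    """Aggregate cube-level clustering coefficients to atlas labels.

    Each cube takes the parcel label of its center voxel; background cubes
    (label 0) stay in the graph but are excluded from the aggregation.  A
    label present in the parcellation with no cubes yields NaN.
    """
    centers = np.asarray(cube_centers, dtype=int)
    if centers.shape[0] != graph.n_nodes:
        raise ValueError("graph nodes must correspond 1:1 to cube centers")
    local = clustering_coefficients(graph).local
    cube_labels = parcellation[centers[:, 0], centers[:, 1], centers[:, 2]]
    all_labels = np.unique(parcellation)
    values: dict[int, float] = {}
    for lab in all_labels:
        if lab == 0:
            continue
        sel = cube_labels == lab
        values[int(lab)] = float(local[sel].mean()) if sel.any() else float("nan")
    return NodalClustering(
        subject_id=graph.subject_id,
        values=values,
        label_names=label_names or {},
        modality="structural",
    )
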