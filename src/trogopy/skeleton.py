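"""Medial-axis skeletons of 3D masks as weighted graphs.

Skeleton voxels become graph nodes; 26-neighbour voxel pairs become edges
weighted by their anisotropic Euclidean step length, so geodesic (along-
skeleton) distances are in physical units. Used for microglial process
tips (motility) and spine/filopodium morphometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize as _sk_skeletonize

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

# 13 half-space neighbour offsets (the other 13 are their negatives)
_HALF_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]


@dataclass
class ProcessSkeleton:
    """Skeleton graph of one connected component, rooted at the soma.

    ``coords`` are voxel (z, y, x) indices; ``root_distance_nm`` holds the
    geodesic distance of every node from the root along the skeleton.
    """

    coords: np.ndarray                 # (N, 3) int
    spacing_nm: tuple[float, float, float]
    edges: np.ndarray                  # (E, 2) int node indices
    edge_lengths_nm: np.ndarray        # (E,)
    root: int
    root_distance_nm: np.ndarray       # (N,)
    predecessors: np.ndarray           # (N,) shortest-path tree parents
    degree: np.ndarray                 # (N,)

    @property
    def tips(self) -> np.ndarray:
        """Indices of degree-1 non-root nodes."""
        t = np.flatnonzero(self.degree <= 1)
        return t[t != self.root]

    @property
    def total_length_um(self) -> float:
        return float(self.edge_lengths_nm.sum()) / 1000.0

    def node_nm(self, idx) -> np.ndarray:
        """Physical (z, y, x) coordinates of node(s) in nm (voxel centers)."""
        return (np.asarray(self.coords[idx], dtype=float) + 0.5) * np.asarray(
            self.spacing_nm
        )

    def branch_point_toward_root(self, node: int) -> int:
        """First node of degree >= 3 on the path from ``node`` to the root."""
        cur = int(node)
        while cur != self.root:
            parent = int(self.predecessors[cur])
            if parent < 0:
                break
            if self.degree[parent] >= 3:
                return parent
            cur = parent
        return self.root


def geodesic_from(skel: ProcessSkeleton, node: int) -> np.ndarray:
    """Along-skeleton distances (nm) of every node from ``node``."""
    n = len(skel.coords)
    if not len(skel.edges):
        return np.zeros(n)
    src, dst = skel.edges[:, 0], skel.edges[:, 1]
    w = skel.edge_lengths_nm
    graph = csr_matrix(
        (np.concatenate([w, w]), (np.concatenate([src, dst]),
                                  np.concatenate([dst, src]))),
        shape=(n, n),
    )
    return dijkstra(graph, directed=False, indices=int(node))


def skeletonize(mask_frame: np.ndarray, spacing_nm: tuple[float, float, float],
                soma_seed_vox: tuple[int, int, int] | None = None
                ) -> ProcessSkeleton:
    """Skeletonize a single connected 3D mask into a rooted graph.

    The root is the skeleton node nearest ``soma_seed_vox`` (or the mask
    centroid if no seed is given). A disconnected or empty mask is an
    error.
    """
    mask = np.asarray(mask_frame, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) mask")
    if not mask.any():
        raise ValueError("empty mask: nothing to skeletonize")
    _, n_comp = ndimage.label(mask, structure=_STRUCT26)
    if n_comp != 1:
        raise ValueError(
            f"mask has {n_comp} connected components; expected exactly 1"
        )
    skel = _sk_skeletonize(mask)
    if not skel.any():  # tiny blob collapses; keep a single voxel
        skel = np.zeros_like(mask)
        zyx = np.argwhere(mask)[0]
        skel[tuple(zyx)] = True

    coords = np.argwhere(skel)
    n = len(coords)
    index = -np.ones(skel.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(n)

    spacing = np.asarray(spacing_nm, dtype=float)
    src, dst, wts = [], [], []
    shape = np.asarray(skel.shape)
    for off in _HALF_OFFSETS:
        shifted = coords + np.asarray(off)
        ok = np.all((shifted >= 0) & (shifted < shape), axis=1)
        nb = index[tuple(shifted[ok].T)]
        here = np.arange(n)[ok]
        valid = nb >= 0
        src.append(here[valid])
        dst.append(nb[valid])
        w = float(np.linalg.norm(np.asarray(off) * spacing))
        wts.append(np.full(valid.sum(), w))
    src = np.concatenate(src) if src else np.empty(0, dtype=int)
    dst = np.concatenate(dst) if dst else np.empty(0, dtype=int)
    wts = np.concatenate(wts) if wts else np.empty(0)

    seed = (
        np.asarray(soma_seed_vox, dtype=float)
        if soma_seed_vox is not None
        else coords.mean(axis=0)
    )
    root = int(np.argmin(np.linalg.norm((coords - seed) * spacing, axis=1)))

    graph = csr_matrix(
        (np.concatenate([wts, wts]), (np.concatenate([src, dst]),
                                      np.concatenate([dst, src]))),
        shape=(n, n),
    )
    dist, pred = dijkstra(graph, directed=False, indices=root,
                          return_predecessors=True)
    degree = np.bincount(np.concatenate([src, dst]), minlength=n)
    return ProcessSkeleton(
        coords=coords,
        spacing_nm=tuple(float(s) for s in spacing_nm),
        edges=np.stack([src, dst], axis=1) if len(src) else np.empty((0, 2), int),
        edge_lengths_nm=wts,
        root=root,
        root_distance_nm=dist,
        predecessors=pred,
        degree=degree,
    )
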