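"""Residue graphs: k-nearest-neighbor topology and rigid-motion-invariant edges.

A protein becomes a directed k-NN graph over its Cβ trace.  Edge attributes
are invariant under any global rotation + translation of the coordinates:

* a Gaussian radial basis encoding of the inter-residue distance,
* the unit displacement vector expressed in the *local frame* of the source
  residue (3 values), and
* the relative orientation of the two residues' local frames as a unit
  quaternion (4 values, scalar-first, sign fixed by a nonnegative scalar).

Local frames are built by Gram–Schmidt on the sequence-adjacent Cβ
displacements, giving every residue a right-handed orthonormal basis that
co-rotates with the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "EdgeFeatureConfig",
    "ResidueGraph",
    "DegenerateGraphError",
    "build_knn_graph",
    "local_frames",
    "rbf_encode",
    "edge_features",
    "build_residue_graph",
]


class DegenerateGraphError(ValueError):
    """Too few nodes, or geometry that defeats frame/edge construction."""


@dataclass(frozen=True)
class EdgeFeatureConfig:
    """Shape and range of the geometric edge encoding."""

    n_rbf: int = 16
    d_min: float = 0.0
    d_max: float = 20.0
    include_direction: bool = True
    include_orientation: bool = True

    def __post_init__(self):
        if self.n_rbf < 1:
            raise ValueError("n_rbf must be >= 1")
        if self.d_max <= self.d_min:
            raise ValueError("d_max must exceed d_min")

    @property
    def edge_dim(self) -> int:
        return (
            self.n_rbf
            + (3 if self.include_direction else 0)
            + (4 if self.include_orientation else 0)
        )


@dataclass
class ResidueGraph:
    """Node coordinates/features plus per-k neighbor lists and edge tensors."""

    coords: np.ndarray                       # (N, 3) Cβ positions, Å
    node_feats: np.ndarray                   # (N, dim)
    neighbors: dict[int, np.ndarray] = field(default_factory=dict)   # k -> (N, k')
    edge_feats: dict[int, np.ndarray] = field(default_factory=dict)  # k -> (N, k', E)
    frames: np.ndarray | None = None         # (N, 3, 3) row-orthonormal bases

    @property
    def n_nodes(self) -> int:
        return len(self.coords)


def build_knn_graph(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``min(k, N-1)`` nearest other nodes per node, ascending.

    Ties are broken deterministically by lower index.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise DegenerateGraphError("need at least 2 nodes for a k-NN graph")
    if k < 1:
        raise ValueError("k must be >= 1")
    k_eff = min(k, n - 1)
    tree = cKDTree(coords)
    # query k_eff+1 including self, then drop self per row
    _, idx = tree.query(coords, k=k_eff + 1)
    out = np.empty((n, k_eff), dtype=int)
    for i in range(n):
        row = idx[i][idx[i] != i][:k_eff]
        if len(row) < k_eff:  # self appeared late due to coincident points
            extra = [j for j in idx[i] if j != i and j not in row]
            row = np.concatenate([row, extra])[:k_eff]
        # re-sort by (distance, index) for a deterministic tie-break
        d = np.linalg.norm(coords[row] - coords[i], axis=1)
        order = np.lexsort((row, np.round(d, 9)))
        out[i] = row[order]
    return out


def local_frames(coords: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame per residue from adjacent Cβ positions.

    Frame ``i`` is Gram–Schmidt on ``(x[i+1]-x[i], x[i-1]-x[i])`` with the
    cross product as the third axis; terminal residues copy the frame of
    their unique sequence neighbor.  Returned as (N, 3, 3) with basis vectors
    in rows.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 3:
        raise DegenerateGraphError("need at least 3 residues to build local frames")
    frames = np.empty((n, 3, 3), dtype=float)
    for i in range(1, n - 1):
        u = coords[i + 1] - coords[i]
        v = coords[i - 1] - coords[i]
        nu = np.linalg.norm(u)
        if nu < 1e-8:
            raise DegenerateGraphError(f"coincident consecutive residues at {i}")
        e1 = u / nu
        w = v - (v @ e1) * e1
        nw = np.linalg.norm(w)
        if nw < 1e-8:
            raise DegenerateGraphError(f"collinear/coincident neighborhood at {i}")
        e2 = w / nw
        e3 = np.cross(e1, e2)
        frames[i] = np.stack([e1, e2, e3])
    frames[0] = frames[1]
    frames[-1] = frames[-2]
    return frames


def rbf_encode(d: float | np.ndarray, config: EdgeFeatureConfig = EdgeFeatureConfig()) -> np.ndarray:
    """Gaussian radial basis encoding of a distance (Å).

    Centers are evenly spaced on ``[d_min, d_max]``; the width equals the
    center spacing.  Vectorized over the leading shape of ``d``.
    """
    centers = np.linspace(config.d_min, config.d_max, config.n_rbf)
    sigma = (config.d_max - config.d_min) / max(config.n_rbf - 1, 1)
    d = np.asarray(d, dtype=float)[..., None]
    return np.exp(-(((d - centers) / sigma) ** 2))


def _quat_scalar_first(rot: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of a rotation matrix, w >= 0."""
    q = Rotation.from_matrix(rot).as_quat()  # (x, y, z, w)
    q = np.concatenate([q[..., 3:4], q[..., 0:3]], axis=-1)
    sign = np.where(q[..., 0:1] < 0, -1.0, 1.0)
    return q * sign


def edge_features(
    coords: np.ndarray,
    frames: np.ndarray,
    neighbors: np.ndarray,
    config: EdgeFeatureConfig = EdgeFeatureConfig(),
) -> np.ndarray:
    """Invariant edge tensor of shape ``(N, k, E)`` for the given topology.

    For edge ``(i, j)``: RBF(‖x_j−x_i‖), then the unit displacement in frame
    ``i``, then the quaternion of ``frame_i · frame_jᵀ`` mapping frame-j axes
    into frame-i coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    n, k = neighbors.shape
    diff = coords[neighbors] - coords[:, None, :]          # (N, k, 3)
    dist = np.linalg.norm(diff, axis=-1)                   # (N, k)
    if np.any(dist < 1e-8):
        raise DegenerateGraphError("zero-length edge (coincident residues)")
    blocks = [rbf_encode(dist, config)]
    if config.include_direction:
        unit = diff / dist[..., None]
        # rows of frames[i] are basis vectors: components = frames[i] @ u
        blocks.append(np.einsum("iab,ikb->ika", frames, unit))
    if config.include_orientation:
        rel = np.einsum("iab,ikcb->ikac", frames, frames[neighbors])  # R_i R_jᵀ
        quat = _quat_scalar_first(rel.reshape(-1, 3, 3)).reshape(n, k, 4)
        blocks.append(quat)
    return np.concatenate(blocks, axis=-1)


def build_residue_graph(
    coords: np.ndarray,
    node_feats: np.ndarray,
    k_values: tuple[int, ...] = (16,),
    config: EdgeFeatureConfig = EdgeFeatureConfig(),
) -> ResidueGraph:
    """Assemble a :class:`ResidueGraph` with neighbor lists for each ``k``."""
    coords = np.asarray(coords, dtype=float)
    node_feats = np.asarray(node_feats, dtype=float)
    if len(coords) != len(node_feats):
        raise ValueError("coords and node_feats disagree on residue count")
    frames = local_frames(coords)
    g = ResidueGraph(coords=coords, node_feats=node_feats, frames=frames)
    for k in sorted(set(k_values)):
        nbr = build_knn_graph(coords, k)
        g.neighbors[k] = nbr
        g.edge_feats[k] = edge_features(coords, frames, nbr, config)
    return g
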