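"""Structural disconnectomes from lesion geometry.

A lesion's impact on the connection between parcellation nodes i and j is
estimated against a reference path atlas: for each reference subject r the
loss is the path probability mass falling inside the lesion relative to the
pair's total path probability,

    loss_r(i, j) = sum_{v in lesion} p_r(v) / sum_v p_r(v),

and the pair's disconnection value is the mean of loss_r over reference
subjects.  Values are continuous in [0, 1], 1 meaning complete disconnection.
The per-subject result is a symmetric n_nodes x n_nodes matrix with zero
diagonal.

Edge matrices vectorize the upper triangle in fixed lexicographic order
((1,2), (1,3), ..., (1,n), (2,3), ...) with 1-based node ids; the order is
part of the on-disk format so matrices are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .vlsm import coverage_threshold

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import LesionMask, ReferencePathAtlas

logger = logging.getLogger("svrlsm")

__all__ = [
    "Disconnectome",
    "edge_pairs",
    "vectorize_edges",
    "devectorize_edges",
    "edge_disconnection",
    "batch_disconnectomes",
    "edge_coverage_mask",
    "cumulative_region_disconnection",
]


@dataclass
class Disconnectome:
    """Symmetric node x node proportional connectivity loss for one subject."""

    subject_id: str
    n_nodes: int
    values: np.ndarray
    unconnected_pairs: set = field(default_factory=set)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.n_nodes, self.n_nodes):
            raise ValueError(f"values shape {v.shape} != ({self.n_nodes},)*2")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("disconnectome must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("disconnectome diagonal must be exactly 0")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("disconnection values must lie in [0, 1]")
        self.values = v


def edge_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """Upper-triangle node pairs (1-based, i < j) in lexicographic order."""
    return [(i, j) for i in range(1, n_nodes + 1) for j in range(i + 1, n_nodes + 1)]


def vectorize_edges(matrix: np.ndarray) -> np.ndarray:
    """Flatten a symmetric node matrix to the canonical edge vector."""
    m = np.asarray(matrix)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def devectorize_edges(vector: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`; fills both triangles, zero diagonal."""
    vector = np.asarray(vector)
    if vector.shape[0] != n_nodes * (n_nodes - 1) // 2:
        raise ValueError(
            f"edge vector length {vector.shape[0]} does not match n_nodes={n_nodes}"
        )
    out = np.zeros((n_nodes, n_nodes), dtype=vector.dtype)
    iu = np.triu_indices(n_nodes, k=1)
    out[iu] = vector
    out[(iu[1], iu[0])] = vector
    return out


def edge_disconnection(lesion: "LesionMask", atlas: "ReferencePathAtlas") -> Disconnectome:
    """Proportional connectivity loss for every node pair of one lesion."""
    if tuple(lesion.mask.shape) != tuple(atlas.grid_shape):
        raise ValueError(
            f"lesion grid {lesion.mask.shape} does not match atlas grid "
            f"{atlas.grid_shape}"
        )
    flat = lesion.mask.reshape(-1).astype(float)
    idx, probs, seg_starts, pair_ids = atlas.flat_segments()
    n = atlas.n_nodes
    n_pairs = n * (n - 1) // 2
    unconnected = set()
    if idx.size:
        contrib = probs * flat[idx]
        seg_loss = np.add.reduceat(contrib, seg_starts)
        seg_total = np.add.reduceat(probs, seg_starts)
        ratio = np.divide(seg_loss, seg_total,
                          out=np.zeros_like(seg_loss), where=seg_total > 0)
        # Mean of per-reference losses within each pair.
        sums = np.bincount(pair_ids, weights=ratio, minlength=n_pairs)
        counts = np.bincount(pair_ids, minlength=n_pairs)
        pair_values = np.divide(sums, counts, out=np.zeros(n_pairs),
                                where=counts > 0)
        values = devectorize_edges(pair_values, n)
        for k, pair in enumerate(edge_pairs(n)):
            if counts[k] == 0:
                unconnected.add(pair)
    else:
        values = np.zeros((n, n))
        unconnected = set(edge_pairs(n))
    values = np.clip(values, 0.0, 1.0)
    return Disconnectome(subject_id=lesion.subject_id, n_nodes=n,
                         values=values, unconnected_pairs=unconnected)


def batch_disconnectomes(lesions, atlas: "ReferencePathAtlas") -> np.ndarray:
    """Subjects x edges matrix of disconnection (canonical edge order)."""
    rows = []
    for les in lesions:
        disc = edge_disconnection(les, atlas)
        rows.append(vectorize_edges(disc.values))
    return np.stack(rows)


def edge_coverage_mask(edge_matrix: np.ndarray, n_subjects: int,
                       min_fraction: float = 0.10,
                       min_disconnect: float = 0.0) -> np.ndarray:
    """Group-level edge inclusion, mirroring the voxel coverage rule.

    An edge counts as "lesioned" for a subject when its disconnection is
    strictly greater than min_disconnect (default 0); edges lesioned in at
    least floor(min_fraction * n) subjects are included.
    """
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must be in (0, 1)")
    mat = np.asarray(edge_matrix, dtype=float)
    counts = (mat > min_disconnect).sum(axis=0)
    return counts >= coverage_threshold(n_subjects, min_fraction)


def cumulative_region_disconnection(disconnectome: Disconnectome,
                                    region_nodes) -> float:
    """Total disconnection of edges touching a region (each edge once).

    Sums the disconnection value of every unique edge with at least one
    endpoint in region_nodes, the nuisance covariate used to control for
    gross regional disconnection in the edge-level analysis.
    """
    region = {int(r) for r in region_nodes}
    if not region:
        raise ValueError("region_nodes must be non-empty")
    bad = region - set(range(1, disconnectome.n_nodes + 1))
    if bad:
        raise ValueError(f"region nodes outside parcellation: {sorted(bad)}")
    total = 0.0
    for (i, j) in edge_pairs(disconnectome.n_nodes):
        if i in region or j in region:
            total += float(disconnectome.values[i - 1, j - 1])
    return total
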