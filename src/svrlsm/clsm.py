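"""Edge-level SVR connectome-based lesion-symptom mapping.

Edge disconnection values are first residualized on three nuisance factors
(cumulative disconnection of the regions flagged by the voxel-level
analysis, total lesion volume, months post-stroke), then entered into the
same cross-validated SVR + permutation machinery as the voxel analysis.
The permutation shuffles the behavioral residual vector; the nuisance
regression is computed once outside the loop.

Surviving edges (z strictly below the one-tailed threshold) form a weighted
graph with weight |z|; the maximally disconnected subgraph is the connected
subgraph of greatest total weight.  Because all weights are positive, the
optimum over connected subgraphs is attained by taking every edge of the
best connected component — the exact solver exploits this; a greedy solver
(expand outward from the heaviest edge) is provided for comparison and for
very large graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .behavior import ResidualScores
from .disconnectome import devectorize_edges, edge_pairs
from .engine import SvrConfig, permutation_zscores

logger = logging.getLogger("svrlsm")

__all__ = [
    "ZMatrix",
    "Subgraph",
    "nuisance_residualize_edges",
    "run_clsm",
    "significant_edges",
    "max_disconnected_subgraph",
    "node_disconnection_count",
]

#: Node-count bound below which the exact subgraph solver is used by "auto".
EXACT_SOLVER_MAX_NODES = 15


@dataclass
class ZMatrix:
    """Symmetric edge-level permutation z-scores (NaN where not included)."""

    n_nodes: int
    z: np.ndarray
    included_edges: np.ndarray
    threshold: float = -1.65

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("z matrix shape does not match n_nodes")
        defined = ~np.isnan(self.z)
        if not np.array_equal(defined, defined.T):
            raise ValueError("z definedness must be symmetric")
        if not np.allclose(self.z[defined], self.z.T[defined], atol=1e-12):
            raise ValueError("z matrix must be symmetric where defined")
        n_edges = self.n_nodes * (self.n_nodes - 1) // 2
        self.included_edges = np.asarray(self.included_edges, dtype=bool)
        if self.included_edges.shape != (n_edges,):
            raise ValueError("included_edges must be an edge vector")


@dataclass
class Subgraph:
    nodes: set = field(default_factory=set)
    edges: dict = field(default_factory=dict)   # (i, j) i<j -> weight
    total_weight: float = 0.0
    node_degree_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (i, j) in self.edges:
            if i not in self.nodes or j not in self.nodes:
                raise ValueError(f"edge {(i, j)} endpoint outside node set")


def nuisance_residualize_edges(edge_matrix: np.ndarray, covariates: dict) -> np.ndarray:
    """Per-edge OLS residuals after removing nuisance covariates.

    covariates maps names to per-subject vectors; an intercept is always
    included.  Residual columns are orthogonal to every covariate.
    """
    mat = np.asarray(edge_matrix, dtype=float)
    if not covariates:
        raise ValueError("at least one covariate is required")
    n = mat.shape[0]
    names = list(covariates)
    cols = []
    for name in names:
        v = np.asarray(covariates[name], dtype=float)
        if v.shape != (n,):
            raise ValueError(f"covariate {name!r} has shape {v.shape}, expected ({n},)")
        if np.std(v) == 0:
            raise ValueError(f"covariate {name!r} has zero variance")
        cols.append(v)
    design = np.column_stack([np.ones(n)] + cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # Name a collinear pair for the error message.
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                sub = np.column_stack([np.ones(n), cols[a], cols[b]])
                if np.linalg.matrix_rank(sub) < 3:
                    raise ValueError(
                        f"collinear covariates: {names[a]!r} and {names[b]!r}"
                    )
        raise ValueError("rank-deficient nuisance design")
    beta, *_ = np.linalg.lstsq(design, mat, rcond=None)
    return mat - design @ beta


def run_clsm(residual_edges: np.ndarray, target: ResidualScores,
             config: SvrConfig, included_edges: Optional[np.ndarray] = None,
             z_threshold: float = -1.65) -> ZMatrix:
    """Permutation z-matrix over included edge features.

    residual_edges has one column per canonical edge (all node pairs);
    included_edges selects the columns entered into the SVR.  Columns not
    included come back NaN in the z matrix.
    """
    mat = np.asarray(residual_edges, dtype=float)
    n_edges = mat.shape[1]
    n_nodes = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if n_nodes * (n_nodes - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} columns is not a triangular number")
    if included_edges is None:
        included_edges = mat.std(axis=0) > 0
    included_edges = np.asarray(included_edges, dtype=bool)
    if not included_edges.any():
        raise ValueError("no edges included")
    values = np.asarray(target.values, dtype=float)
    if values.shape[0] != mat.shape[0]:
        raise ValueError("subjects misaligned between edges and target")
    pairs = edge_pairs(n_nodes)
    ids = [pairs[k] for k in np.flatnonzero(included_edges)]
    logger.info("CLSM: n=%d subjects, %d/%d edges included, %d permutations",
                mat.shape[0], len(ids), n_edges, config.n_permutations)
    wm = permutation_zscores(mat[:, included_edges], values, config,
                             feature_ids=ids)
    z_vec = np.full(n_edges, np.nan)
    z_vec[included_edges] = wm.z_scores
    z = devectorize_edges(z_vec, n_nodes)
    np.fill_diagonal(z, np.nan)
    return ZMatrix(n_nodes=n_nodes, z=z, included_edges=included_edges,
                   threshold=z_threshold)


def significant_edges(zmat: ZMatrix, thresh: float = -1.65) -> dict:
    """Undirected edges with z strictly below the threshold, weighted by |z|."""
    out = {}
    for k, (i, j) in enumerate(edge_pairs(zmat.n_nodes)):
        zij = zmat.z[i - 1, j - 1]
        if np.isfinite(zij) and zij < thresh:
            out[(i, j)] = abs(float(zij))
    return out


def _subgraph_from_edges(edges: dict) -> Subgraph:
    nodes = set()
    for (i, j) in edges:
        nodes.update((i, j))
    degrees = {n: 0 for n in nodes}
    for (i, j) in edges:
        degrees[i] += 1
        degrees[j] += 1
    return Subgraph(nodes=nodes, edges=dict(edges),
                    total_weight=float(sum(edges.values())),
                    node_degree_counts=degrees)


def _exact_max_subgraph(edges: dict) -> Subgraph:
    """Maximum-total-weight connected subgraph, exact.

    With strictly positive weights any connected subgraph can be extended
    edge-by-edge within its component without losing weight, so the optimum
    is the full edge set of the best-scoring connected component.
    """
    g = nx.Graph()
    for (i, j), w in edges.items():
        g.add_edge(i, j, weight=w)
    best, best_weight = {}, -np.inf
    for comp in nx.connected_components(g):
        comp_edges = {
            (min(i, j), max(i, j)): d["weight"]
            for i, j, d in g.subgraph(comp).edges(data=True)
        }
        weight = sum(comp_edges.values())
        if weight > best_weight:
            best, best_weight = comp_edges, weight
    return _subgraph_from_edges(best)


def _greedy_max_subgraph(edges: dict) -> Subgraph:
    """Greedy expansion from the heaviest edge."""
    remaining = dict(edges)
    start = max(remaining, key=lambda e: (remaining[e], -e[0], -e[1]))
    chosen = {start: remaining.pop(start)}
    nodes = set(start)
    while True:
        adjacent = {e: w for e, w in remaining.items()
                    if e[0] in nodes or e[1] in nodes}
        if not adjacent:
            break
        nxt = max(adjacent, key=lambda e: (adjacent[e], -e[0], -e[1]))
        chosen[nxt] = remaining.pop(nxt)
        nodes.update(nxt)
    return _subgraph_from_edges(chosen)


def max_disconnected_subgraph(edges: dict, solver: str = "auto") -> Subgraph:
    """Connected subgraph of significant edges maximizing total |z| weight."""
    if not edges:
        return Subgraph()
    for e, w in edges.items():
        if w <= 0:
            raise ValueError(f"edge {e} has non-positive weight {w}")
    n_nodes = len({n for e in edges for n in e})
    if solver == "auto":
        solver = "exact" if n_nodes <= EXACT_SOLVER_MAX_NODES else "greedy"
    logger.info("subgraph solver: %s (%d nodes, %d edges)",
                solver, n_nodes, len(edges))
    if solver == "exact":
        return _exact_max_subgraph(edges)
    if solver == "greedy":
        return _greedy_max_subgraph(edges)
    raise ValueError(f"unknown solver {solver!r}")


def node_disconnection_count(edges: dict, n_nodes: Optional[int] = None) -> dict:
    """Count of surviving edges incident to each node (handshake-consistent)."""
    counts = {n: 0 for n in range(1, n_nodes + 1)} if n_nodes else {}
    for (i, j) in edges:
        counts[i] = counts.get(i, 0) + 1
        counts[j] = counts.get(j, 0) + 1
    return counts
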