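"""Post-hoc seed-node disconnection screening.

Given a seed node (in the motivating use case, the left inferior parietal
lobule flagged by the subgraph analysis), each remote node's residual
disconnection from the seed is screened by three sequential criteria:

1. the remote node lies essentially outside the lesion territory (< 1% of
   its voxels lesioned in any subject), so weak signal at the remote site
   cannot drive the correlation;
2. the seed-remote disconnection column correlates negatively with the
   behavioral residual (one-tailed p < 0.05 — at n = 57 the pass boundary
   is r ~ -0.22);
3. the true correlation sits at least 2 SD below the mean of a Monte-Carlo
   permutation null for that edge (z < -1.96).

The final pass set is the conjunction of the three; all diagnostic rows are
retained in the report.

Note: the source description of criterion 2 prints the p inequality as
"P > 0.05", which contradicts the accompanying "minimum r < -0.22" at
n = 57; it is treated as a misprint and implemented as p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import ResidualScores, one_tailed_p_negative
from .disconnectome import edge_pairs

logger = logging.getLogger("svrlsm")

__all__ = [
    "SeedReport",
    "node_lesion_overlap_fraction",
    "seed_edge_screen",
    "seed_permutation_z",
    "build_seed_report",
]

REPORT_HEADER_NOTE = (
    "criterion 2: one-tailed p < 0.05 for negative r "
    "(source's 'P > 0.05' read as a misprint)"
)


@dataclass
class SeedReport:
    seed_node: int
    rows: pd.DataFrame
    note: str = REPORT_HEADER_NOTE

    def passing_nodes(self) -> list:
        return [int(r) for r in self.rows.loc[self.rows["passed_all"], "remote_node"]]


def node_lesion_overlap_fraction(node_voxel_idx, overlap_map: np.ndarray,
                                 weighted: bool = False,
                                 n_subjects: int | None = None) -> float:
    """Fraction of a node's voxels lesioned in at least one subject.

    With ``weighted=True`` the fraction is instead weighted by how many
    subjects lesion each voxel (mean overlap count divided by the cohort
    size), a stricter reading of "overlap with the lesion overlap map".
    """
    idx = np.asarray(node_voxel_idx, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("node voxel set is empty")
    flat = np.asarray(overlap_map).reshape(-1)
    if weighted:
        if n_subjects is None or n_subjects < 1:
            raise ValueError("weighted overlap requires n_subjects")
        return float(flat[idx].mean() / n_subjects)
    return float((flat[idx] >= 1).mean())


def _seed_columns(n_nodes: int, seed_node: int, included: np.ndarray):
    """Edge-vector column index and remote node for each seed-incident edge."""
    cols, remotes = [], []
    for k, (i, j) in enumerate(edge_pairs(n_nodes)):
        if seed_node in (i, j) and included[k]:
            cols.append(k)
            remotes.append(j if i == seed_node else i)
    return cols, remotes


def seed_edge_screen(residual_edges: np.ndarray, seed_node: int,
                     target: ResidualScores, n_nodes: int,
                     included_edges=None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-remote-node correlation screen (criterion 2).

    Pearson r between each seed-remote residual disconnection column and
    the behavioral residual, with a one-tailed p for negative r.
    """
    mat = np.asarray(residual_edges, dtype=float)
    y = np.asarray(target.values, dtype=float)
    n = y.shape[0]
    n_edges = n_nodes * (n_nodes - 1) // 2
    if included_edges is None:
        included_edges = np.ones(n_edges, dtype=bool)
    included_edges = np.asarray(included_edges, dtype=bool)
    cols, remotes = _seed_columns(n_nodes, seed_node, included_edges)
    if not cols:
        raise ValueError(f"seed node {seed_node} has no included edges")
    rows = []
    for col, remote in zip(cols, remotes):
        x = mat[:, col]
        if np.std(x) == 0:
            rows.append({"remote_node": remote, "edge_column": col,
                         "r": np.nan, "one_tailed_p": np.nan,
                         "zero_variance": True, "passed_screen": False})
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        p = one_tailed_p_negative(r, n)
        rows.append({"remote_node": remote, "edge_column": col,
                     "r": r, "one_tailed_p": p, "zero_variance": False,
                     "passed_screen": bool(p < alpha)})
    return pd.DataFrame(rows)


def seed_permutation_z(residual_edges: np.ndarray, seed_node: int,
                       target: ResidualScores, n_nodes: int,
                       included_edges=None, n_permutations: int = 10000,
                       seed: int = 0) -> pd.DataFrame:
    """Permutation z of each seed-remote correlation (criterion 3).

    The behavioral residual is shuffled across subjects; the null is the
    resulting distribution of the edge-behavior correlation, and
    z = (r_true - mean_null) / sd_null.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    mat = np.asarray(residual_edges, dtype=float)
    y = np.asarray(target.values, dtype=float)
    n = y.shape[0]
    n_edges = n_nodes * (n_nodes - 1) // 2
    if included_edges is None:
        included_edges = np.ones(n_edges, dtype=bool)
    included_edges = np.asarray(included_edges, dtype=bool)
    cols, remotes = _seed_columns(n_nodes, seed_node, included_edges)
    if not cols:
        raise ValueError(f"seed node {seed_node} has no included edges")
    X = mat[:, cols]
    sd_x = X.std(axis=0, ddof=1)
    nonzero = sd_x > 0
    Zx = np.zeros_like(X)
    Zx[:, nonzero] = (X[:, nonzero] - X[:, nonzero].mean(axis=0)) / sd_x[nonzero]
    zy = (y - y.mean()) / y.std(ddof=1)
    r_true = Zx.T @ zy / (n - 1)

    rng = np.random.default_rng(seed)
    perm_targets = np.stack([zy[rng.permutation(n)] for _ in range(n_permutations)],
                            axis=1)
    r_null = Zx.T @ perm_targets / (n - 1)   # edges x permutations
    null_mean = r_null.mean(axis=1)
    null_sd = r_null.std(axis=1, ddof=1)
    degenerate = (null_sd <= 0) | ~nonzero
    z = np.where(degenerate, 0.0,
                 (r_true - null_mean) / np.where(degenerate, 1.0, null_sd))
    return pd.DataFrame({
        "remote_node": remotes,
        "edge_column": cols,
        "r": np.where(nonzero, r_true, np.nan),
        "z": z,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "degenerate_null": degenerate,
    })


def build_seed_report(parcellation, overlap_map: np.ndarray,
                      residual_edges: np.ndarray, seed_node: int,
                      target: ResidualScores, included_edges=None,
                      overlap_threshold: float = 0.01, alpha: float = 0.05,
                      z_threshold: float = -1.96, n_permutations: int = 10000,
                      seed: int = 0) -> SeedReport:
    """Join the three criteria into a per-remote-node report.

    The criteria form a pure conjunction; passed_all is their AND and does
    not depend on evaluation order.
    """
    from .synthetic import node_voxels

    screen = seed_edge_screen(residual_edges, seed_node, target,
                              parcellation.n_nodes, included_edges, alpha)
    perm = seed_permutation_z(residual_edges, seed_node, target,
                              parcellation.n_nodes, included_edges,
                              n_permutations, seed)
    merged = screen.merge(
        perm[["remote_node", "edge_column", "z", "degenerate_null"]],
        on=["remote_node", "edge_column"], how="left",
    )
    overlaps = {
        int(node): node_lesion_overlap_fraction(
            node_voxels(parcellation, int(node)), overlap_map)
        for node in merged["remote_node"].unique()
    }
    merged["lesion_overlap_fraction"] = merged["remote_node"].map(overlaps)
    merged["passed_outside_territory"] = merged["lesion_overlap_fraction"] < overlap_threshold
    merged["passed_permutation"] = merged["z"] < z_threshold
    merged["passed_all"] = (
        merged["passed_outside_territory"]
        & merged["passed_screen"]
        & merged["passed_permutation"]
    )
    merged = merged.sort_values("remote_node").reset_index(drop=True)
    logger.info("seed %d: %d/%d remote nodes pass all three criteria",
                seed_node, int(merged["passed_all"].sum()), len(merged))
    return SeedReport(seed_node=seed_node, rows=merged)
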