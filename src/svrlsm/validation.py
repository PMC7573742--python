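"""Validation experiments: calibration, planted-effect recovery, oracles.

The study this package models cannot ship its lesions or disconnectomes, so
the imaging analyses are validated by properties rather than by reproducing
printed maps:

* permutation calibration — on null cohorts (no planted effect) the
  fraction of voxels/edges with z below the one-tailed 5% threshold must
  sit near 5%;
* planted-signal recovery — a cohort with a strong planted voxel effect
  must yield a top VLSM cluster that overlaps the planted region (Dice),
  and a planted edge effect must surface among the most negative CLSM
  z-scores, across a majority of seeds;
* exact-solver, loss-formula and OLS oracles — closed-form or enumerative
  checks of the deterministic primitives.

Each experiment is a pure function of its seed and returns plain dicts, so
the same procedures back both the test suite and the reporting script.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import numpy as np
from scipy import ndimage

from .behavior import residualize
from .clsm import max_disconnected_subgraph, nuisance_residualize_edges, run_clsm
from .disconnectome import (Disconnectome, batch_disconnectomes,
                            cumulative_region_disconnection, devectorize_edges,
                            edge_coverage_mask, edge_disconnection, edge_pairs)
from .engine import SvrConfig
from .pipeline import RunConfig, _analysis_targets, run_full_pipeline
from .synthetic import (LesionMask, ReferencePathAtlas, default_planted_model,
                        default_territory, generate_cohort, generate_lesion,
                        generate_parcellation, generate_reference_paths,
                        null_planted_model)
from .vlsm import VlsmThresholds, coverage_threshold, dtlvc_scale, run_vlsm

logger = logging.getLogger("svrlsm")

__all__ = [
    "null_calibration",
    "planted_recovery",
    "subgraph_enumeration_check",
    "disconnection_formula_checks",
    "residualization_checks",
    "fusiform_dissociation_case",
]

Z_ONE_TAILED_05 = -1.65


def _study_geometry(seed: int, grid=(32, 32, 32), n_nodes=12, n_reference=20):
    parcellation = generate_parcellation(grid, n_nodes, seed)
    atlas = generate_reference_paths(parcellation, n_reference=n_reference,
                                     jitter_sd=1.0, seed=seed + 1)
    return parcellation, atlas


def _dominant_territory_node(parcellation) -> int:
    territory = default_territory(parcellation.grid_shape).reshape(-1)
    labels = parcellation.labels.reshape(-1)
    counts = [int((territory & (labels == k + 1)).sum())
              for k in range(parcellation.n_nodes)]
    return int(np.argmax(counts)) + 1


def null_calibration(n_seeds: int = 20, n_permutations: int = 500,
                     base_seed: int = 0, n_subjects: int = 57) -> dict:
    """False-positive rate of the voxel and edge permutation z-maps.

    Cohorts carry no planted effect, so behavior is independent of lesion
    geometry; a calibrated one-tailed test at z < -1.65 should flag about
    5% of features.  Fractions are pooled over seeds.
    """
    parcellation, atlas = _study_geometry(base_seed + 901_000)
    model = null_planted_model()
    nuisance_node = _dominant_territory_node(parcellation)
    voxel_counts = np.zeros(2, dtype=np.int64)  # (below threshold, total)
    edge_counts = np.zeros(2, dtype=np.int64)
    per_seed_voxel, per_seed_edge = [], []
    for s in range(n_seeds):
        seed = base_seed + 1000 + s
        lesions, behavior = generate_cohort(parcellation, atlas, model,
                                            n_subjects=n_subjects, seed=seed)
        vlsm_target, clsm_target, _ = _analysis_targets(behavior, "tool_use")
        cfg = SvrConfig(n_permutations=n_permutations, seed=seed)

        # Voxel side: z-scores over the coverage mask, no clustering.
        mat = np.stack([l.mask.reshape(-1) for l in lesions]).astype(float)
        mask = mat.sum(axis=0) >= coverage_threshold(n_subjects, 0.10)
        X = dtlvc_scale(mat)[:, mask]
        from .engine import permutation_zscores
        wm = permutation_zscores(X, vlsm_target.values, cfg)
        valid = ~wm.degenerate
        frac_v = float((wm.z_scores[valid] < Z_ONE_TAILED_05).mean())
        voxel_counts += [(wm.z_scores[valid] < Z_ONE_TAILED_05).sum(), valid.sum()]
        per_seed_voxel.append(frac_v)

        # Edge side: three-factor nuisance, then the permutation z-matrix.
        edge_matrix = batch_disconnectomes(lesions, atlas)
        included = edge_coverage_mask(edge_matrix, n_subjects)
        cumulative = np.array([
            cumulative_region_disconnection(
                Disconnectome(l.subject_id, atlas.n_nodes,
                              devectorize_edges(edge_matrix[k], atlas.n_nodes)),
                {nuisance_node})
            for k, l in enumerate(lesions)
        ])
        residual = nuisance_residualize_edges(edge_matrix, {
            "cumulative": cumulative,
            "lesion_volume": behavior["lesion_volume"].to_numpy(float),
            "months_post": behavior["months_post"].to_numpy(float),
        })
        zmat = run_clsm(residual, clsm_target, cfg, included_edges=included)
        zvec = np.array([zmat.z[i - 1, j - 1]
                         for (i, j) in edge_pairs(atlas.n_nodes)])
        zvec = zvec[np.isfinite(zvec)]
        frac_e = float((zvec < Z_ONE_TAILED_05).mean())
        edge_counts += [(zvec < Z_ONE_TAILED_05).sum(), zvec.size]
        per_seed_edge.append(frac_e)
        logger.info("null calibration seed %d: voxel %.3f, edge %.3f",
                    s, frac_v, frac_e)
    return {
        "voxel_fraction": float(voxel_counts[0] / voxel_counts[1]),
        "edge_fraction": float(edge_counts[0] / edge_counts[1]),
        "per_seed_voxel": per_seed_voxel,
        "per_seed_edge": per_seed_edge,
        "n_seeds": n_seeds,
        "n_permutations": n_permutations,
    }


def _dice(top_cluster, grid_shape, target_set: np.ndarray) -> float:
    cluster = set(np.ravel_multi_index(top_cluster.voxels.T, grid_shape).tolist())
    target = set(np.asarray(target_set).tolist())
    if not cluster and not target:
        return 1.0
    return 2 * len(cluster & target) / (len(cluster) + len(target))


def planted_recovery(n_seeds: int = 20, n_permutations: int = 200,
                     base_seed: int = 0, n_subjects: int = 57,
                     top_k: int = 3) -> dict:
    """Recovery of planted effects, one fresh study geometry per seed.

    Each channel is validated on a cohort that isolates it, with noise-free
    scores so failures reflect the mapping machinery rather than sampling
    noise.  Voxel channel: a strong voxel effect (no edge effect); the VLSM
    map must localize the planted region — measured as Dice of the top
    cluster against the planted voxel set.  Edge channel: a strong edge
    effect (no voxel effect) pushed through the full pipeline (VLSM
    localizer, three-factor nuisance regression, CLSM) — measured as the
    rank of the planted edge among the most negative z-scores.  Mixing the
    two channels in one score is avoided deliberately: the voxel effect
    smears the z-map along the edge's path corridor and the edge's
    disconnection can be nearly collinear with region load plus lesion
    volume, making the combined planting unidentifiable on some geometries.
    """
    dices, ranks = [], []
    for s in range(n_seeds):
        seed = base_seed + 2000 + s
        parcellation, atlas = _study_geometry(seed)

        # --- voxel-effect cohort -------------------------------------------
        # Single-channel isolation: no edge effect and no volume-severity
        # channel, so the voxel map reflects the planted region alone.
        vox_model = default_planted_model(parcellation, noise_sd=0.0)
        vox_model.effect_sizes = dict(vox_model.effect_sizes, edge=0.0,
                                      volume=0.0, volume_control=0.0)
        lesions, behavior = generate_cohort(parcellation, atlas, vox_model,
                                            n_subjects=n_subjects, seed=seed + 10)
        vlsm_target, _, _ = _analysis_targets(behavior, "tool_use")
        stat_map = run_vlsm(lesions, vlsm_target,
                            SvrConfig(n_permutations=n_permutations, seed=seed),
                            VlsmThresholds())
        dice = (_dice(stat_map.clusters[0], parcellation.grid_shape,
                      vox_model.target_voxel_set)
                if stat_map.clusters else 0.0)
        dices.append(dice)

        # --- edge-effect cohort through the full pipeline ------------------
        edge_model = default_planted_model(parcellation, noise_sd=0.0)
        edge_model.effect_sizes = dict(edge_model.effect_sizes, voxel=0.0,
                                       volume=0.0, volume_control=0.0)
        lesions_e, behavior_e = generate_cohort(parcellation, atlas, edge_model,
                                                n_subjects=n_subjects,
                                                seed=seed + 20)
        cfg = RunConfig(analysis="tool_use",
                        svr=SvrConfig(n_permutations=n_permutations, seed=seed),
                        seed=seed)
        result = run_full_pipeline(cfg, parcellation, atlas, lesions_e,
                                   behavior_e)
        pairs = edge_pairs(atlas.n_nodes)
        zvec = np.array([result.zmatrix.z[i - 1, j - 1] for (i, j) in pairs])
        order = np.argsort(np.where(np.isfinite(zvec), zvec, np.inf))
        planted_idx = pairs.index(edge_model.target_edges[0])
        rank = int(np.where(order == planted_idx)[0][0]) + 1
        ranks.append(rank)
        logger.info("recovery seed %d: dice %.3f, planted edge rank %d",
                    s, dice, rank)
    return {
        "dice": dices,
        "dice_pass": int(sum(d > 0.5 for d in dices)),
        "edge_rank": ranks,
        "edge_rank_pass": int(sum(r <= top_k for r in ranks)),
        "n_seeds": n_seeds,
    }


def _enumerate_max_connected_weight(edges: dict) -> float:
    best = 0.0
    edge_list = list(edges)
    for r in range(1, len(edge_list) + 1):
        for subset in itertools.combinations(edge_list, r):
            g = nx.Graph(subset)
            if nx.is_connected(g):
                best = max(best, sum(edges[e] for e in subset))
    return best


def subgraph_enumeration_check(n_graphs: int = 100, base_seed: int = 0,
                               max_nodes: int = 6) -> dict:
    """Exact solver vs exhaustive enumeration on small random weighted graphs."""
    rng = np.random.default_rng(base_seed + 3000)
    matches = 0
    tested = 0
    while tested < n_graphs:
        n = int(rng.integers(2, max_nodes + 1))
        pairs = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
        keep = rng.random(len(pairs)) < 0.5
        edges = {p: float(rng.random() + 0.01)
                 for p, k in zip(pairs, keep) if k}
        if not edges:
            continue
        tested += 1
        solver = max_disconnected_subgraph(edges, solver="exact").total_weight
        oracle = _enumerate_max_connected_weight(edges)
        matches += bool(abs(solver - oracle) < 1e-9)
    return {"matches": matches, "n_graphs": n_graphs}


def disconnection_formula_checks(n_pairs: int = 1000, base_seed: int = 0) -> dict:
    """Hand-computed loss case plus monotonicity under lesion growth."""
    # Toy path {v1: 0.5, v2: 0.3, v3: 0.2}, lesion {v1, v3} -> loss 0.7.
    grid = (6, 6, 6)
    flat = lambda c: np.ravel_multi_index(c, grid)
    atlas = ReferencePathAtlas(
        grid_shape=grid, n_nodes=2, n_reference=1,
        paths={(1, 2): [(np.array([flat((0, 0, 0)), flat((1, 0, 0)),
                                   flat((2, 0, 0))], dtype=np.intp),
                         np.array([0.5, 0.3, 0.2]))]},
    )
    mask = np.zeros(grid, dtype=np.uint8)
    mask[0, 0, 0] = mask[2, 0, 0] = 1
    toy_loss = float(edge_disconnection(LesionMask("toy", mask), atlas)
                     .values[0, 1])
    toy_error = abs(toy_loss - 0.7)

    # Monotonicity: enlarging a lesion never decreases any edge value.
    parcellation, growth_atlas = _study_geometry(base_seed + 4000,
                                                 grid=(20, 20, 20), n_nodes=6,
                                                 n_reference=3)
    territory = default_territory(parcellation.grid_shape)
    rng = np.random.default_rng(base_seed + 4001)
    violations = 0
    for k in range(n_pairs):
        small = generate_lesion(parcellation, territory,
                                int(rng.integers(10, 150)),
                                seed=int(rng.integers(2**31 - 1)))
        grown = ndimage.binary_dilation(small.mask).astype(np.uint8)
        d_small = edge_disconnection(small, growth_atlas).values
        d_big = edge_disconnection(LesionMask("g", grown), growth_atlas).values
        violations += int(np.any(d_big < d_small - 1e-12))
    return {"toy_loss": toy_loss, "toy_error": toy_error,
            "monotonicity_violations": violations, "n_pairs": n_pairs}


def residualization_checks(n_random: int = 50, base_seed: int = 0) -> dict:
    """OLS residuals against closed-form normal-equation solutions."""
    errors = []
    # Hand case: y = [1, 2, 4] on x = [1, 2, 3] -> [1/6, -1/3, 1/6].
    res = residualize([1.0, 2.0, 4.0], [1.0, 2.0, 3.0])
    errors.append(float(np.abs(res.values - np.array([1 / 6, -1 / 3, 1 / 6])).max()))
    rng = np.random.default_rng(base_seed + 5000)
    for _ in range(n_random):
        n = int(rng.integers(8, 60))
        p = int(rng.integers(1, 4))
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        res = residualize(y, *(X[:, j] for j in range(p)))
        design = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        errors.append(float(np.abs(res.values - (y - design @ beta)).max()))
    return {"max_abs_error": max(errors), "n_cases": len(errors)}


def fusiform_dissociation_case(base_seed: int = 0,
                               n_permutations: int = 10_000) -> dict:
    """An edge that passes the correlation screen but fails the permutation z.

    Constructs a seed-remote disconnection column whose sample correlation
    with behavior is exactly -0.24 at n = 57.  One-tailed p is then about
    0.036 (< 0.05, screen passed) while the permutation z is about
    r * sqrt(n - 1) = -1.80 (> -1.96, permutation criterion failed) — the
    structural pattern of a borderline remote node.
    """
    from .behavior import ResidualScores
    from .seed import build_seed_report

    n, r_target = 57, -0.24
    rng = np.random.default_rng(base_seed + 6000)
    y = rng.normal(size=n)
    zy = (y - y.mean()) / y.std(ddof=1)
    raw = rng.normal(size=n)
    orth = raw - (raw @ zy) / (zy @ zy) * zy
    orth = (orth - orth.mean()) / orth.std(ddof=1)
    x = r_target * zy + np.sqrt(1 - r_target**2) * orth

    # Two-node parcellation: node 2 is the remote node, untouched by lesions.
    grid = (8, 8, 8)
    labels = np.zeros(grid, dtype=int)
    labels[:4] = 1
    labels[4:] = 2
    from .synthetic import Parcellation
    parcellation = Parcellation(
        grid_shape=grid, labels=labels, node_names=["seed", "remote"],
        node_centroids=np.array([[2.0, 4, 4], [6.0, 4, 4]]))
    overlap = np.zeros(grid, dtype=int)
    overlap[:2] = 5  # lesions confined to the seed side
    target = ResidualScores(list(range(n)), y - y.mean())
    report = build_seed_report(parcellation, overlap, x[:, None], seed_node=1,
                               target=target, n_permutations=n_permutations,
                               seed=base_seed + 6001)
    row = report.rows.iloc[0]
    return {
        "r": float(row["r"]),
        "one_tailed_p": float(row["one_tailed_p"]),
        "z": float(row["z"]),
        "passed_screen": bool(row["passed_screen"]),
        "passed_permutation": bool(row["passed_permutation"]),
        "classified_as_dissociation": bool(row["passed_screen"]
                                           and not row["passed_permutation"]),
    }
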