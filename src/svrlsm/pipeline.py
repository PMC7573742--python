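"""End-to-end orchestration of the two mapping analyses.

``run_full_pipeline`` wires the stages together for either analysis:

tool_use: gts_hp residualized on imi_hp (VLSM) and on imi_hp + lesion
volume (CLSM); grip: rh_grip residualized on lh_grip (VLSM) and on
lh_grip + lesion volume (CLSM), restricted to subjects with complete grip
scores.

Stage order: behavior preparation -> voxel-level SVR mapping -> extraction
of the significant region set ("localizer") -> disconnectome construction
-> three-factor nuisance regression (cumulative localizer-region
disconnection, lesion volume, months post) -> edge-level SVR mapping ->
maximally disconnected subgraph -> optional seed-node screening.  Every
output directory receives a manifest with seeds and a config hash.
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io as sio
from .behavior import pearson_r, residualize
from .clsm import (max_disconnected_subgraph, node_disconnection_count,
                   nuisance_residualize_edges, run_clsm, significant_edges)
from .disconnectome import (batch_disconnectomes, cumulative_region_disconnection,
                            edge_coverage_mask, edge_pairs, Disconnectome,
                            devectorize_edges)
from .engine import SvrConfig
from .seed import build_seed_report
from .synthetic import (LesionMask, Parcellation, ReferencePathAtlas,
                        default_planted_model, default_territory,
                        generate_cohort, generate_parcellation,
                        generate_reference_paths)
from .vlsm import VlsmThresholds, label_clusters, lesion_overlap_map, run_vlsm

logger = logging.getLogger("svrlsm")

__all__ = ["RunConfig", "PipelineResult", "run_full_pipeline", "simulate_inputs"]

ANALYSES = ("tool_use", "grip")


@dataclass
class RunConfig:
    analysis: str = "tool_use"
    svr: SvrConfig = field(default_factory=SvrConfig)
    thresholds: VlsmThresholds = field(default_factory=VlsmThresholds)
    edge_min_fraction: float = 0.10
    edge_min_disconnect: float = 0.0
    clsm_z_threshold: float = -1.65
    subgraph_solver: str = "auto"
    seed_node: Optional[int] = None
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ValueError(f"analysis must be one of {ANALYSES}")

    def as_dict(self) -> dict:
        # outdir is location metadata, not analysis configuration; dropping
        # it keeps manifests identical across output locations.
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        return d


@dataclass
class PipelineResult:
    behavior: pd.DataFrame
    vlsm_target: object = None
    clsm_target: object = None
    stat_map: object = None
    cluster_table: Optional[pd.DataFrame] = None
    localizer_nodes: Optional[list] = None
    edge_matrix: Optional[np.ndarray] = None
    included_edges: Optional[np.ndarray] = None
    residual_edges: Optional[np.ndarray] = None
    zmatrix: object = None
    subgraph: object = None
    node_counts: Optional[dict] = None
    seed_report: object = None
    skipped: list = field(default_factory=list)
    behavior_summary: dict = field(default_factory=dict)


def simulate_inputs(seed: int, grid_shape=(32, 32, 32), n_nodes: int = 12,
                    n_subjects: int = 57, n_reference: int = 20,
                    effect_scale: float = 1.0, model=None):
    """Generate a complete synthetic study (parcellation, atlas, cohort)."""
    parcellation = generate_parcellation(grid_shape, n_nodes, seed)
    atlas = generate_reference_paths(parcellation, n_reference=n_reference,
                                     jitter_sd=1.0, seed=seed + 1)
    if model is None:
        model = default_planted_model(parcellation, effect_scale=effect_scale)
    lesions, behavior = generate_cohort(parcellation, atlas, model,
                                        n_subjects=n_subjects, seed=seed + 2)
    return parcellation, atlas, model, lesions, behavior


def _analysis_targets(behavior: pd.DataFrame, analysis: str):
    """(VLSM residual, CLSM residual, retained row index) for an analysis."""
    if analysis == "tool_use":
        rows = behavior.dropna(subset=["gts_hp", "imi_hp"])
        y, ctrl = rows["gts_hp"].to_numpy(float), rows["imi_hp"].to_numpy(float)
        ctrl_name = "imi_hp"
    else:
        rows = behavior.dropna(subset=["rh_grip", "lh_grip"])
        y, ctrl = rows["rh_grip"].to_numpy(float), rows["lh_grip"].to_numpy(float)
        ctrl_name = "lh_grip"
    ids = list(rows["subject_id"])
    volume = rows["lesion_volume"].to_numpy(float)
    vlsm_target = residualize(y, ctrl, subject_ids=ids, names=[ctrl_name])
    clsm_target = residualize(y, ctrl, volume, subject_ids=ids,
                              names=[ctrl_name, "lesion_volume"])
    return vlsm_target, clsm_target, rows.index


def run_full_pipeline(config: RunConfig, parcellation: Parcellation = None,
                      atlas: ReferencePathAtlas = None, lesions=None,
                      behavior: pd.DataFrame = None) -> PipelineResult:
    """Run one analysis end to end; inputs default to a synthetic study."""
    if behavior is None:
        parcellation, atlas, _, lesions, behavior = simulate_inputs(config.seed)
    outdir = pathlib.Path(config.outdir) if config.outdir else None
    artifacts = []
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    vlsm_target, clsm_target, row_index = _analysis_targets(behavior, config.analysis)
    primary, control = (("gts_hp", "imi_hp") if config.analysis == "tool_use"
                        else ("rh_grip", "lh_grip"))
    rows = behavior.loc[row_index]
    summary = {
        "analysis": config.analysis,
        "n_subjects": int(len(rows)),
        "r_primary_control": pearson_r(rows[primary].to_numpy(float),
                                       rows[control].to_numpy(float)),
    }
    result = PipelineResult(behavior=behavior, vlsm_target=vlsm_target,
                            clsm_target=clsm_target, behavior_summary=summary)
    if outdir:
        path = outdir / "behavior_residuals.tsv"
        pd.DataFrame({
            "subject_id": vlsm_target.subject_ids,
            "vlsm_residual": vlsm_target.values,
            "clsm_residual": clsm_target.values,
        }).to_csv(path, sep="\t", index=False)
        artifacts.append(path)

    if lesions is None or parcellation is None or atlas is None:
        result.skipped.append(
            "imaging stages skipped: no lesion/parcellation/atlas inputs"
        )
        logger.warning(result.skipped[-1])
        if outdir:
            sio.write_manifest(outdir, config.as_dict(),
                               {"seed": config.seed}, artifacts)
        return result

    keep = list(row_index)
    lesions_used = [lesions[i] for i in keep]

    # --- voxel-level stage -------------------------------------------------
    stat_map = run_vlsm(lesions_used, vlsm_target, config.svr, config.thresholds)
    result.stat_map = stat_map
    cluster_table = label_clusters(stat_map, parcellation)
    result.cluster_table = cluster_table
    localizer = sorted(cluster_table["node_id"].unique().tolist())
    if not localizer:
        # No significant regions: fall back to the planted-model convention of
        # the territory's best-covered node so the nuisance stage stays sane.
        territory = default_territory(parcellation.grid_shape)
        labels_flat = parcellation.labels.reshape(-1)
        counts = [int((territory.reshape(-1) & (labels_flat == k + 1)).sum())
                  for k in range(parcellation.n_nodes)]
        localizer = [int(np.argmax(counts)) + 1]
        result.skipped.append("VLSM found no clusters; localizer fell back to "
                              "the dominant territory node")
    result.localizer_nodes = localizer

    # --- edge-level stage --------------------------------------------------
    edge_matrix = batch_disconnectomes(lesions_used, atlas)
    result.edge_matrix = edge_matrix
    included = edge_coverage_mask(edge_matrix, len(lesions_used),
                                  config.edge_min_fraction,
                                  config.edge_min_disconnect)
    result.included_edges = included
    cumulative = np.array([
        cumulative_region_disconnection(
            Disconnectome(subject_id=les.subject_id, n_nodes=atlas.n_nodes,
                          values=devectorize_edges(edge_matrix[s], atlas.n_nodes)),
            localizer)
        for s, les in enumerate(lesions_used)
    ])
    covariates = {
        "cumulative_localizer_disconnection": cumulative,
        "lesion_volume": rows["lesion_volume"].to_numpy(float),
        "months_post": rows["months_post"].to_numpy(float),
    }
    residual_edges = nuisance_residualize_edges(edge_matrix, covariates)
    result.residual_edges = residual_edges
    zmat = run_clsm(residual_edges, clsm_target, config.svr,
                    included_edges=included, z_threshold=config.clsm_z_threshold)
    result.zmatrix = zmat
    surviving = significant_edges(zmat, config.clsm_z_threshold)
    result.subgraph = max_disconnected_subgraph(surviving, config.subgraph_solver) \
        if surviving else None
    result.node_counts = node_disconnection_count(surviving, atlas.n_nodes)

    if config.seed_node is not None:
        overlap = lesion_overlap_map(lesions_used)
        result.seed_report = build_seed_report(
            parcellation, overlap, residual_edges, config.seed_node,
            clsm_target, included_edges=included,
            n_permutations=config.svr.n_permutations, seed=config.seed + 7,
        )

    # --- artifacts ---------------------------------------------------------
    if outdir:
        overlap = lesion_overlap_map(lesions_used)
        for name, vol in (("lesion_overlap.nii.gz", overlap),
                          ("zmap.nii.gz", np.nan_to_num(stat_map.z)),
                          ("coverage_mask.nii.gz", stat_map.in_mask)):
            sio.write_volume(np.asarray(vol, dtype=float), outdir / name)
            artifacts.append(outdir / name)
        cluster_path = outdir / "cluster_table.tsv"
        cluster_table.to_csv(cluster_path, sep="\t", index=False)
        artifacts.append(cluster_path)
        edge_path = outdir / "edge_disconnection.tsv"
        sio.write_edge_matrix(edge_matrix, atlas.n_nodes,
                              [l.subject_id for l in lesions_used], edge_path)
        artifacts.append(edge_path)
        z_path = outdir / "clsm_zmatrix.tsv"
        sio.write_node_matrix(np.nan_to_num(zmat.z), parcellation.node_names, z_path)
        artifacts.append(z_path)
        sub_path = outdir / "subgraph_edges.tsv"
        sub_edges = result.subgraph.edges if result.subgraph else {}
        pd.DataFrame([
            {"node_i": i, "node_j": j,
             "z": float(zmat.z[i - 1, j - 1]),
             "in_subgraph": (i, j) in sub_edges}
            for (i, j) in sorted(surviving)
        ], columns=["node_i", "node_j", "z", "in_subgraph"]).to_csv(
            sub_path, sep="\t", index=False)
        artifacts.append(sub_path)
        counts_path = outdir / "node_disconnection_counts.tsv"
        pd.DataFrame({
            "node_id": sorted(result.node_counts),
            "node_name": [parcellation.node_names[k - 1]
                          for k in sorted(result.node_counts)],
            "count": [result.node_counts[k] for k in sorted(result.node_counts)],
        }).to_csv(counts_path, sep="\t", index=False)
        artifacts.append(counts_path)
        if result.seed_report is not None:
            seed_path = outdir / "seed_report.tsv"
            result.seed_report.rows.to_csv(seed_path, sep="\t", index=False)
            artifacts.append(seed_path)
        sio.write_manifest(outdir, config.as_dict(), {"seed": config.seed},
                           artifacts)
    return result
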