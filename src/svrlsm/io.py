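"""Standard-format I/O: NIfTI volumes, TSV tables/matrices, YAML configs.

Conventions: voxel coordinates are 0-based and dimension-ordered; volumes
written here carry an identity affine (synthetic grids have no scanner
space).  TSV matrices carry node names as header row and first column so
node ordering is part of the file.  Every artifact directory gets a JSON
manifest with seeds, a config hash and the package version, sufficient to
re-create the outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import pathlib

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .disconnectome import edge_pairs

__all__ = [
    "read_volume",
    "write_volume",
    "write_node_matrix",
    "read_node_matrix",
    "write_edge_matrix",
    "read_edge_matrix",
    "write_weight_map",
    "load_yaml_config",
    "dump_yaml_config",
    "config_hash",
    "write_manifest",
    "save_atlas",
    "load_atlas",
]


def write_volume(array: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(array).astype(np.float32), affine=np.eye(4))
    nib.save(img, str(path))


def read_volume(path, expected_shape=None) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if expected_shape is not None and tuple(data.shape) != tuple(expected_shape):
        raise ValueError(
            f"volume {path} has grid {tuple(data.shape)}, expected "
            f"{tuple(expected_shape)}"
        )
    return data


def write_node_matrix(matrix: np.ndarray, node_names, path) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(node_names),
                      columns=list(node_names))
    df.to_csv(path, sep="\t")


def read_node_matrix(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"node matrix {path}: row/column name mismatch")
    return df.to_numpy(dtype=float), list(df.columns)


def _edge_headers(n_nodes: int) -> list:
    return [f"{i}|{j}" for (i, j) in edge_pairs(n_nodes)]


def write_edge_matrix(edge_matrix: np.ndarray, n_nodes: int, subject_ids, path) -> None:
    df = pd.DataFrame(np.asarray(edge_matrix), index=list(subject_ids),
                      columns=_edge_headers(n_nodes))
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t")


def read_edge_matrix(path) -> tuple[np.ndarray, int, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_edges = df.shape[1]
    n_nodes = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if list(df.columns) != _edge_headers(n_nodes):
        raise ValueError(f"edge matrix {path}: unexpected edge column order")
    return df.to_numpy(dtype=float), n_nodes, [str(s) for s in df.index]


def write_weight_map(weight_map, path) -> None:
    data = {"feature_id": [str(f) for f in weight_map.feature_ids],
            "weight": weight_map.weights}
    for name in ("z_scores", "null_mean", "null_sd"):
        arr = getattr(weight_map, name)
        if arr is not None:
            data[{"z_scores": "z"}.get(name, name)] = arr
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def dump_yaml_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(outdir, cfg: dict, seeds: dict, artifacts: list) -> pathlib.Path:
    from . import __version__

    outdir = pathlib.Path(outdir)
    # Artifact names are stored relative to the manifest so a run is
    # byte-identical regardless of where its output directory lives.
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seeds": seeds,
        "artifacts": sorted(pathlib.Path(a).name for a in artifacts),
        "coordinate_convention": "0-based, dimension-ordered voxel indices",
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def save_atlas(atlas, path) -> None:
    """Reference path atlas as a compressed sparse archive + JSON manifest."""
    path = pathlib.Path(path)
    arrays, index = {}, []
    for (i, j), refs in sorted(atlas.paths.items()):
        for r, (idx, probs) in enumerate(refs):
            key = f"p{i}_{j}_r{r}"
            arrays[key + "_idx"] = idx
            arrays[key + "_prob"] = probs
            index.append([i, j, r, key])
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    manifest = {
        "grid_shape": list(atlas.grid_shape),
        "n_nodes": atlas.n_nodes,
        "n_reference": atlas.n_reference,
        "entries": index,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(manifest, fh)


def load_atlas(path):
    from .synthetic import ReferencePathAtlas

    path = pathlib.Path(path)
    with open(path.with_suffix(".json")) as fh:
        manifest = json.load(fh)
    npz = np.load(path.with_suffix(".npz"))
    paths: dict = {}
    for i, j, r, key in manifest["entries"]:
        paths.setdefault((i, j), []).append(
            (npz[key + "_idx"].astype(np.intp), npz[key + "_prob"])
        )
    return ReferencePathAtlas(
        grid_shape=tuple(manifest["grid_shape"]),
        n_nodes=manifest["n_nodes"],
        n_reference=manifest["n_reference"],
        paths=paths,
    )
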