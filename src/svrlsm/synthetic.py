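"""Seeded synthetic cohorts for lesion-symptom mapping.

Real lesion masks and disconnectomes from the study this package models are
not publicly archivable, so every imaging-side analysis is exercised on
synthetic cohorts that reproduce the statistical structure the method
assumes:

* a toy integer-labeled parcellation of connected node blobs on a small
  3-D grid (default 32x32x32, 12 nodes), standing in for a left-hemisphere
  cortical parcellation;
* a reference path atlas — per node pair and per reference subject, a
  voxel chain from centroid to centroid with core-peaked visitation
  probabilities normalized to 1 — emulating shortest-path tractography
  averaged over a healthy reference cohort;
* single contiguous lesion "blobs" grown by seeded random accretion inside
  a hemisphere-like territory, with heavy-tailed (log-normal) volumes
  calibrated to the observed cohort range (337 to 303,310 mm^3-equivalents);
* behavioral scores generated as baseline minus planted lesion-load and
  edge-disconnection effects plus homoscedastic Gaussian noise, with the
  correlated primary/control score pairs (tool-use vs. imitation, right
  vs. left grip) that the residualization step assumes.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "ReferencePathAtlas",
    "LesionMask",
    "PlantedModel",
    "VolumeDistribution",
    "generate_parcellation",
    "generate_reference_paths",
    "generate_lesion",
    "generate_behavior",
    "generate_cohort",
    "default_territory",
    "default_planted_model",
    "null_planted_model",
    "node_voxels",
    "fractional_load",
]

DEFAULT_GRID = (32, 32, 32)
DEFAULT_N_NODES = 12
DEFAULT_N_SUBJECTS = 57
DEFAULT_N_REFERENCE = 20

#: Nominal lesionable left-hemisphere volume in mm^3; the ratio of territory
#: size to this constant maps observed mm^3 lesion volumes onto toy grids.
REFERENCE_HEMISPHERE_MM3 = 600_000.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Parcellation:
    grid_shape: tuple
    labels: np.ndarray
    node_names: list
    node_centroids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if tuple(self.labels.shape) != tuple(self.grid_shape):
            raise ValueError("label volume shape does not match grid_shape")
        n = len(self.node_names)
        present = set(np.unique(self.labels)) - {0}
        if present != set(range(1, n + 1)):
            raise ValueError(
                f"every label 1..{n} must occur; found {sorted(present)}"
            )
        self.node_centroids = np.asarray(self.node_centroids, dtype=float)
        if self.node_centroids.shape != (n, 3):
            raise ValueError("node_centroids must be (n_nodes, 3)")
        upper = np.asarray(self.grid_shape, dtype=float)
        if np.any(self.node_centroids < 0) or np.any(self.node_centroids >= upper):
            raise ValueError("centroids must lie inside grid bounds")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)


@dataclass
class ReferencePathAtlas:
    """Per node-pair, per reference-subject sparse voxel visitation maps."""

    grid_shape: tuple
    n_nodes: int
    n_reference: int
    paths: dict  # (i, j) -> list over refs of (flat voxel idx array, prob array)

    def __post_init__(self) -> None:
        self._flat_cache = None
        nvox = int(np.prod(self.grid_shape))
        for (i, j), refs in self.paths.items():
            if not i < j:
                raise ValueError(f"pairs must be stored with i < j, got {(i, j)}")
            for idx, probs in refs:
                if idx.size == 0:
                    raise ValueError(f"empty path for pair {(i, j)}")
                if np.any((idx < 0) | (idx >= nvox)):
                    raise ValueError(f"path voxels out of grid bounds for {(i, j)}")
                if np.any(probs <= 0) or np.any(probs > 1):
                    raise ValueError(f"path probabilities must be in (0, 1] for {(i, j)}")
                if abs(float(probs.sum()) - 1.0) > 1e-9:
                    raise ValueError(f"path probabilities must sum to 1 for {(i, j)}")

    def flat_segments(self):
        """Concatenated (idx, probs, segment starts, segment pair ids).

        Segments are ordered by pair (canonical lexicographic order) then by
        reference subject; cached for fast lesion intersection.
        """
        if self._flat_cache is None:
            from .disconnectome import edge_pairs

            idx_parts, prob_parts, starts, pair_ids = [], [], [], []
            pos = 0
            for k, pair in enumerate(edge_pairs(self.n_nodes)):
                for (idx, probs) in self.paths.get(pair, []):
                    idx_parts.append(idx)
                    prob_parts.append(probs)
                    starts.append(pos)
                    pair_ids.append(k)
                    pos += idx.size
            if idx_parts:
                self._flat_cache = (
                    np.concatenate(idx_parts),
                    np.concatenate(prob_parts),
                    np.asarray(starts, dtype=np.intp),
                    np.asarray(pair_ids, dtype=np.intp),
                )
            else:
                self._flat_cache = (
                    np.empty(0, dtype=np.intp), np.empty(0),
                    np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp),
                )
        return self._flat_cache


@dataclass
class LesionMask:
    subject_id: str
    mask: np.ndarray
    volume: int = -1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(np.uint8)
        nz = int(np.count_nonzero(self.mask))
        if self.volume == -1:
            self.volume = nz
        elif self.volume != nz:
            raise ValueError(
                f"declared volume {self.volume} != nonzero voxel count {nz}"
            )


@dataclass
class PlantedModel:
    """Generative structure planted into a synthetic cohort.

    Voxel sets are flat grid indices.  Lesion load on target_voxel_set and
    disconnection of target_edges lower the primary (tool-use) score;
    shared_voxel_set drives the control (imitation) score; and overall
    lesion size (the "volume"/"volume_control" effects, applied to the
    lesioned fraction of the grid) lowers both scores.  The volume channel
    is what makes the primary/control score pair reliably positively
    correlated whatever the node geometry — bigger strokes impair both
    tasks — mirroring the severity confound that the real analyses remove
    by volume control.  motor_voxel_set plays the target role for
    right-hand grip, whose left/right correlation comes from a per-subject
    latent strength factor instead.
    """

    target_voxel_set: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    target_edges: list = field(default_factory=list)
    shared_voxel_set: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    motor_voxel_set: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    effect_sizes: dict = field(default_factory=dict)
    noise_sd: float = 0.08
    baseline: float = 0.78
    control_baseline: float = 0.68
    grip_baseline: float = 28.0
    grip_strength_sd: float = 7.0
    grip_noise_sd: float = 6.0

    def __post_init__(self) -> None:
        self.target_voxel_set = np.asarray(self.target_voxel_set, dtype=np.intp)
        self.shared_voxel_set = np.asarray(self.shared_voxel_set, dtype=np.intp)
        self.motor_voxel_set = np.asarray(self.motor_voxel_set, dtype=np.intp)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for key, value in self.effect_sizes.items():
            if not math.isfinite(value):
                raise ValueError(f"effect size {key!r} is not finite")
        if self.effect_sizes.get("voxel", 0) and self.target_voxel_set.size == 0:
            raise ValueError("nonzero voxel effect requires a target voxel set")
        if self.effect_sizes.get("edge", 0) and not self.target_edges:
            raise ValueError("nonzero edge effect requires target edges")
        if self.effect_sizes.get("shared", 0) and self.shared_voxel_set.size == 0:
            raise ValueError("nonzero shared effect requires a shared voxel set")
        if self.effect_sizes.get("motor", 0) and self.motor_voxel_set.size == 0:
            raise ValueError("nonzero motor effect requires a motor voxel set")


@dataclass
class VolumeDistribution:
    """Log-normal lesion volume model in mm^3-equivalents.

    Defaults are the log-mean/log-SD of the packaged cohort's 57 lesion
    volumes, clipped to the observed range.
    """

    ln_mean: float = 10.694
    ln_sd: float = 1.215
    mm3_min: float = 337.0
    mm3_max: float = 303_310.0

    def sample_mm3(self, rng: np.random.Generator, size: int) -> np.ndarray:
        vols = np.exp(rng.normal(self.ln_mean, self.ln_sd, size=size))
        return np.clip(vols, self.mm3_min, self.mm3_max)


# ---------------------------------------------------------------------------
# Grid helpers
# ---------------------------------------------------------------------------

def _offsets(connectivity: int) -> list:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                offs.append((dx, dy, dz))
    return offs


@functools.lru_cache(maxsize=8)
def _neighbor_table(grid_shape: tuple, connectivity: int) -> list:
    """Per-voxel flat-index neighbor lists (Python lists, for fast accretion)."""
    nx, ny, nz = grid_shape
    shape = np.array(grid_shape)
    idx = np.arange(nx * ny * nz)
    coords = np.stack(np.unravel_index(idx, grid_shape), axis=1)
    neighbor_cols = []
    for off in _offsets(connectivity):
        shifted = coords + np.array(off)
        valid = np.all((shifted >= 0) & (shifted < shape), axis=1)
        flat = np.where(valid, np.ravel_multi_index(
            np.clip(shifted, 0, shape - 1).T, grid_shape), -1)
        neighbor_cols.append(flat)
    table_arr = np.stack(neighbor_cols, axis=1)
    return [[int(v) for v in row if v >= 0] for row in table_arr]


def node_voxels(parcellation: Parcellation, node_id: int) -> np.ndarray:
    """Flat indices of a node's voxels."""
    return np.flatnonzero(parcellation.labels.reshape(-1) == node_id)


def fractional_load(lesion: LesionMask, voxel_set: np.ndarray) -> float:
    """Fraction of a voxel set covered by the lesion."""
    voxel_set = np.asarray(voxel_set, dtype=np.intp)
    if voxel_set.size == 0:
        return 0.0
    flat = lesion.mask.reshape(-1)
    return float(flat[voxel_set].sum() / voxel_set.size)


def default_territory(grid_shape) -> np.ndarray:
    """Hemisphere-like lesion territory: the low-x half of the grid."""
    territory = np.zeros(grid_shape, dtype=bool)
    territory[: grid_shape[0] // 2, :, :] = True
    return territory


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_parcellation(grid_shape, n_nodes: int, seed: int,
                          fill_fraction: float = 0.9) -> Parcellation:
    """Grow ``n_nodes`` connected node blobs from spread-out random centroids.

    Seeds are chosen by farthest-point sampling; blobs grow by seeded
    round-robin face-connected accretion (hence 26-connected) until about
    ``fill_fraction`` of the grid is covered, the rest remaining background.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    volume = int(np.prod(grid_shape))
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if volume < 10 * n_nodes:
        raise ValueError(
            f"grid volume {volume} too small to pack {n_nodes} nodes "
            "(need >= 10 voxels per node)"
        )
    rng = np.random.default_rng(seed)
    # Farthest-point sampling over a random candidate subset keeps seeds apart.
    n_cand = min(volume, 4096)
    candidates = rng.choice(volume, size=n_cand, replace=False)
    cand_coords = np.stack(np.unravel_index(candidates, grid_shape), axis=1).astype(float)
    chosen = [int(rng.integers(n_cand))]
    dist = np.linalg.norm(cand_coords - cand_coords[chosen[0]], axis=1)
    for _ in range(n_nodes - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(cand_coords - cand_coords[nxt], axis=1))
    seeds = candidates[chosen]

    table = _neighbor_table(grid_shape, 6)
    labels = np.zeros(volume, dtype=np.int32)
    frontiers: list[list[int]] = [[] for _ in range(n_nodes)]
    for k, s in enumerate(seeds):
        labels[s] = k + 1
        frontiers[k] = list(table[s])
    target_total = int(fill_fraction * volume)
    assigned = n_nodes
    active = list(range(n_nodes))
    while active and assigned < target_total:
        rng.shuffle(active)
        still = []
        for k in active:
            frontier = frontiers[k]
            grew = False
            while frontier:
                pick = int(rng.integers(len(frontier)))
                frontier[pick], frontier[-1] = frontier[-1], frontier[pick]
                v = frontier.pop()
                if labels[v] == 0:
                    labels[v] = k + 1
                    assigned += 1
                    frontier.extend(table[v])
                    grew = True
                    break
            if grew:
                still.append(k)
        active = still

    labels = labels.reshape(grid_shape)
    centroids = np.stack([
        np.argwhere(labels == k + 1).mean(axis=0) for k in range(n_nodes)
    ])
    names = [f"node_{k + 1:02d}" for k in range(n_nodes)]
    return Parcellation(grid_shape=grid_shape, labels=labels,
                        node_names=names, node_centroids=centroids)


def _rasterize_line(start: np.ndarray, stop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Points and parameters t of a voxelized straight line (inclusive)."""
    delta = stop - start
    n_steps = int(np.max(np.abs(delta)))
    if n_steps == 0:
        return start[None, :].astype(float), np.array([0.5])
    t = np.linspace(0.0, 1.0, n_steps + 1)
    pts = start[None, :] + t[:, None] * delta[None, :]
    return pts, t


def _perpendicular_basis(delta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = delta.astype(float)
    norm = np.linalg.norm(d)
    if norm == 0:
        return np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
    d = d / norm
    helper = np.array([1.0, 0, 0]) if abs(d[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def generate_reference_paths(parcellation: Parcellation, n_reference: int = DEFAULT_N_REFERENCE,
                             jitter_sd: float = 1.0, seed: int = 0) -> ReferencePathAtlas:
    """Straight centroid-to-centroid voxel chains with lateral Gaussian jitter.

    Each reference subject's chain is the rasterized straight line between
    node centroids displaced laterally by a smooth sinusoidal bow whose two
    perpendicular amplitudes are drawn from N(0, jitter_sd) — a cartoon of
    between-subject tract variability.  Visitation probabilities are peaked
    at the chain core and normalized to sum to 1.
    """
    if n_reference < 1:
        raise ValueError("n_reference must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    grid_shape = parcellation.grid_shape
    upper = np.asarray(grid_shape) - 1
    centroids = np.rint(parcellation.node_centroids).astype(int)
    paths = {}
    n = parcellation.n_nodes
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            ci, cj = centroids[i - 1], centroids[j - 1]
            base_pts, t = _rasterize_line(ci, cj)
            u, v = _perpendicular_basis(cj - ci)
            refs = []
            for _ in range(n_reference):
                amp = rng.normal(0.0, jitter_sd, size=2) if jitter_sd > 0 else np.zeros(2)
                bow = np.sin(np.pi * t)[:, None] * (amp[0] * u + amp[1] * v)[None, :]
                pts = np.clip(np.rint(base_pts + bow).astype(int), 0, upper)
                flat = np.ravel_multi_index(pts.T, grid_shape)
                weights = 0.5 + 0.5 * np.sin(np.pi * t)  # core-peaked profile
                if flat.size == 1:
                    weights = np.array([1.0])
                uniq, inverse = np.unique(flat, return_inverse=True)
                agg = np.bincount(inverse, weights=weights)
                probs = agg / agg.sum()
                refs.append((uniq.astype(np.intp), probs))
            paths[(i, j)] = refs
    return ReferencePathAtlas(grid_shape=grid_shape, n_nodes=n,
                              n_reference=n_reference, paths=paths)


def generate_lesion(parcellation: Parcellation, territory, target_volume: int,
                    seed: int, subject_id: str = "synthetic") -> LesionMask:
    """Grow one 26-connected lesion blob by seeded random accretion.

    Growth starts at a random territory voxel and repeatedly annexes a
    random frontier voxel (26-neighbors inside the territory) until the
    target volume — capped at the territory size — is reached.
    """
    if target_volume < 1:
        raise ValueError("target_volume must be >= 1")
    territory = np.asarray(territory, dtype=bool)
    if tuple(territory.shape) != tuple(parcellation.grid_shape):
        raise ValueError("territory shape must match the parcellation grid")
    terr_flat = territory.reshape(-1)
    terr_idx = np.flatnonzero(terr_flat)
    if terr_idx.size == 0:
        raise ValueError("territory is empty")
    rng = np.random.default_rng(seed)
    goal = min(int(target_volume), int(terr_idx.size))
    table = _neighbor_table(tuple(parcellation.grid_shape), 26)
    grown = np.zeros(terr_flat.shape[0], dtype=bool)
    start = int(terr_idx[rng.integers(terr_idx.size)])
    grown[start] = True
    count = 1
    frontier = [v for v in table[start] if terr_flat[v]]
    while count < goal and frontier:
        pick = int(rng.integers(len(frontier)))
        frontier[pick], frontier[-1] = frontier[-1], frontier[pick]
        v = frontier.pop()
        if grown[v]:
            continue
        grown[v] = True
        count += 1
        for w in table[v]:
            if terr_flat[w] and not grown[w]:
                frontier.append(w)
    mask = grown.reshape(parcellation.grid_shape).astype(np.uint8)
    return LesionMask(subject_id=subject_id, mask=mask)


def default_planted_model(parcellation: Parcellation, territory=None,
                          effect_scale: float = 1.0,
                          noise_sd: float = 0.08) -> PlantedModel:
    """Deterministic default planted-effect structure for a parcellation.

    The five largest-in-territory nodes become, in order: the primary
    target region (voxel effect on the tool-use score), the shared region
    driving the control (imitation) score, the motor-strip stand-in for
    grip, and the two endpoints of the planted disconnection edge.  The
    roles are distinct on purpose: the control score must load on a
    different region than the primary target, otherwise residualizing the
    primary on the control would cancel the planted voxel effect (the
    primary/control correlation still arises because contiguous lesions
    hit both regions together); and keeping the planted edge off the
    primary target node means the edge effect can survive the nuisance
    regression that removes cumulative target-region disconnection
    downstream.
    """
    if territory is None:
        territory = default_territory(parcellation.grid_shape)
    territory = np.asarray(territory, dtype=bool)
    terr_flat = territory.reshape(-1)
    labels_flat = parcellation.labels.reshape(-1)
    in_territory = [
        int((terr_flat & (labels_flat == k + 1)).sum())
        for k in range(parcellation.n_nodes)
    ]
    ranked = sorted(range(parcellation.n_nodes),
                    key=lambda k: (-in_territory[k], k))
    eligible = [k + 1 for k in ranked if in_territory[k] >= 10]
    if len(eligible) < 5:
        raise ValueError("territory must substantially cover at least 5 nodes")
    target_node, shared_node, motor_node, edge_a, edge_b = eligible[:5]
    target_set = node_voxels(parcellation, target_node)
    return PlantedModel(
        target_voxel_set=target_set,
        target_edges=[(min(edge_a, edge_b), max(edge_a, edge_b))],
        shared_voxel_set=node_voxels(parcellation, shared_node),
        motor_voxel_set=node_voxels(parcellation, motor_node),
        effect_sizes={
            "voxel": 0.45 * effect_scale,
            "edge": 0.45 * effect_scale,
            "shared": 0.55 * effect_scale,
            "motor": 22.0 * effect_scale,
            "volume": 0.9,
            "volume_control": 1.1,
        },
        noise_sd=noise_sd,
    )


def null_planted_model(noise_sd: float = 0.08) -> PlantedModel:
    """No planted effects: behavior is baseline plus noise only."""
    return PlantedModel(effect_sizes={}, noise_sd=noise_sd)


def generate_behavior(lesions, model: PlantedModel,
                      atlas: Optional[ReferencePathAtlas], seed: int,
                      mm3_per_voxel: float = 1.0) -> pd.DataFrame:
    """Planted-effect behavioral table for a list of lesions.

    Demographics (age, education, gender) and months post-stroke are drawn
    to match the observed cohort's marginals and are independent of the
    planted effects; months post-stroke is a nuisance covariate downstream,
    not a modeled effect.
    """
    from .disconnectome import edge_disconnection

    rng = np.random.default_rng(seed)
    eff = model.effect_sizes
    rows = []
    for les in lesions:
        load_t = fractional_load(les, model.target_voxel_set)
        load_s = fractional_load(les, model.shared_voxel_set)
        load_m = fractional_load(les, model.motor_voxel_set)
        vol_frac = float(les.volume) / les.mask.size
        disc_e = 0.0
        if model.target_edges and atlas is not None and eff.get("edge", 0):
            disc = edge_disconnection(les, atlas)
            disc_e = float(np.mean([
                disc.values[i - 1, j - 1] for (i, j) in model.target_edges
            ]))
        gts = (model.baseline
               - eff.get("voxel", 0.0) * load_t
               - eff.get("edge", 0.0) * disc_e
               - eff.get("volume", 0.0) * vol_frac
               - rng.normal(0.0, model.noise_sd))
        imi = (model.control_baseline
               - eff.get("shared", 0.0) * load_s
               - eff.get("volume_control", 0.0) * vol_frac
               - rng.normal(0.0, model.noise_sd))
        strength = rng.normal(0.0, model.grip_strength_sd)
        lh = model.grip_baseline + strength + rng.normal(0.0, model.grip_noise_sd)
        rh = (model.grip_baseline + strength
              - eff.get("motor", 0.0) * load_m
              + rng.normal(0.0, model.grip_noise_sd))
        rows.append({
            "subject_id": les.subject_id,
            "gts_hp": float(np.clip(gts, 0.0, 1.0)),
            "imi_hp": float(np.clip(imi, 0.0, 1.0)),
            "lh_grip": float(max(lh, 0.0)),
            "rh_grip": float(max(rh, 0.0)),
            "months_post": float(np.clip(np.exp(rng.normal(3.2, 1.0)), 3.0, 200.0)),
            "lesion_volume": int(round(les.volume * mm3_per_voxel)),
            "age": float(np.clip(rng.normal(56.0, 11.5), 18.0, 90.0)),
            "education": float(np.clip(rng.normal(14.2, 2.8), 9.0, 21.0)),
            "gender": "F" if rng.random() < 28 / 57 else "M",
        })
    return pd.DataFrame(rows)


def generate_cohort(parcellation: Parcellation, atlas: Optional[ReferencePathAtlas],
                    model: PlantedModel, n_subjects: int = DEFAULT_N_SUBJECTS,
                    volume_distribution: Optional[VolumeDistribution] = None,
                    seed: int = 0, territory=None):
    """Full synthetic cohort: lesion masks plus a behavior table.

    Lesion volumes are drawn log-normally in mm^3-equivalents and rescaled
    to the toy grid by the ratio of territory size to a nominal hemisphere
    volume, so the cohort's relative lesion-size spread matches the
    observed one.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if territory is None:
        territory = default_territory(parcellation.grid_shape)
    territory = np.asarray(territory, dtype=bool)
    vd = volume_distribution or VolumeDistribution()
    rng = np.random.default_rng(seed)
    terr_size = int(territory.sum())
    voxels_per_mm3 = terr_size / REFERENCE_HEMISPHERE_MM3
    vols_mm3 = vd.sample_mm3(rng, n_subjects)
    lesion_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    behavior_seed = int(rng.integers(0, 2**31 - 1))
    lesions = []
    for s in range(n_subjects):
        target = max(1, int(round(vols_mm3[s] * voxels_per_mm3)))
        lesions.append(generate_lesion(
            parcellation, territory, target, int(lesion_seeds[s]),
            subject_id=f"S{s + 1:02d}",
        ))
    behavior = generate_behavior(
        lesions, model, atlas, behavior_seed,
        mm3_per_voxel=1.0 / voxels_per_mm3,
    )
    return lesions, behavior
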