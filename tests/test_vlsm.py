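"""Voxel-level analysis: overlap, coverage, volume control, clustering, labels."""

import numpy as np
import pytest

from svrlsm.behavior import ResidualScores
from svrlsm.engine import SvrConfig
from svrlsm.synthetic import (LesionMask, default_territory, generate_lesion,
                              generate_parcellation)
from svrlsm.vlsm import (VlsmThresholds, VoxelStatMap, coverage_mask,
                         coverage_threshold, desk_min_cluster, dtlvc_scale,
                         label_clusters, lesion_overlap_map, run_vlsm,
                         threshold_and_cluster)


def _mask(shape, coords):
    m = np.zeros(shape, dtype=np.uint8)
    for c in coords:
        m[c] = 1
    return m


class TestOverlapMap:
    def test_no_lesions_gives_zero_map(self):
        lesions = [LesionMask("a", np.zeros((4, 4, 4), np.uint8))
                   ] * 0 or [LesionMask("a", np.zeros((4, 4, 4), np.uint8))]
        assert lesion_overlap_map(lesions).sum() == 0

    def test_two_identical_masks_double_the_map(self):
        m = _mask((4, 4, 4), [(0, 0, 0), (1, 1, 1)])
        out = lesion_overlap_map([LesionMask("a", m), LesionMask("b", m)])
        assert np.array_equal(out, 2 * m.astype(int))

    def test_three_masks_sharing_one_voxel(self):
        shared = (2, 2, 2)
        lesions = [
            LesionMask(s, _mask((5, 5, 5), [shared, extra]))
            for s, extra in [("a", (0, 0, 0)), ("b", (1, 0, 0)), ("c", (0, 1, 0))]
        ]
        out = lesion_overlap_map(lesions)
        assert out[shared] == 3
        assert out.sum() == 3 + 3

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            lesion_overlap_map([
                LesionMask("a", np.zeros((4, 4, 4), np.uint8)),
                LesionMask("b", np.zeros((5, 5, 5), np.uint8)),
            ])


class TestCoverage:
    @pytest.mark.parametrize("n, expected", [(57, 5), (41, 4), (10, 1)])
    def test_floor_rule_thresholds(self, n, expected):
        assert coverage_threshold(n, 0.10) == expected

    def test_mask_applies_threshold_inclusively(self):
        overlap = np.array([[[0, 4, 5, 6]]])
        out = coverage_mask(overlap, n_subjects=57)
        assert out.tolist() == [[[False, False, True, True]]]


class TestDtlvc:
    def test_unit_norm_scaling(self):
        mat = np.array([[1, 1, 1, 1, 0], [1, 0, 0, 0, 0]], dtype=float)
        out = dtlvc_scale(mat)
        assert np.allclose(out[0, :4], 0.5)
        assert out[1, 0] == pytest.approx(1.0)
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-9)

    def test_empty_row_error_names_subject(self):
        mat = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="S2"):
            dtlvc_scale(mat, subject_ids=["S1", "S2"])


class TestThresholdAndCluster:
    def test_all_zero_z_yields_no_clusters(self):
        z = np.zeros((6, 6, 6))
        assert threshold_and_cluster(z, np.ones_like(z, bool)) == []

    def test_extent_criterion_drops_small_deep_cluster(self):
        z = np.zeros((20, 20, 20))
        mask = np.ones_like(z, bool)
        z[1:11, 1:11, 1:7] = -2.0        # 600 voxels at z = -2
        z[14:19, 14:18, 14:19] = -3.0    # 100 voxels at z = -3
        clusters = threshold_and_cluster(z, mask, min_cluster=500)
        assert len(clusters) == 1
        assert clusters[0].size == 600
        assert clusters[0].peak_z == pytest.approx(-2.0)

    def test_threshold_is_strict(self):
        z = np.zeros((3, 3, 3))
        z[1, 1, 1] = -1.65
        assert threshold_and_cluster(z, np.ones_like(z, bool)) == []
        z[1, 1, 1] = -1.6500001
        assert len(threshold_and_cluster(z, np.ones_like(z, bool))) == 1

    def test_raising_extent_never_increases_cluster_count(self):
        rng = np.random.default_rng(2)
        z = rng.normal(scale=1.5, size=(12, 12, 12))
        mask = np.ones_like(z, bool)
        counts = [len(threshold_and_cluster(z, mask, min_cluster=m))
                  for m in (1, 2, 4, 8, 16)]
        assert counts == sorted(counts, reverse=True)

    def test_connectivity_choices_nest(self):
        rng = np.random.default_rng(3)
        z = rng.normal(scale=1.4, size=(10, 10, 10))
        mask = np.ones_like(z, bool)
        n26 = len(threshold_and_cluster(z, mask, connectivity=26))
        n6 = len(threshold_and_cluster(z, mask, connectivity=6))
        assert n26 <= n6  # merging under looser connectivity


class TestLabelClusters:
    def _stat_map(self, parc, cluster_coords):
        z = np.full(parc.grid_shape, np.nan)
        clusters = threshold_and_cluster
        from svrlsm.vlsm import Cluster
        coords = np.array(cluster_coords)
        z[tuple(coords.T)] = -2.0
        cl = Cluster(cluster_id=1, voxels=coords, peak_z=-2.0,
                     peak_coordinate=tuple(coords[0]), size=len(coords),
                     center_of_mass=tuple(coords.mean(axis=0)))
        return VoxelStatMap(grid_shape=parc.grid_shape,
                            in_mask=~np.isnan(z), z=z, clusters=[cl])

    def test_single_node_cluster(self, parc20):
        inside = np.argwhere(parc20.labels == 3)[:5]
        table = label_clusters(self._stat_map(parc20, inside), parc20)
        assert len(table) == 1
        assert table.loc[0, "node_id"] == 3
        assert table.loc[0, "n_voxels"] == 5

    def test_straddling_cluster_counts_sum(self, parc20):
        a = np.argwhere(parc20.labels == 2)[:4]
        b = np.argwhere(parc20.labels == 5)[:3]
        bg = np.argwhere(parc20.labels == 0)[:2]
        coords = np.vstack([a, b, bg])
        table = label_clusters(self._stat_map(parc20, coords), parc20)
        assert sorted(table["node_id"]) == [2, 5]
        assert table["n_voxels"].sum() == 7  # background excluded

    def test_empty_map_gives_empty_table(self, parc20):
        stat_map = VoxelStatMap(grid_shape=parc20.grid_shape,
                                in_mask=np.zeros(parc20.grid_shape, bool),
                                z=np.full(parc20.grid_shape, np.nan),
                                clusters=[])
        assert label_clusters(stat_map, parc20).empty


class TestRunVlsm:
    def test_desk_scale_cluster_criterion(self):
        assert desk_min_cluster(32 ** 3) == 10
        assert desk_min_cluster(100) == 5
        assert desk_min_cluster(1_700_000) == 500

    def test_two_disjoint_planted_regions_give_two_clusters(self):
        parc = generate_parcellation((20, 20, 20), 8, seed=60)
        territory = default_territory(parc.grid_shape)
        rng = np.random.default_rng(61)
        lesions = [
            generate_lesion(parc, territory, int(v), seed=700 + k,
                            subject_id=f"S{k:02d}")
            for k, v in enumerate(rng.integers(60, 900, size=40))
        ]
        # Two spatially separated boxes inside the territory.
        region_a = np.zeros(parc.grid_shape, bool)
        region_a[1:5, 1:5, 1:5] = True
        region_b = np.zeros(parc.grid_shape, bool)
        region_b[1:5, 14:18, 14:18] = True
        flat_a = np.flatnonzero(region_a.reshape(-1))
        flat_b = np.flatnonzero(region_b.reshape(-1))
        scores = []
        for les in lesions:
            flat = les.mask.reshape(-1)
            scores.append(1.0 - flat[flat_a].mean() - flat[flat_b].mean())
        target = ResidualScores([l.subject_id for l in lesions],
                                np.array(scores) - np.mean(scores))
        res = run_vlsm(lesions, target,
                       SvrConfig(n_permutations=150, seed=62),
                       VlsmThresholds(min_cluster=5))
        assert len(res.clusters) >= 2
        # The two strongest clusters hit the two planted boxes.
        tops = [set(np.ravel_multi_index(c.voxels.T, parc.grid_shape))
                for c in res.clusters[:2]]
        hits_a = any(t & set(flat_a.tolist()) for t in tops)
        hits_b = any(t & set(flat_b.tolist()) for t in tops)
        assert hits_a and hits_b

    def test_misaligned_target_rejected(self, lesions20):
        target = ResidualScores(["x"] * 5, np.zeros(5))
        with pytest.raises(ValueError):
            run_vlsm(lesions20, target, SvrConfig(n_permutations=100, seed=0))
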