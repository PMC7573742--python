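"""Synthetic study generators: determinism, connectivity, planted structure."""

import numpy as np
import pytest
from scipy import ndimage

from svrlsm.behavior import pearson_r
from svrlsm.synthetic import (LesionMask, Parcellation, PlantedModel,
                              default_planted_model, default_territory,
                              generate_behavior, generate_cohort,
                              generate_lesion, generate_parcellation,
                              generate_reference_paths, null_planted_model)

STRUCT26 = ndimage.generate_binary_structure(3, 3)


class TestParcellation:
    def test_seed_determinism(self):
        p1 = generate_parcellation((20, 20, 20), 8, seed=1)
        p2 = generate_parcellation((20, 20, 20), 8, seed=1)
        assert np.array_equal(p1.labels, p2.labels)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            generate_parcellation((20, 20, 20), 1, seed=0)

    def test_impossible_packing_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_parcellation((3, 3, 3), 5, seed=0)

    def test_all_labels_present_and_blobs_connected(self, parc20):
        labels = parc20.labels
        assert set(np.unique(labels)) - {0} == set(range(1, 9))
        for node in range(1, 9):
            _, n_comp = ndimage.label(labels == node, structure=STRUCT26)
            assert n_comp == 1

    def test_centroids_inside_grid(self, parc20):
        assert np.all(parc20.node_centroids >= 0)
        assert np.all(parc20.node_centroids < np.array(parc20.grid_shape))


class TestReferencePaths:
    def test_zero_jitter_makes_references_identical(self, parc20):
        atlas = generate_reference_paths(parc20, n_reference=3, jitter_sd=0.0,
                                         seed=1)
        for refs in atlas.paths.values():
            idx0, p0 = refs[0]
            for idx, p in refs[1:]:
                assert np.array_equal(idx, idx0) and np.allclose(p, p0)

    def test_probabilities_normalized(self, atlas20):
        for refs in atlas20.paths.values():
            for _, probs in refs:
                assert probs.sum() == pytest.approx(1.0, abs=1e-9)
                assert np.all((probs > 0) & (probs <= 1))

    def test_axis_aligned_line_rasterization(self):
        # Two nodes whose centroids sit 10 voxels apart along x: the
        # jitter-free path must visit exactly the 11 colinear voxels.
        labels = np.zeros((16, 5, 5), dtype=int)
        labels[2, 2, 2] = 1
        labels[12, 2, 2] = 2
        parc = Parcellation(grid_shape=(16, 5, 5), labels=labels,
                            node_names=["a", "b"],
                            node_centroids=np.array([[2, 2, 2], [12, 2, 2]],
                                                    dtype=float))
        atlas = generate_reference_paths(parc, n_reference=1, jitter_sd=0.0,
                                         seed=0)
        idx, probs = atlas.paths[(1, 2)][0]
        expected = [np.ravel_multi_index((x, 2, 2), (16, 5, 5))
                    for x in range(2, 13)]
        assert sorted(idx.tolist()) == sorted(expected)
        assert probs.sum() == pytest.approx(1.0)

    def test_degenerate_identical_centroids_collapse_to_one_voxel(self):
        labels = np.zeros((6, 6, 6), dtype=int)
        labels[1, 1, 1] = 1
        labels[2, 2, 2] = 2
        parc = Parcellation(grid_shape=(6, 6, 6), labels=labels,
                            node_names=["a", "b"],
                            node_centroids=np.array([[3.0, 3, 3], [3.0, 3, 3]]))
        atlas = generate_reference_paths(parc, n_reference=2, jitter_sd=0.0,
                                         seed=0)
        for idx, probs in atlas.paths[(1, 2)]:
            assert idx.size == 1 and probs[0] == pytest.approx(1.0)


class TestLesionGrowth:
    def test_single_voxel_target(self, parc20, territory20):
        les = generate_lesion(parc20, territory20, 1, seed=3)
        assert les.volume == 1

    def test_seed_determinism(self, parc20, territory20):
        l1 = generate_lesion(parc20, territory20, 50, seed=4)
        l2 = generate_lesion(parc20, territory20, 50, seed=4)
        assert np.array_equal(l1.mask, l2.mask)

    def test_blob_is_single_26_connected_component(self, lesions20):
        for les in lesions20:
            _, n_comp = ndimage.label(les.mask, structure=STRUCT26)
            assert n_comp == 1

    def test_volume_capped_at_territory_size(self, parc20):
        territory = np.zeros(parc20.grid_shape, dtype=bool)
        territory[:3, :3, :3] = True
        les = generate_lesion(parc20, territory, 10_000, seed=5)
        assert les.volume == 27

    def test_empty_territory_rejected(self, parc20):
        with pytest.raises(ValueError, match="empty"):
            generate_lesion(parc20, np.zeros(parc20.grid_shape, bool), 5, seed=0)


class TestPlantedModel:
    def test_nonzero_effect_requires_target_set(self):
        with pytest.raises(ValueError):
            PlantedModel(effect_sizes={"voxel": 0.5})

    def test_default_model_roles_are_distinct(self):
        parc = generate_parcellation((32, 32, 32), 12, seed=2)
        model = default_planted_model(parc)
        labels = parc.labels.reshape(-1)
        roles = {labels[model.target_voxel_set[0]],
                 labels[model.shared_voxel_set[0]],
                 labels[model.motor_voxel_set[0]],
                 *model.target_edges[0]}
        assert len(roles) == 5


class TestCohort:
    def test_noise_free_empty_lesion_scores_at_baseline(self, parc20, atlas20):
        model = null_planted_model(noise_sd=0.0)
        empty = LesionMask(subject_id="empty",
                           mask=np.zeros(parc20.grid_shape, dtype=np.uint8))
        table = generate_behavior([empty], model, atlas20, seed=0)
        assert table.loc[0, "gts_hp"] == pytest.approx(model.baseline)

    def test_same_seed_gives_identical_table(self, parc20, atlas20):
        model = default_planted_model(parc20)
        _, t1 = generate_cohort(parc20, atlas20, model, n_subjects=12, seed=21)
        _, t2 = generate_cohort(parc20, atlas20, model, n_subjects=12, seed=21)
        assert t1.equals(t2)

    def test_lesion_volumes_heavy_tailed_and_positive(self, parc20, atlas20):
        model = default_planted_model(parc20)
        lesions, table = generate_cohort(parc20, atlas20, model,
                                         n_subjects=25, seed=22)
        vols = np.array([l.volume for l in lesions])
        assert np.all(vols >= 1)
        assert vols.max() / np.median(vols) > 3  # heavy right tail
        assert (table["lesion_volume"] > 0).all()

    def test_planted_effects_induce_primary_control_correlation(self):
        parc = generate_parcellation((32, 32, 32), 12, seed=30)
        atlas = generate_reference_paths(parc, n_reference=5, jitter_sd=1.0,
                                         seed=31)
        model = default_planted_model(parc)
        _, table = generate_cohort(parc, atlas, model, n_subjects=57, seed=32)
        assert pearson_r(table["gts_hp"].to_numpy(),
                         table["imi_hp"].to_numpy()) > 0

    def test_mean_score_correlations_bracket_observed_cohort(self):
        # Across seeded default cohorts the mean tool-use/imitation
        # correlation must lie in (0.2, 0.7), bracketing the observed 0.41.
        parc = generate_parcellation((32, 32, 32), 12, seed=40)
        atlas = generate_reference_paths(parc, n_reference=5, jitter_sd=1.0,
                                         seed=41)
        model = default_planted_model(parc)
        r_gi, r_grip = [], []
        for s in range(20):
            _, table = generate_cohort(parc, atlas, model, n_subjects=57,
                                       seed=500 + s)
            r_gi.append(pearson_r(table["gts_hp"].to_numpy(),
                                  table["imi_hp"].to_numpy()))
            r_grip.append(pearson_r(table["rh_grip"].to_numpy(),
                                    table["lh_grip"].to_numpy()))
        assert 0.2 < np.mean(r_gi) < 0.7
        assert 0.2 < np.mean(r_grip) < 0.7
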