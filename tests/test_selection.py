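import numpy as np
import pandas as pd
import pytest

import lapmix as lm
from lapmix.model import LaplacianMixtureModel
from lapmix.selection import ModelSequence, fit_model_sequence


class TestLabelingErrors:
    def test_identical_labelings(self):
        assert lm.labeling_errors([0, 0, 1, 1], [0, 0, 1, 1]) == 0

    def test_permutation_invariance(self):
        assert lm.labeling_errors([1, 1, 0, 0], [0, 0, 1, 1]) == 0
        assert lm.labeling_errors([2, 2, 0, 0, 1], [0, 0, 1, 1, 2]) == 0

    def test_single_disagreement(self):
        assert lm.labeling_errors([1, 1, 1, 2], [1, 1, 2, 2]) == 1

    def test_different_label_alphabets(self):
        # merged labeling: the best matching still leaves one block wrong
        assert lm.labeling_errors([0, 0, 0, 0], [0, 0, 1, 1]) == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            lm.labeling_errors([0, 1], [0, 1, 2])


class TestRelativeError:
    def test_perfect_recovery(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(size=(30, 3))
        assert lm.relative_error(f, f) == pytest.approx(0.0)

    def test_uniform_scaling(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(size=(30, 2))
        assert lm.relative_error(1.1 * f, f) == pytest.approx(0.1)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        f = rng.uniform(size=(30, 3))
        est = 1.05 * f[:, [2, 0, 1]]
        assert lm.relative_error(est, f) == pytest.approx(
            lm.relative_error(1.05 * f, f)
        )

    def test_stacked_variant(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(size=(30, 2))
        assert lm.relative_error(1.2 * f, f, stacked=True) == pytest.approx(0.2)


class TestBetaSearch:
    @pytest.fixture(scope="class")
    def two_gaussian_grid(self):
        x = np.linspace(-6, 6, 96)
        dx = x[1] - x[0]
        f1 = np.exp(-0.5 * (x + 3) ** 2)
        f1 /= f1.sum() * dx
        f2 = np.exp(-0.5 * (x - 3) ** 2)
        f2 /= f2.sum() * dx
        grid = lm.DensityGrid(0.5 * f1 + 0.5 * f2 + 1e-12, (96,), (dx,))
        return grid, np.column_stack([f1, f2])

    def test_single_beta_returned_trivially(self, two_gaussian_grid):
        grid, truth = two_gaussian_grid
        best, curve = lm.beta_search(
            grid, 2, [1.5], lm.SearchParams(seed=0, n_restarts=6), truth=truth
        )
        assert best == 1.5
        assert len(curve) == 1

    def test_well_separated_mixture_recovered(self, two_gaussian_grid):
        grid, truth = two_gaussian_grid
        best, curve = lm.beta_search(
            grid, 2, [0.5, 1.0, 2.0, 4.0],
            lm.SearchParams(seed=3, n_restarts=6), truth=truth,
        )
        ok = curve[curve["status"] == "ok"]
        assert ok["relative_error"].min() < 0.1
        assert len(curve) == 4

    def test_rejects_bad_betas(self, two_gaussian_grid):
        grid, _ = two_gaussian_grid
        with pytest.raises(ValueError, match="positive"):
            lm.beta_search(grid, 2, [-1.0])


class TestSilhouetteProfile:
    def _model_with_labels(self, labels, m):
        n = len(labels)
        p = np.eye(m)[labels]
        return LaplacianMixtureModel(
            p=p, M_star=np.eye(m), loss=0.1,
            component_losses=np.zeros(m), weights=np.full(m, 1 / m),
            labels=np.asarray(labels), m=m,
        )

    def test_separated_blobs_score_near_one(self):
        rng = np.random.default_rng(0)
        feats = np.vstack([
            rng.normal(size=(40, 2)) * 0.05,
            rng.normal(size=(40, 2)) * 0.05 + 20.0,
        ])
        model = self._model_with_labels([0] * 40 + [1] * 40, 2)
        score = lm.silhouette_profile(model, feats, subsample_size=80, seed=1)
        assert score > 0.9

    def test_random_labels_score_near_zero(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(500, 2))
        labels = rng.integers(0, 2, size=500)
        model = self._model_with_labels(labels.tolist(), 2)
        score = lm.silhouette_profile(model, feats, subsample_size=500, seed=2)
        assert abs(score) < 0.1

    def test_subsampling_is_seeded(self):
        rng = np.random.default_rng(2)
        feats = rng.normal(size=(100, 2))
        labels = ([0] * 50 + [1] * 50)
        model = self._model_with_labels(labels, 2)
        s1 = lm.silhouette_profile(model, feats, n_subsamples=4,
                                   subsample_size=30, seed=7)
        s2 = lm.silhouette_profile(model, feats, n_subsamples=4,
                                   subsample_size=30, seed=7)
        assert s1 == s2


class TestSelectModel:
    def _sequence(self, losses):
        models = []
        for i, L in enumerate(losses):
            m = i + 2
            models.append(LaplacianMixtureModel(
                p=np.ones((4, m)) / m, M_star=np.eye(m), loss=L,
                component_losses=np.zeros(m), weights=np.full(m, 1 / m),
                labels=np.zeros(4, dtype=int), m=m,
            ))
        return ModelSequence(models=models)

    def test_single_positive_outlier_chosen(self):
        losses = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        scores = [1.0 - L for L in losses]
        scores[3] += 0.3  # m = 5 sits above the line
        seq = self._sequence(losses)
        assert lm.select_model(seq, scores) == 5

    def test_highest_dimensional_positive_residual_wins(self):
        losses = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        scores = [1.0 - L for L in losses]
        scores[1] += 0.3  # m = 3
        scores[5] += 0.25  # m = 7
        seq = self._sequence(losses)
        assert lm.select_model(seq, scores) == 7

    def test_fallback_to_smallest_m(self):
        losses = [0.1, 0.2, 0.3]
        scores = [0.0, 0.0, 0.0]
        seq = self._sequence(losses)
        with pytest.warns(UserWarning, match="residual"):
            assert lm.select_model(seq, scores) == 2

    def test_requires_three_models(self):
        seq = self._sequence([0.1, 0.2])
        with pytest.raises(ValueError, match="3 models"):
            lm.select_model(seq, [0.5, 0.4])


class TestModelSequence:
    def test_sequence_truncates_at_first_degenerate_m(self, spec_345):
        graph = lm.interpolating_cluster_graph(spec_345)
        seq = fit_model_sequence(
            lm.build_laplacian(graph), m_max=5,
            params=lm.SearchParams(seed=1, n_restarts=6),
        )
        assert seq.ms[:2] == [2, 3]
        assert seq.statuses[2] == "ok" and seq.statuses[3] == "ok"
        # whatever m it stops at, the statuses past the last model are absent
        last = seq.ms[-1]
        assert set(seq.statuses) == set(range(2, last + 2)) or last == 5


class TestKnnGridSearch:
    def test_single_cell_grid(self, spec_345):
        graph = lm.interpolating_cluster_graph(spec_345)
        table = lm.knn_grid_search(
            graph, [0], [6], m=3,
            params=lm.SearchParams(seed=0, n_restarts=6),
        )
        assert len(table) == 1
        assert table.iloc[0]["status"] == "ok"

    def test_recovers_block_sizes_on_noisy_graph(self):
        spec = lm.ClusterGraphSpec(3, (10, 20, 30), 0.5)
        graph = lm.add_noise(
            lm.interpolating_cluster_graph(spec), lm.NoiseSpec(0.2, 0, seed=4)
        )
        table = lm.knn_grid_search(
            graph, [1], [15, 25], m=3,
            params=lm.SearchParams(seed=2, n_restarts=10),
        )
        ok = table[table["status"] == "ok"]
        assert not ok.empty
        sizes = ok.iloc[0]["sizes"]
        assert sizes[0] >= 25 and sizes[0] <= 35
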