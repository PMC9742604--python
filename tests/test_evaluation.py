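"""Metrics, cross-validation mechanics, ROI shielding, altered connectivity."""

import numpy as np
import pytest

from atatnet import (altered_connectivity, compute_metrics, cross_validate,
                     roi_importance, shield)


class TestComputeMetrics:
    def test_confusion_arithmetic(self):
        # TP=3, TN=4, FP=1, FN=2 -> ACC = 7/10
        y_true = [1] * 5 + [0] * 5
        y_pred = [1, 1, 1, 0, 0, 0, 0, 0, 0, 1]
        m = compute_metrics(y_true, y_pred)
        assert m["TP"] == 3 and m["TN"] == 4 and m["FP"] == 1 and m["FN"] == 2
        assert np.isclose(m["ACC"], 0.7)
        assert np.isclose(m["SEN"], 3 / 5)
        assert np.isclose(m["SPE"], 4 / 5)
        # F1 = 2 * (3/4) * (3/5) / ((3/4) + (3/5)) = 2/3
        assert np.isclose(m["F1"], 2 / 3)

    def test_perfect_predictions(self):
        m = compute_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert m["ACC"] == m["SEN"] == m["SPE"] == m["F1"] == 1.0

    def test_degenerate_denominator_warns_and_zeroes(self):
        with pytest.warns(RuntimeWarning):
            m = compute_metrics([0, 0], [0, 0])
        assert m["SEN"] == 0.0 and m["ACC"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])


class TestCrossValidateMechanics:
    """Fold arithmetic checked with a stub trainer (no network fits)."""

    def _run(self, subjects, model_config, n_repeats=1, seed=0):
        from atatnet import TrainConfig

        class StubModel:
            pass

        calls = []

        def train_fn(model, train_subjects, cfg):
            model._train_ids = [s.subject_id for s in train_subjects]
            calls.append(model._train_ids)
            model.predict = lambda subj, path="generated": subj.label  # oracle
        frame = cross_validate(subjects, model_config, TrainConfig(epochs=1),
                               n_folds=2, n_repeats=n_repeats, seed=seed,
                               train_fn=lambda m, s, c: train_fn(m, s, c))
        return frame, calls

    def test_every_subject_tested_exactly_once_per_repeat(self, tiny_cohort,
                                                          tiny_model_config):
        frame, calls = self._run(list(tiny_cohort), tiny_model_config)
        assert len(frame) == 2  # 2 folds x 1 repeat
        tested = 6 * 1 - sum(len(c) for c in calls) + 6 * (1 - 1)
        # each fold trains on the complement: 2 folds of 3 train subjects each
        assert sorted(len(c) for c in calls) == [3, 3]
        union = set(calls[0]) | set(calls[1])
        assert len(union) == 6  # partition property

    def test_same_master_seed_reproduces_folds(self, tiny_cohort, tiny_model_config):
        _, calls_a = self._run(list(tiny_cohort), tiny_model_config, seed=5)
        _, calls_b = self._run(list(tiny_cohort), tiny_model_config, seed=5)
        assert calls_a == calls_b

    def test_undersized_class_rejected(self, tiny_cohort, tiny_model_config):
        from atatnet import TrainConfig
        with pytest.raises(ValueError, match="strat"):
            cross_validate(list(tiny_cohort)[:4], tiny_model_config,
                           TrainConfig(), n_folds=5, n_repeats=1)


class TestShielding:
    def test_shield_zeroes_row_and_column_keeps_diag(self):
        f = np.ones((4, 6))
        a = np.full((4, 4), 0.5)
        np.fill_diagonal(a, 1.0)
        fs, as_ = shield(f, a, 2)
        assert np.all(fs[2] == 0) and np.all(fs[[0, 1, 3]] == 1)
        assert np.all(as_[2, [0, 1, 3]] == 0) and np.all(as_[[0, 1, 3], 2] == 0)
        assert as_[2, 2] == 1.0
        assert np.all(as_[np.ix_([0, 1, 3], [0, 1, 3])] == a[np.ix_([0, 1, 3], [0, 1, 3])])

    def test_importance_ranking_is_roi_permutation(self, tiny_cohort,
                                                   tiny_model_config):
        from atatnet import ATATModel
        model = ATATModel(tiny_model_config)
        frame = roi_importance(model, list(tiny_cohort)[:2], path="empirical")
        assert sorted(frame["roi"]) == [1, 2, 3, 4]
        assert list(frame["rank"]) == [1, 2, 3, 4]
        assert frame["shielded_acc"].is_monotonic_increasing


class TestAlteredConnectivity:
    def _toy(self, values):
        """Symmetric 5x5 matrix whose upper triangle holds ``values``."""
        m = np.zeros((5, 5))
        iu, ju = np.triu_indices(5, k=1)
        m[iu, ju] = values
        return m + m.T + np.eye(5)

    def test_identical_groups_give_null_result(self):
        m = self._toy(np.arange(10.0))
        res = altered_connectivity([m, m], [m])
        assert np.allclose(res.difference, 0.0)
        assert res.reduced_edges == [] or all(v == 0 for _, _, v in res.top_edges)

    def test_quantile_threshold_matches_order_statistic_oracle(self):
        # |D| upper triangle = 1..10; linear-interpolation 90% quantile = 9.1,
        # so exactly the largest entry survives
        diff = self._toy(np.arange(1.0, 11.0)) - np.eye(5)
        res = altered_connectivity([diff + np.eye(5)], [np.eye(5)])
        sorted_abs = np.sort(np.arange(1.0, 11.0))
        k = 0.9 * 9
        oracle = sorted_abs[8] + (k - 8) * (sorted_abs[9] - sorted_abs[8])
        assert np.isclose(res.threshold, oracle)  # = 9.1
        survivors = res.reduced_edges + res.increased_edges
        assert len(survivors) == 1
        assert survivors[0][2] == 10.0

    def test_partition_is_disjoint_and_sign_consistent(self, rng):
        a = [rng.uniform(size=(6, 6)) for _ in range(3)]
        b = [rng.uniform(size=(6, 6)) for _ in range(3)]
        a = [(m + m.T) / 2 for m in a]
        b = [(m + m.T) / 2 for m in b]
        res = altered_connectivity(a, b)
        reduced = {(i, j) for i, j, _ in res.reduced_edges}
        increased = {(i, j) for i, j, _ in res.increased_edges}
        assert not reduced & increased
        for i, j, v in res.reduced_edges:
            assert v < 0 and res.difference[i, j] == v
        for i, j, v in res.increased_edges:
            assert v > 0

    def test_top_lists_ranked_by_magnitude_with_lexicographic_ties(self):
        vals = np.array([5.0, -5.0, 3.0, 0.1, 0.2, -0.3, 0.4, -0.1, 0.05, 0.0])
        res = altered_connectivity([self._toy(vals)], [np.eye(5)])
        mags = [abs(v) for _, _, v in res.top_edges]
        assert mags == sorted(mags, reverse=True)
        (i1, j1, v1) = res.top_edges[0]
        assert abs(v1) == 5.0 and (i1, j1) == (0, 1)  # tie broken lexicographically

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            altered_connectivity([np.eye(4)], [np.eye(5)])
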