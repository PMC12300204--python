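import numpy as np
import pytest

import gazeid as gz
from gazeid.errors import ValidationError
from gazeid.evaluation import stat_vectors


def kappa_contingency(pred, truth, l):
    """Independent Cohen's kappa from the raw contingency table."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    n = len(pred)
    table = np.zeros((l, l))
    for p, t in zip(pred, truth):
        table[t, p] += 1
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / n**2
    return (p_o - p_e) / (1 - p_e)


class TestSampleCounts:
    @pytest.mark.parametrize(
        "S,U,X,expected",
        [
            (9, 14, 50, (18900, 16800, 2100)),
            (9, 14, 35, (13230, 11760, 1470)),
            (9, 14, 25, (9450, 8400, 1050)),
            (8, 26, 50, (31200, 27300, 3900)),
            (7, 29, 50, (30450, 26100, 4350)),
            (6, 52, 50, (46800, 39000, 7800)),
            (5, 65, 50, (48750, 39000, 9750)),
            (4, 85, 50, (51000, 38250, 12750)),
            (3, 90, 50, (40500, 27000, 13500)),
        ],
    )
    def test_session_cohort_bookkeeping(self, S, U, X, expected):
        design = gz.ExperimentDesign(S=S, U=U, X=X, G=3)
        assert gz.sample_counts(design) == expected

    def test_degenerate_design(self):
        assert gz.sample_counts(gz.ExperimentDesign(S=1, U=1, X=1, G=1)) == (1, 0, 1)

    def test_per_user_per_session_sample_formula(self):
        d = gz.ExperimentDesign(S=9, U=14, X=50)
        assert d.fv_per_session == 150
        assert d.fv_total == 1350


class TestLosoSplit:
    def test_one_fold_per_session_partitioning_samples(self):
        sessions = np.repeat([f"R{k}" for k in range(9)], 10)
        folds = gz.loso_split(sessions)
        assert len(folds) == 9
        seen = np.concatenate([test for _, test, _ in folds])
        assert sorted(seen.tolist()) == list(range(90))
        for train, test, s in folds:
            assert set(train) & set(test) == set()
            assert set(sessions[test]) == {s}
            assert s not in set(sessions[train])

    def test_fold_sizes_match_counting_formula(self, cohort_samples, cohort_design):
        total, n_train, n_test = gz.sample_counts(cohort_design)
        assert len(cohort_samples) == total
        for train, test, _ in gz.loso_split(cohort_samples.session_ids):
            assert (len(train), len(test)) == (n_train, n_test)

    def test_single_session_rejected(self):
        with pytest.raises(ValidationError):
            gz.loso_split(np.array(["R0"] * 5))


class TestFusion:
    def test_single_vector_is_identity(self):
        np.testing.assert_allclose(
            gz.fuse_probabilities(np.array([[0.3, 0.7]])), [0.3, 0.7]
        )

    def test_hand_computed_mean(self):
        fused = gz.fuse_probabilities(np.array([[0.6, 0.4], [0.2, 0.8]]))
        np.testing.assert_allclose(fused, [0.4, 0.6])

    def test_fused_vector_stays_normalized(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(5), size=30)
        assert gz.fuse_probabilities(p).sum() == pytest.approx(1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(4), size=12)
        shuffled = p[rng.permutation(12)]
        np.testing.assert_allclose(
            gz.fuse_probabilities(p), gz.fuse_probabilities(shuffled)
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            gz.fuse_probabilities(np.empty((0, 3)))

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValidationError):
            gz.fuse_probabilities(np.array([[0.5, 0.1]]))


class TestDecision:
    def test_argmax(self):
        assert gz.decide_label(np.array([0.1, 0.7, 0.2])) == 1

    def test_tie_breaks_to_lowest_index(self):
        assert gz.decide_label(np.array([0.5, 0.5])) == 0

    def test_one_hot(self):
        assert gz.decide_label(np.array([0.0, 0.0, 1.0])) == 2


class TestMetrics:
    def test_perfect_agreement(self):
        assert gz.compute_metrics([0, 1, 2], [0, 1, 2], 3) == (1.0, 1.0, 1.0)

    def test_known_confusion_matrix(self):
        # truth-major table [[2,0],[1,1]]: p_o=0.75, p_e=0.5 -> kappa=0.5
        truth = [0, 0, 1, 1]
        pred = [0, 0, 0, 1]
        acc, _, kappa = gz.compute_metrics(pred, truth, 2)
        assert acc == pytest.approx(0.75)
        assert kappa == pytest.approx(0.5)

    def test_kappa_matches_contingency_formula_on_random_labels(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            l = int(rng.integers(2, 6))
            n = int(rng.integers(10, 60))
            truth = rng.integers(0, l, n)
            pred = rng.integers(0, l, n)
            _, _, kappa = gz.compute_metrics(pred, truth, l)
            assert kappa == pytest.approx(kappa_contingency(pred, truth, l), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            gz.compute_metrics([], [], 2)


class TestStatVectors:
    def test_matches_per_sample_builder(self, cohort_samples):
        from gazeid.features import build_stat_features

        scaled = cohort_samples.channels[:5]
        vecs = stat_vectors(scaled)
        for i in range(5):
            expected = build_stat_features(gz.TimeSeriesFeatures(scaled[i])).values
            np.testing.assert_allclose(vecs[i], expected)


class TestRunExperiment:
    def test_dense_run_structure_and_fold_count(self, cohort_samples, cohort_design):
        report = gz.run_experiment(
            cohort_samples,
            cohort_design,
            feature_set="stats",
            train_cfg=gz.TrainConfig(epochs=5, batch_size=128),
            seed=0,
        )
        assert len(report.folds) == cohort_design.S
        for fold in report.folds:
            assert fold.fused.shape == (cohort_design.U, cohort_design.l)
            np.testing.assert_allclose(fold.fused.sum(axis=1), 1.0, atol=1e-6)
            assert len(fold.decisions) == cohort_design.U
            assert len(fold.loss_trace) == 5
        for metric in ("accuracy", "f1", "kappa"):
            mean, std = report.summary[metric]
            assert 0.0 <= mean <= 1.0 and std >= 0.0

    def test_size_mismatch_rejected(self, cohort_samples):
        wrong = gz.ExperimentDesign(S=3, U=8, X=19)
        with pytest.raises(ValidationError):
            gz.run_experiment(cohort_samples, wrong)
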