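"""Metrics, ROC/AUC, fully-disordered calling, resampling significance."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import disofun as d


def pair_ordering_auc(prop: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force oracle: P(random positive ranked above random negative),
    counting ties as half."""
    pos = prop[labels == 1]
    neg = prop[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBinaryMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        rep = d.binary_metrics(y, y)
        assert rep.mcc == pytest.approx(1.0) and rep.f1 == pytest.approx(1.0)

    def test_inverted_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        rep = d.binary_metrics(y, 1 - y)
        assert rep.mcc == pytest.approx(-1.0)

    def test_hand_computed_counts(self):
        # TP=3, FP=1, FN=1, TN=5: F1 = 6/8, MCC = 14/sqrt(4*4*6*6) = 14/24
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        p = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        rep = d.binary_metrics(y, p)
        assert (rep.counts.tp, rep.counts.fp, rep.counts.fn, rep.counts.tn) == (3, 1, 1, 5)
        assert rep.f1 == pytest.approx(0.75)
        assert rep.mcc == pytest.approx(14 / 24)

    def test_degenerate_denominator_flagged_zero(self):
        rep = d.binary_metrics(np.array([1, 1]), np.array([1, 0]))
        assert rep.mcc == 0.0 and rep.mcc_degenerate

    def test_permutation_invariance_and_symmetry(self, rng):
        y = rng.integers(0, 2, 60)
        p = rng.integers(0, 2, 60)
        perm = rng.permutation(60)
        assert d.binary_metrics(y[perm], p[perm]).mcc == pytest.approx(
            d.binary_metrics(y, p).mcc
        )
        assert d.binary_metrics(p, y).mcc == pytest.approx(d.binary_metrics(y, p).mcc)

    def test_matches_sklearn_mcc(self, rng):
        from sklearn.metrics import matthews_corrcoef

        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        assert d.binary_metrics(y, p).mcc == pytest.approx(matthews_corrcoef(y, p))

    def test_pooling_over_proteins(self):
        ys = [np.array([1, 0]), np.array([1, 1, 0])]
        ps = [np.array([1, 0]), np.array([0, 1, 1])]
        pooled = d.binary_metrics(ys, ps)
        flat = d.binary_metrics(np.concatenate(ys), np.concatenate(ps))
        assert pooled.counts == flat.counts

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            d.binary_metrics(np.zeros(3), np.zeros(4))


class TestRocAuc:
    def test_perfect_ranking(self):
        y = np.array([0, 1, 0, 1])
        _, auc = d.roc_auc(y.astype(float), y)
        assert auc == pytest.approx(1.0)

    def test_constant_propensities_give_half(self):
        _, auc = d.roc_auc(np.full(10, 0.3), np.array([0, 1] * 5))
        assert auc == pytest.approx(0.5)

    def test_hand_counted_pairs(self):
        prop = np.array([0.9, 0.8, 0.7, 0.6])
        y = np.array([1, 0, 1, 0])
        _, auc = d.roc_auc(prop, y)
        assert auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotonicity(self, rng):
        prop = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        points, _ = d.roc_auc(prop, y)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
        fpr = [p[0] for p in points]
        tpr = [p[1] for p in points]
        assert all(a <= b + 1e-12 for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(tpr, tpr[1:]))

    def test_reversed_ranking_complements(self, rng):
        prop = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        _, auc = d.roc_auc(prop, y)
        _, rev = d.roc_auc(1 - prop, y)
        assert rev == pytest.approx(1 - auc)

    def test_exhaustive_small_inputs_match_pair_oracle(self):
        grid = [0.25, 0.5, 0.75]
        for L in (2, 3, 4):
            for prop in itertools.product(grid, repeat=L):
                for labels in itertools.product((0, 1), repeat=L):
                    labels = np.array(labels)
                    if labels.min() == labels.max():
                        continue
                    prop_arr = np.array(prop)
                    _, auc = d.roc_auc(prop_arr, labels)
                    assert auc == pytest.approx(pair_ordering_auc(prop_arr, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            d.roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestFullyDisordered:
    def test_all_disordered(self):
        assert d.fully_disordered_truth(np.ones(12))

    def test_boundary_19_of_20_counts_as_fully_disordered(self):
        labels = np.r_[np.ones(19), 0]
        assert d.fully_disordered_truth(labels)

    def test_18_of_20_does_not(self):
        assert not d.fully_disordered_truth(np.r_[np.ones(18), 0, 0])

    def test_length_one_chain(self):
        assert d.fully_disordered_prediction(np.array([1]))

    def test_protein_level_confusion(self):
        truths = [True, True, False, False]
        preds = [True, False, False, False]
        rep = d.evaluate_fully_disordered(truths, preds)
        assert (rep.counts.tp, rep.counts.fn, rep.counts.fp, rep.counts.tn) == (1, 1, 0, 2)
        assert rep.f1 == pytest.approx(2 / 3)

    def test_identical_calls_perfect_mcc(self):
        truths = [True] * 5 + [False] * 5
        rep = d.evaluate_fully_disordered(truths, truths)
        assert rep.mcc == pytest.approx(1.0)

    def test_single_class_truth_flags_degenerate_mcc_but_returns_f1(self):
        rep = d.evaluate_fully_disordered([True, True], [True, False])
        assert rep.mcc_degenerate and rep.f1 == pytest.approx(2 / 3)


class TestResampling:
    def _labels(self, rng, n=40, L=60):
        return [(rng.random(L) < 0.3).astype(int) for _ in range(n)]

    def test_identical_predictors_degenerate_p_one(self, rng):
        labels = self._labels(rng)
        a = [rng.random(60) for _ in labels]
        rep = d.resampling_significance(labels, a, a, metric="AUC", seed=3)
        assert rep.p_value == 1.0 and rep.degenerate and rep.test == "degenerate"

    def test_signal_vs_noise_significant(self, rng):
        labels = self._labels(rng, n=100)
        a = [y + rng.normal(0, 0.2, len(y)) for y in labels]
        b = [rng.random(len(y)) for y in labels]
        rep = d.resampling_significance(labels, a, b, metric="AUC", seed=3)
        assert rep.p_value < 0.05
        assert rep.test in ("paired_t", "wilcoxon")
        assert rep.normal is not None

    def test_replicate_count_and_pairing(self, rng):
        labels = self._labels(rng, n=20)
        a = [rng.random(60) for _ in labels]
        b = [rng.random(60) for _ in labels]
        rep = d.resampling_significance(labels, a, b, metric="F1", seed=5)
        assert len(rep.values_a) == len(rep.values_b) == rep.n_replicates == 10

    def test_single_class_half_samples_redrawn_and_recorded(self, rng):
        # only one of four proteins has positives: half-samples frequently
        # miss it and must be redrawn with an advanced seed
        labels = [np.array([1, 0, 1, 0]), np.zeros(4, int), np.zeros(4, int), np.zeros(4, int)]
        a = [rng.random(4) for _ in labels]
        b = [rng.random(4) for _ in labels]
        rep = d.resampling_significance(labels, a, b, metric="AUC", seed=2)
        assert len(rep.resampled_replicates) >= 1
        assert np.isfinite(rep.p_value)

    def test_too_few_proteins_rejected(self, rng):
        labels = self._labels(rng, n=3)
        a = [rng.random(60) for _ in labels]
        with pytest.raises(ValueError, match="at least 4"):
            d.resampling_significance(labels, a, a)

    def test_unsupported_metric_rejected(self, rng):
        labels = self._labels(rng, n=6)
        a = [rng.random(60) for _ in labels]
        with pytest.raises(ValueError, match="unsupported metric"):
            d.resampling_significance(labels, a, a, metric="accuracy")


@settings(derandomize=True, max_examples=80)
@given(st.data())
def test_randomized_roc_matches_oracle(data):
    L = data.draw(st.integers(2, 12))
    labels = np.array(data.draw(st.lists(st.integers(0, 1), min_size=L, max_size=L)))
    if labels.min() == labels.max():
        labels[0], labels[1] = 0, 1
    prop = np.array(
        data.draw(
            st.lists(
                st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.75, 1.0]),
                min_size=L,
                max_size=L,
            )
        )
    )
    _, auc = d.roc_auc(prop, labels)
    assert auc == pytest.approx(pair_ordering_auc(prop, labels))
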