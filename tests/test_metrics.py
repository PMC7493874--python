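import numpy as np
import pytest
from scipy.stats import chi2_contingency
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import roc_auc_score

from fpscreen.metrics import (
    ConfusionMatrix,
    MetricError,
    RankedScreen,
    auc,
    balanced_accuracy,
    bce_loss,
    confusion,
    enrichment_factor,
    evaluation_report,
    f1,
    mcc,
    sensitivity,
    specificity,
)


def brute_force_ef(ids, scores, labels, p):
    order = np.argsort(-np.asarray(scores), kind="stable")
    ranked = [labels[i] for i in order]
    window = int(np.floor(p * len(ids) / 100))
    hits = sum(ranked[:window])
    return window, hits, 100 * hits / min(window, sum(labels))


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self):
        cm = confusion([1] * 10 + [0] * 90, [1] * 10 + [0] * 90)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 90, 0, 0)

    def test_inverted_prediction(self):
        cm = confusion([1, 1, 0, 0], [0, 0, 1, 1])
        assert cm.tp == cm.tn == 0
        assert cm.fp == cm.fn == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_reference_counts(self, seed):
        rng = np.random.default_rng(seed)
        yt = rng.integers(0, 2, 200)
        yp = rng.integers(0, 2, 200)
        cm = confusion(yt, yp)
        ref = sk_confusion(yt, yp, labels=[0, 1])
        assert (cm.tn, cm.fp, cm.fn, cm.tp) == tuple(ref.ravel())

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricError):
            confusion([1, 0], [1])


class TestScalarMetrics:
    def test_balanced_accuracy_arithmetic(self):
        cm = ConfusionMatrix(tp=9, fn=1, tn=90, fp=0)
        assert balanced_accuracy(cm) == pytest.approx(0.95)

    def test_constant_classifier_scores_half(self):
        cm = confusion([1] * 10 + [0] * 90, [1] * 100)
        assert balanced_accuracy(cm) == pytest.approx(0.5)

    def test_perfect_classifier_tops_every_metric(self):
        cm = ConfusionMatrix(tp=10, fn=0, tn=90, fp=0)
        assert balanced_accuracy(cm) == sensitivity(cm) == specificity(cm) == 1.0
        assert f1(cm) == mcc(cm) == 1.0

    def test_mcc_zero_for_independent_margins(self):
        # counts in exact product proportions: prediction carries no signal
        cm = ConfusionMatrix(tp=10, fn=30, fp=40, tn=120)
        assert mcc(cm) == pytest.approx(0.0, abs=1e-12)

    def test_mcc_degenerate_margin_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert mcc(ConfusionMatrix(tp=5, fn=5, fp=0, tn=0)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_mcc_chi_square_identity(self, seed):
        rng = np.random.default_rng(seed)
        tp, fp, tn, fn = rng.integers(1, 200, 4)
        cm = ConfusionMatrix(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))
        table = [[cm.tp, cm.fn], [cm.fp, cm.tn]]
        chi2 = chi2_contingency(table, correction=False).statistic
        assert abs(mcc(cm)) == pytest.approx(np.sqrt(chi2 / cm.total), abs=1e-10)

    def test_metrics_invariant_to_sample_order(self, rng):
        yt = rng.integers(0, 2, 100)
        sc = rng.random(100)
        perm = rng.permutation(100)
        a = evaluation_report(yt, sc)
        b = evaluation_report(yt[perm], sc[perm])
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)


class TestAuc:
    def test_perfectly_separated(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]  # both classes present
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )
        assert auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = rng.random(100)
        assert auc(scores, labels) == pytest.approx(
            auc(np.exp(3 * scores), labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            auc([0.1, 0.9], [1, 1])


class TestBceLoss:
    def test_near_zero_for_confident_correct_scores(self):
        labels = [1, 1, 0, 0]
        assert bce_loss(labels, labels) == pytest.approx(0.0, abs=1e-6)

    def test_clipping_avoids_infinities(self):
        assert np.isfinite(bce_loss([0.0, 1.0], [1, 0]))


class TestEnrichmentFactor:
    def _screen(self, n, n_active, hits_in_window, window):
        """Screen with exactly hits_in_window actives in the top window."""
        labels = [1] * hits_in_window + [0] * (window - hits_in_window)
        rest_actives = n_active - hits_in_window
        labels += [1] * rest_actives + [0] * (n - len(labels) - rest_actives)
        scores = np.linspace(1, 0, n)
        return RankedScreen.from_predictions(
            [str(i) for i in range(n)], scores, labels
        )

    def test_reported_screen1_cell(self):
        # 701 compounds, 70 actives, 34 hits in the 5% window of 35
        screen = self._screen(701, 70, 34, 35)
        ef = enrichment_factor(screen, 5)
        assert (ef.window, ef.hits) == (35, 34)
        assert ef.percent == pytest.approx(97.14, abs=0.005)

    def test_reported_screen2_cell(self):
        # 3720 compounds, 80 actives, 65 hits in the 2% window of 74
        screen = self._screen(3720, 80, 65, 74)
        ef = enrichment_factor(screen, 2)
        assert (ef.window, ef.hits) == (74, 65)
        assert ef.percent == pytest.approx(87.84, abs=0.005)

    def test_perfect_ranking_hits_100_percent(self):
        screen = self._screen(200, 20, 10, 10)
        assert enrichment_factor(screen, 5).percent == 100.0

    def test_window_larger_than_actives_uses_active_count(self):
        # 20 hits, window 41 > 41 actives? window > P: denominator is P
        labels = [1] * 20 + [0] * 21 + [1] * 21 + [0] * 758
        screen = RankedScreen.from_predictions(
            [str(i) for i in range(820)], np.linspace(1, 0, 820), labels
        )
        ef = enrichment_factor(screen, 5)
        assert ef.window == 41
        assert ef.percent == pytest.approx(100 * 20 / 41)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_screens(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 10_000))
        labels = (rng.random(n) < 0.1).astype(int)
        labels[0] = 1
        scores = rng.random(n)
        screen = RankedScreen.from_predictions(
            [str(i) for i in range(n)], scores, labels
        )
        for p in (1, 2, 5, 10):
            window, hits, pct = brute_force_ef(list(range(n)), scores, labels, p)
            if window == 0:
                continue
            ef = enrichment_factor(screen, p)
            assert (ef.window, ef.hits) == (window, hits)
            assert ef.percent == pytest.approx(pct, abs=1e-12)

    def test_ties_broken_by_stable_input_order(self):
        screen = RankedScreen.from_predictions(
            ["a", "b", "c", "d"], [0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]
        )
        assert screen.ids == ("a", "b", "c", "d")

    def test_empty_window_rejected(self):
        screen = RankedScreen.from_predictions(["a", "b"], [0.9, 0.1], [1, 0])
        with pytest.raises(MetricError, match="window"):
            enrichment_factor(screen, 1)
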