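"""AUC / RFPP / confusion metrics and the cross-validation protocols."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from ppisites.datasets import build_dataset
from ppisites.evaluation import (ScoredComplex, auc, confusion_at,
                                 evaluate_scored, first_positive_rank,
                                 kfold_cv, loco_cv, rfpp)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_example(self):
        # positives at ranks 1 and 3 of four: 3 of 4 pos-neg comparisons won
        assert auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_all_tied_scores_give_half(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_agrees_with_sklearn_and_trapezoid(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(5, 40)
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        a = auc(scores, labels)
        assert auc(np.exp(5 * scores), labels) == pytest.approx(a)


class TestRfpp:
    def test_first_positive_rank_basic(self):
        assert first_positive_rank([0.9, 0.5, 0.4], [0, 1, 1]) == 2

    def test_ties_get_pessimistic_rank(self):
        # one positive tied with four negatives: worst rank of the tie group
        assert first_positive_rank([0.5] * 5, [1, 0, 0, 0, 0]) == 5

    def test_worked_percentile_examples(self):
        ranks = [1, 3, 7, 20]
        assert rfpp(ranks, 25) == 1
        assert rfpp(ranks, 50) == 3
        assert rfpp(ranks, 100) == 20

    def test_all_top_ranked(self):
        for p in (10, 50, 100):
            assert rfpp([1, 1, 1], p) == 1

    def test_single_complex(self):
        for p in (10, 100):
            assert rfpp([7], p) == 7

    def test_monotone_in_percentage(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ranks = rng.integers(1, 500, size=rng.integers(2, 15)).tolist()
            qs = [rfpp(ranks, p) for p in (10, 25, 50, 75, 90, 100)]
            assert qs == sorted(qs)

    def test_matches_direct_enumeration(self):
        """RFPP(p) is the smallest q covering >= p% of complexes."""
        rng = np.random.default_rng(4)
        ranks = rng.integers(1, 60, size=9).tolist()
        for p in (10, 30, 50, 77, 100):
            q = rfpp(ranks, p)
            cover = lambda t: 100.0 * sum(r <= t for r in ranks) / len(ranks)
            assert cover(q) >= p
            assert q == 1 or cover(q - 1) < p


class TestConfusion:
    def test_zero_threshold_predicts_everything_positive(self):
        ntp, ntn, nfp, nfn = confusion_at([0.2, 0.8], [0, 1], 0.0)
        assert (ntp, ntn, nfp, nfn) == (1, 0, 1, 0)

    def test_above_max_threshold_predicts_nothing(self):
        ntp, ntn, nfp, nfn = confusion_at([0.2, 0.8], [0, 1], 0.81)
        assert (ntp, nfp) == (0, 0) and (ntn, nfn) == (1, 1)

    def test_matches_bruteforce_recount_and_conserves_total(self):
        rng = np.random.default_rng(5)
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        for thr in (0.0, 0.3, 0.62, 1.0):
            ntp, ntn, nfp, nfn = confusion_at(scores, labels, thr)
            want = [0, 0, 0, 0]
            for s, l in zip(scores, labels):
                pred = s >= thr
                if pred and l == 1: want[0] += 1
                elif not pred and l == 0: want[1] += 1
                elif pred and l == 0: want[2] += 1
                else: want[3] += 1
            assert [ntp, ntn, nfp, nfn] == want
            assert ntp + ntn + nfp + nfn == 20


class RecordingStub(BaseEstimator, ClassifierMixin):
    """Deterministic stub scoring by a fixed feature; records training markers."""

    seen: list = []

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        RecordingStub.seen.append(set(np.unique(X[..., 0, 0, 0]).tolist()))
        return self

    def predict_proba(self, X):
        s = 1 / (1 + np.exp(-X[:, 0, 0, 0]))
        return np.column_stack([1 - s, s])


def marked_datasets(n_complexes=4, seed=0):
    """Complexes whose pairs carry a per-complex marker in feature 0."""
    from ppisites.datasets import FeaturizedComplex
    from ppisites.interface import PairLabel
    rng = np.random.default_rng(seed)
    out = []
    for c in range(n_complexes):
        n = 30
        y = (rng.random(n) < 0.2).astype(int)
        y[0] = 1
        y[1] = 0
        X = rng.standard_normal((n, 2, 217, 1)) + y[:, None, None, None]
        X[:, 0, 0, 0] = c  # complex marker
        pairs = [PairLabel(("A", i), ("B", i), "A", "L", 3.0 if t else 9.0, int(t))
                 for i, t in enumerate(y)]
        out.append(FeaturizedComplex(f"C{c}", pairs, X, y))
    return build_dataset(out, "none")


class TestLocoCv:
    def test_each_round_excludes_held_out_complex(self):
        ds = marked_datasets(3)
        RecordingStub.seen = []
        report = loco_cv(ds, RecordingStub(), seed=0)
        assert len(RecordingStub.seen) == 3
        for held_idx, markers in enumerate(RecordingStub.seen):
            assert float(held_idx) not in markers
        assert set(report.per_complex_auc) == {"C0", "C1", "C2"}

    def test_needs_two_complexes(self):
        with pytest.raises(ValueError):
            loco_cv(marked_datasets(1), RecordingStub(), seed=0)

    def test_planted_signal_benchmark_with_linear_oracle(self):
        """A linear learner recovers the injected class signal across folds."""
        class Logi(LogisticRegression):
            def fit(self, X, y):
                return super().fit(X.reshape(len(X), -1), y)
            def predict_proba(self, X):
                return super().predict_proba(X.reshape(len(X), -1))

        from ppisites.pipeline import featurize_benchmark
        from ppisites.synth import SynthSpec, make_benchmark
        spec = SynthSpec(n_complexes=6, chain_lengths=(20, 20), interface_size=4,
                         signal_strength=3.0, seed=5)
        ds = build_dataset(featurize_benchmark(make_benchmark(spec), spec, seed=5))
        report = loco_cv(ds, Logi(max_iter=2000), seed=5)
        assert report.auc > 0.8
        assert list(report.rfpp_curve) == [10, 25, 50, 75, 90, 100]


class TestKfoldCv:
    def test_folds_partition_complexes(self):
        ds = marked_datasets(6)
        RecordingStub.seen = []
        kfold_cv(ds, RecordingStub(), k=3, seed=1)
        assert len(RecordingStub.seen) == 3
        held = [set(range(6)) - {int(m) for m in markers} for markers in RecordingStub.seen]
        all_held = set().union(*held)
        assert all_held == set(range(6))
        assert sum(len(h) for h in held) == 6

    def test_k_equal_n_reduces_to_loco(self):
        ds = marked_datasets(4)
        a = kfold_cv(ds, RecordingStub(), k=4, seed=2)
        b = loco_cv(ds, RecordingStub(), seed=2)
        assert a.per_complex_auc == b.per_complex_auc

    def test_same_seed_same_folds(self):
        ds = marked_datasets(5)
        RecordingStub.seen = []
        kfold_cv(ds, RecordingStub(), k=2, seed=3)
        first = list(RecordingStub.seen)
        RecordingStub.seen = []
        kfold_cv(ds, RecordingStub(), k=2, seed=3)
        assert RecordingStub.seen == first

    def test_fold_statistics_reported(self):
        ds = marked_datasets(6)
        report = kfold_cv(ds, RecordingStub(), k=3, seed=4)
        assert len(report.fold_aucs) == 3
        assert 0 <= report.mean_fold_auc <= 1
        assert report.sd_fold_auc >= 0


class TestEvaluateScored:
    def test_complex_without_positives_excluded_from_rfpp(self):
        good = ScoredComplex("G", np.array([0.9, 0.1]), np.array([1, 0]))
        empty = ScoredComplex("E", np.array([0.5, 0.4]), np.array([0, 0]))
        report = evaluate_scored([good, empty])
        assert list(report.first_ranks) == ["G"]
        assert report.rfpp_curve[100] == 1

    def test_confusion_totals_conserved_across_thresholds(self):
        rng = np.random.default_rng(6)
        sc = ScoredComplex("X", rng.random(30), rng.integers(0, 2, 30))
        report = evaluate_scored([sc], thresholds=(0.1, 0.5, 0.9))
        for counts in report.confusion.values():
            assert sum(counts) == 30
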