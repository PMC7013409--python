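"""AUC, rank-of-first-positive (RFPP), confusion counts, and CV drivers.

Evaluation follows the imbalanced-test protocol for docking-benchmark
complexes: the model is trained on balanced subsets drawn from the training
complexes and scored on *all* cross-chain pairs of each held-out complex.
The headline AUC pools the held-out scores; RFPP(p) is the smallest rank q
such that at least p% of complexes place a true interacting pair within
their top-q predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone

from .datasets import ComplexDataset, balanced_subsets
from .features import STRUCT5_SLICE

RFPP_PERCENTAGES = (10, 25, 50, 75, 90, 100)


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def first_positive_rank(scores, labels) -> int:
    """Rank (1-based, descending score) of the best-ranked positive.

    Tied scores receive the worst rank of their tie group, so the result is
    deterministic and pessimistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if (labels == 1).sum() == 0:
        raise ValueError("no positive pairs in complex")
    pos_scores = scores[labels == 1]
    # pessimistic rank of score s: #(> s) + #(== s)
    ranks = [(scores > s).sum() + (scores == s).sum() for s in np.unique(pos_scores)]
    return int(min(ranks))


def rfpp(first_ranks: list[int], p: float) -> int:
    """Smallest q such that >= p% of complexes have first-positive rank <= q."""
    if not first_ranks:
        raise ValueError("no complexes to evaluate")
    if not 0 < p <= 100:
        raise ValueError("p must be in (0, 100]")
    ranks = sorted(first_ranks)
    k = max(1, math.ceil(p * len(ranks) / 100.0))
    return int(ranks[k - 1])


def confusion_at(scores, labels, threshold: float) -> tuple[int, int, int, int]:
    """(NTP, NTN, NFP, NFN) with score >= threshold predicted positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    ntp = int((pred & (labels == 1)).sum())
    ntn = int((~pred & (labels == 0)).sum())
    nfp = int((pred & (labels == 0)).sum())
    nfn = int((~pred & (labels == 1)).sum())
    return ntp, ntn, nfp, nfn


@dataclass
class ScoredComplex:
    pdb_id: str
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must be aligned")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")


@dataclass
class EvalReport:
    auc: float
    rfpp_curve: dict[int, int]
    per_complex_auc: dict[str, float]
    first_ranks: dict[str, int]
    confusion: dict[float, tuple[int, int, int, int]] = field(default_factory=dict)
    fold_aucs: list[float] = field(default_factory=list)

    @property
    def mean_fold_auc(self) -> float:
        return float(np.mean(self.fold_aucs)) if self.fold_aucs else self.auc

    @property
    def sd_fold_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1)) if len(self.fold_aucs) > 1 else 0.0


def evaluate_scored(complexes: list[ScoredComplex],
                    percentages=RFPP_PERCENTAGES,
                    thresholds=()) -> EvalReport:
    """Pooled AUC + RFPP curve over scored complexes.

    Complexes without a positive pair are excluded from RFPP (with the pooled
    AUC still using their scores).
    """
    all_scores = np.concatenate([c.scores for c in complexes])
    all_labels = np.concatenate([c.labels for c in complexes])
    per_auc, firsts = {}, {}
    for c in complexes:
        if (c.labels == 1).any():
            firsts[c.pdb_id] = first_positive_rank(c.scores, c.labels)
            if (c.labels == 0).any():
                per_auc[c.pdb_id] = auc(c.scores, c.labels)
    curve = {int(p): rfpp(list(firsts.values()), p) for p in percentages}
    report = EvalReport(
        auc=auc(all_scores, all_labels),
        rfpp_curve=curve,
        per_complex_auc=per_auc,
        first_ranks=firsts,
    )
    for t in thresholds:
        report.confusion[float(t)] = confusion_at(all_scores, all_labels, t)
    return report


# ---------------------------------------------------------------------------
# Cross-validation drivers
# ---------------------------------------------------------------------------

def _fit_struct5_minmax(X_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    block = X_train[:, :, STRUCT5_SLICE, 0]
    lo = block.min(axis=(0, 1))
    hi = block.max(axis=(0, 1))
    span = np.where(hi > lo, hi - lo, 1.0)
    return lo, span


def _apply_struct5_minmax(X: np.ndarray, lo: np.ndarray, span: np.ndarray) -> np.ndarray:
    X = X.copy()
    X[:, :, STRUCT5_SLICE, 0] = (X[:, :, STRUCT5_SLICE, 0] - lo) / span
    return X


def _train_and_score(train_sets: list[ComplexDataset], test_X: np.ndarray,
                     estimator, n_subsets: int, seed: int) -> np.ndarray:
    X_pos = np.concatenate([d.X_pos for d in train_sets if len(d.X_pos)])
    X_neg = np.concatenate([d.X_neg for d in train_sets if len(d.X_neg)])
    lo, span = _fit_struct5_minmax(np.concatenate([X_pos, X_neg]))
    subsets = balanced_subsets(_apply_struct5_minmax(X_pos, lo, span),
                               _apply_struct5_minmax(X_neg, lo, span),
                               n_subsets=n_subsets, seed=seed)
    test_X = _apply_struct5_minmax(test_X, lo, span)
    probs = []
    for sub in subsets:
        model = clone(estimator)
        if "random_state" in model.get_params():
            model.set_params(random_state=sub.seed)
        model.fit(sub.X, sub.y)
        probs.append(model.predict_proba(test_X)[:, list(model.classes_).index(1)])
    return np.mean(probs, axis=0)


def loco_cv(datasets: list[ComplexDataset], estimator, n_subsets: int = 1,
            seed: int = 0, percentages=RFPP_PERCENTAGES) -> EvalReport:
    """Leave-one-complex-out: train balanced on the rest, score all pairs held out.

    Held-out scores never come from a model that saw the held-out complex;
    the struct-feature min-max normalisation is fit on the training folds only.
    """
    if len(datasets) < 2:
        raise ValueError("leave-one-complex-out needs at least 2 complexes")
    scored = []
    ss = np.random.SeedSequence(seed)
    for held, child in zip(datasets, ss.spawn(len(datasets))):
        train_sets = [d for d in datasets if d is not held]
        test_X = np.concatenate([held.X_pos, held.X_neg])
        test_y = np.concatenate([np.ones(len(held.X_pos), dtype=int),
                                 np.zeros(len(held.X_neg), dtype=int)])
        scores = _train_and_score(train_sets, test_X, estimator, n_subsets,
                                  int(child.generate_state(1)[0] % (2 ** 31)))
        scored.append(ScoredComplex(held.pdb_id, scores, test_y))
    return evaluate_scored(scored, percentages)


def kfold_cv(datasets: list[ComplexDataset], estimator, k: int = 5, seed: int = 0,
             n_subsets: int = 1, percentages=RFPP_PERCENTAGES) -> EvalReport:
    """k-fold CV with complexes (not pairs) as the split unit.

    Reports the pooled AUC/RFPP plus per-fold AUCs (mean +/- sd via
    ``mean_fold_auc``/``sd_fold_auc``).
    """
    if k < 2 or k > len(datasets):
        raise ValueError("need 2 <= k <= number of complexes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(datasets))
    folds = np.array_split(order, k)
    scored, fold_aucs = [], []
    ss = np.random.SeedSequence(seed)
    for fold, child in zip(folds, ss.spawn(k)):
        test_ids = set(fold.tolist())
        train_sets = [d for i, d in enumerate(datasets) if i not in test_ids]
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        held_list = [datasets[i] for i in fold]
        test_X = np.concatenate([np.concatenate([d.X_pos, d.X_neg]) for d in held_list])
        scores = _train_and_score(train_sets, test_X, estimator, n_subsets, sub_seed)
        fold_scored, pos = [], 0
        for d in held_list:
            n = len(d.X_pos) + len(d.X_neg)
            test_y = np.concatenate([np.ones(len(d.X_pos), dtype=int),
                                     np.zeros(len(d.X_neg), dtype=int)])
            fold_scored.append(ScoredComplex(d.pdb_id, scores[pos:pos + n], test_y))
            pos += n
        scored.extend(fold_scored)
        fold_scores = np.concatenate([c.scores for c in fold_scored])
        fold_labels = np.concatenate([c.labels for c in fold_scored])
        if (fold_labels == 1).any() and (fold_labels == 0).any():
            fold_aucs.append(auc(fold_scores, fold_labels))
    report = evaluate_scored(scored, percentages)
    report.fold_aucs = fold_aucs
    return report
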