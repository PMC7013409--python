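"""Per-complex datasets, positive-sample selection, and balanced undersampling.

Training sets are balanced by undersampling the (vastly larger) negative
class: each balanced subset keeps every positive and draws an equal number of
negatives without replacement. Several subsets may be drawn (negatives are
redrawn independently across subsets) and their models averaged at prediction
time, in the spirit of ensemble undersampling for imbalanced data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interface import PairLabel
from .propensity import filter_positives


@dataclass
class FeaturizedComplex:
    """All cross-chain pairs of one dimer with their feature blocks."""

    pdb_id: str
    pairs: list[PairLabel]
    X: np.ndarray                    # (n_pairs, 2, 217, 1)
    y: np.ndarray                    # (n_pairs,)

    def __post_init__(self):
        if len(self.pairs) != len(self.X) or len(self.X) != len(self.y):
            raise ValueError("pairs, X and y must be aligned")


@dataclass
class ComplexDataset:
    """Positive/negative split of one complex after sample selection."""

    pdb_id: str
    X_pos: np.ndarray
    X_neg: np.ndarray
    pos_pairs: list[PairLabel]
    neg_pairs: list[PairLabel]
    provenance: dict = field(default_factory=dict)


@dataclass
class BalancedSubset:
    X: np.ndarray
    y: np.ndarray
    seed: int


def build_dataset(complexes: list[FeaturizedComplex], filter_mode: str = "none",
                  high: set[tuple[str, str]] | None = None,
                  n_positives: int | None = None,
                  seed: int | None = None) -> list[ComplexDataset]:
    """Select positive samples per complex; negatives always pass untouched.

    ``filter_mode``:
      * ``"none"`` -- keep all distance-rule positives;
      * ``"high_propensity"`` -- keep positives whose residue-type pair is in
        ``high`` (either orientation);
      * ``"random_sample"`` -- draw ``n_positives`` positives uniformly
        without replacement across all complexes (seeded), as a composition
        control for the propensity filter.
    """
    if filter_mode not in ("none", "high_propensity", "random_sample"):
        raise ValueError(f"unknown filter_mode {filter_mode!r}")

    keep_masks: list[np.ndarray] = []
    for fc in complexes:
        pos_mask = fc.y == 1
        if filter_mode == "high_propensity":
            if high is None:
                raise ValueError("high_propensity mode needs the high-propensity pair set")
            kept = {id(pl) for pl in filter_positives(fc.pairs, high) if pl.y == 1}
            keep = np.array([pl.y == 1 and id(pl) in kept for pl in fc.pairs])
        else:
            keep = pos_mask.copy()
        keep_masks.append(keep)

    if filter_mode == "random_sample":
        if n_positives is None:
            raise ValueError("random_sample mode needs n_positives")
        total = int(sum(m.sum() for m in keep_masks))
        if n_positives > total:
            raise ValueError(f"requested {n_positives} positives but only {total} available")
        rng = np.random.default_rng(seed)
        flat = np.concatenate([np.flatnonzero(m) + off for m, off in
                               zip(keep_masks, np.cumsum([0] + [len(fc.y) for fc in complexes[:-1]]))])
        chosen = set(rng.choice(flat, size=n_positives, replace=False).tolist())
        off = 0
        for k, fc in enumerate(complexes):
            idx = np.flatnonzero(keep_masks[k]) + off
            keep_masks[k] = np.zeros(len(fc.y), dtype=bool)
            keep_masks[k][[i - off for i in idx if i in chosen]] = True
            off += len(fc.y)

    out = []
    for fc, keep in zip(complexes, keep_masks):
        neg_mask = fc.y == 0
        out.append(ComplexDataset(
            pdb_id=fc.pdb_id,
            X_pos=fc.X[keep],
            X_neg=fc.X[neg_mask],
            pos_pairs=[pl for pl, k in zip(fc.pairs, keep) if k],
            neg_pairs=[pl for pl, k in zip(fc.pairs, neg_mask) if k],
            provenance={"filter_mode": filter_mode, "seed": seed,
                        "n_distance_positives": int((fc.y == 1).sum())},
        ))
    return out


def balanced_subsets(X_pos: np.ndarray, X_neg: np.ndarray, n_subsets: int = 1,
                     seed: int | None = None) -> list[BalancedSubset]:
    """Balanced training subsets: all positives + |pos| negatives apiece.

    Negatives are drawn without replacement within a subset and independently
    across subsets.
    """
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    n_pos, n_neg = len(X_pos), len(X_neg)
    if n_pos < 1 or n_neg < n_pos:
        raise ValueError(f"need |neg| >= |pos| >= 1, got {n_pos} positives, {n_neg} negatives")
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_subsets):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(sub_seed)
        idx = rng.choice(n_neg, size=n_pos, replace=False)
        X = np.concatenate([X_pos, X_neg[idx]])
        y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_pos, dtype=int)])
        out.append(BalancedSubset(X, y, sub_seed))
    return out
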