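"""Residue abundance, interface contact propensity (RAIR), and sample filtering.

The central statistic is the relative abundance of interacting residues

    AR_i    = N_i / N                (background abundance of residue type i)
    AIR_ij  = M_ij / M_i             (conditional partner frequency at interfaces)
    RAIR_ij = AIR_ij / AR_j          (enrichment of partner j over background)

where M_ij counts interface contacts between residue types i and j, M_i is the
row total, and the background universe for AR is the protein *surface*. A pair
(i, j) has high binding propensity when RAIR_ij >= 1 (inclusive); positive
training pairs are kept only when their type pair is high-propensity.

Homotypic contact counting is configurable. ``homotypic="double"`` (default)
counts an (a, a) contact as two partner observations, which makes each AIR row
the exact conditional partner frequency, so RAIR is identically 1 when
contacts are composition-random. ``homotypic="single"`` counts it once; the
packaged reference matrix has visibly depressed diagonal cells, consistent
with that convention, so recomputation offers both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_ALPHABET, AA_INDEX
from .interface import PairLabel
from .resources import load_abundance_reference, load_rair_reference
from .structure import Structure, SurfaceParams, compute_asa, surface_residues


@dataclass
class AbundanceTable:
    counts: np.ndarray          # (20,) int, canonical alphabet order
    universe: str               # "whole" | "surface"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (20,):
            raise ValueError("counts must have 20 entries")
        if self.total == 0:
            raise ValueError(f"empty residue universe {self.universe!r}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def ar(self) -> np.ndarray:
        return self.counts / self.total

    def ar_of(self, aa: str) -> float:
        return float(self.ar[AA_INDEX[aa]])


@dataclass
class ContactCounts:
    m: np.ndarray               # (20, 20) int, symmetric
    homotypic: str = "double"

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=np.int64)
        if self.m.shape != (20, 20) or (self.m < 0).any():
            raise ValueError("m must be a nonnegative 20x20 matrix")
        if not (self.m == self.m.T).all():
            raise ValueError("contact counts must be symmetric")

    @property
    def row_totals(self) -> np.ndarray:
        return self.m.sum(axis=1)


@dataclass
class PropensityMatrix:
    air: np.ndarray             # (20, 20); rows with no contacts are NaN
    rair: np.ndarray            # (20, 20); NaN where undefined
    threshold: float = 1.0


@dataclass
class TendencyTable:
    """Interior/surface distribution tendency, AR_whole / AR_surface per residue.

    ``ratio`` is full precision; ``printed_ratio`` divides the 3-decimal
    rounded abundances and rounds to 2 decimals, the convention under which
    the reference table's printed column is exactly reproducible. Entries
    with zero surface abundance are NaN.
    """

    ratio: np.ndarray
    printed_ratio: np.ndarray

    def of(self, aa: str, printed: bool = False) -> float:
        v = (self.printed_ratio if printed else self.ratio)[AA_INDEX[aa]]
        return float(v)


def abundance(structures: list[Structure], universe: str = "whole",
              p: SurfaceParams | None = None, asa_results=None) -> AbundanceTable:
    """Count residue types over structures, restricted to the given universe.

    ``universe="surface"`` keeps residues whose relative ASA meets the surface
    threshold; per-structure ASA is computed on demand unless ``asa_results``
    (parallel list) is provided.
    """
    if universe not in ("whole", "surface"):
        raise ValueError("universe must be 'whole' or 'surface'")
    p = p or SurfaceParams()
    counts = np.zeros(20, dtype=np.int64)
    for k, s in enumerate(structures):
        if universe == "surface":
            asa = asa_results[k] if asa_results is not None else compute_asa(s, p)
            keep = surface_residues(s, asa, p)
            residues = (r for r in s.residues() if r.key in keep)
        else:
            residues = s.residues()
        for r in residues:
            counts[AA_INDEX[r.aa]] += 1
    return AbundanceTable(counts, universe)


def contact_counts(pairsets: list[list[PairLabel]], homotypic: str = "double") -> ContactCounts:
    """Accumulate the symmetric 20x20 contact-count matrix from positive pairs.

    Each heterotypic pair (a, b) increments both m[a][b] and m[b][a]; a
    homotypic pair (a, a) increments m[a][a] twice under ``"double"`` (partner
    observations) or once under ``"single"``.
    """
    if homotypic not in ("double", "single"):
        raise ValueError("homotypic must be 'double' or 'single'")
    m = np.zeros((20, 20), dtype=np.int64)
    for pairs in pairsets:
        for pl in pairs:
            if pl.y != 1:
                raise ValueError("contact_counts expects positive pairs only")
            a, b = AA_INDEX[pl.aa_r], AA_INDEX[pl.aa_l]
            if a == b:
                m[a, a] += 2 if homotypic == "double" else 1
            else:
                m[a, b] += 1
                m[b, a] += 1
    return ContactCounts(m, homotypic)


def rair(c: ContactCounts, ar_table: AbundanceTable, threshold: float = 1.0) -> PropensityMatrix:
    """AIR and RAIR matrices from contact counts and a surface abundance table.

    Rows with no observed contacts are NaN. A partner type with zero
    background abundance but observed contacts is an error (the enrichment is
    undefined, not merely unobserved).
    """
    ar = ar_table.ar
    totals = c.row_totals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        air = np.where(totals[:, None] > 0, c.m / totals[:, None], np.nan)
    bad = (ar[None, :] == 0) & (c.m > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"partner type {AA_ALPHABET[j]} has zero surface abundance but "
            f"{c.m[i, j]} contacts with {AA_ALPHABET[i]}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(ar[None, :] > 0, air / ar[None, :], np.nan)
    return PropensityMatrix(air=air, rair=r, threshold=threshold)


def classify_high_propensity(pm: PropensityMatrix) -> set[tuple[str, str]]:
    """Ordered (i, j) type pairs with RAIR >= threshold (inclusive)."""
    out = set()
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            v = pm.rair[i, j]
            if np.isfinite(v) and v >= pm.threshold:
                out.add((a, b))
    return out


def high_propensity_partners(pm: PropensityMatrix, majority: int = 11) -> list[str]:
    """Partner residue types that are high-propensity for most (>= majority of 20) rows.

    Column-wise reading: partner type j counts when at least ``majority`` of
    the 20 rows have RAIR_ij >= threshold.
    """
    cols = np.nansum(pm.rair >= pm.threshold, axis=0)
    return [AA_ALPHABET[j] for j in range(20) if cols[j] >= majority]


def tendency(whole: AbundanceTable, surf: AbundanceTable) -> TendencyTable:
    """Distribution tendency AR_whole / AR_surface per residue type."""
    if whole.universe != "whole" or surf.universe != "surface":
        raise ValueError("tendency expects (whole, surface) abundance tables")
    ar_w, ar_s = whole.ar, surf.ar
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(ar_s > 0, ar_w / ar_s, np.nan)
        rw, rs = np.round(ar_w, 3), np.round(ar_s, 3)
        printed = np.where(rs > 0, np.round(rw / np.where(rs > 0, rs, 1), 2), np.nan)
    return TendencyTable(ratio=ratio, printed_ratio=printed)


def filter_positives(pairs: list[PairLabel], high: set[tuple[str, str]]) -> list[PairLabel]:
    """Keep positives whose type pair (either orientation) is high-propensity.

    Negatives pass through untouched.
    """
    out = []
    for pl in pairs:
        if pl.y == 0 or (pl.aa_r, pl.aa_l) in high or (pl.aa_l, pl.aa_r) in high:
            out.append(pl)
    return out


def reference_propensity_matrix(threshold: float = 1.0) -> PropensityMatrix:
    """The packaged reference RAIR matrix (AIR left NaN: not shipped)."""
    r = load_rair_reference()
    return PropensityMatrix(air=np.full((20, 20), np.nan), rair=r, threshold=threshold)


def reference_abundance(universe: str = "surface") -> AbundanceTable:
    """Abundance table of the packaged reference counts."""
    df = load_abundance_reference()
    col = "n_surface" if universe == "surface" else "n_whole"
    return AbundanceTable(df[col].to_numpy(), universe)
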