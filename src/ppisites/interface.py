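"""Cross-chain residue-pair enumeration and interface labelling.

A pair of residues from the two partner chains is *interacting* when the
minimum Euclidean distance over all heavy-atom pairs is less than or equal to
the cutoff (6 A by default, inclusive). All |chain1| x |chain2| cross-chain
pairs are enumerated; intra-chain contacts are never considered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure import Residue, Structure


@dataclass
class InterfaceParams:
    cutoff: float = 6.0  # Angstrom, inclusive

    def __post_init__(self):
        if self.cutoff < 0:
            raise ValueError("cutoff must be nonnegative")


@dataclass
class PairLabel:
    """One labelled cross-chain residue pair."""

    r_key: tuple[str, int]   # residue on chain 1
    l_key: tuple[str, int]   # residue on chain 2
    aa_r: str
    aa_l: str
    min_atom_distance: float
    y: int                   # 1 = interacting, 0 = not

    @property
    def aa_pair(self) -> tuple[str, str]:
        return (self.aa_r, self.aa_l)


def min_atom_distance(r: Residue, l: Residue) -> float:
    """Minimum Euclidean distance over all atom pairs of two residues."""
    if not r.atoms or not l.atoms:
        raise ValueError("residue with empty atom list")
    return float(cdist(r.coords(), l.coords()).min())


def label_pairs(s: Structure, p: InterfaceParams | None = None) -> list[PairLabel]:
    """Label every cross-chain residue pair of a dimer by the distance rule.

    Returns one :class:`PairLabel` per (chain-1 residue, chain-2 residue)
    combination, in row-major order, with ``y = 1`` iff the minimum heavy-atom
    distance is <= cutoff.
    """
    p = p or InterfaceParams()
    c1, c2 = s.partner_chains
    res1, res2 = s.chains[c1], s.chains[c2]
    if not res1 or not res2:
        return []

    coords1 = np.concatenate([r.coords() for r in res1])
    coords2 = np.concatenate([r.coords() for r in res2])
    idx1 = np.concatenate([[i] * len(r.atoms) for i, r in enumerate(res1)]).astype(int)
    idx2 = np.concatenate([[j] * len(r.atoms) for j, r in enumerate(res2)]).astype(int)

    d = cdist(coords1, coords2)
    mins = np.full((len(res1), len(res2)), np.inf)
    np.minimum.at(mins, (idx1[:, None], idx2[None, :]), d)

    out = []
    for i, r in enumerate(res1):
        for j, l in enumerate(res2):
            md = float(mins[i, j])
            out.append(PairLabel(r.key, l.key, r.aa, l.aa, md, int(md <= p.cutoff)))
    return out


def positives(pairs: list[PairLabel]) -> list[PairLabel]:
    return [pl for pl in pairs if pl.y == 1]


def pair_table(s: Structure, pairs: list[PairLabel]) -> pd.DataFrame:
    """Pair labels as a TSV-ready table with author residue numbering."""
    rows = []
    for pl in pairs:
        r = s.residue(pl.r_key)
        l = s.residue(pl.l_key)
        rows.append({
            "pdb_id": s.pdb_id,
            "chainR": r.chain_id, "resR": r.author_number, "aaR": r.aa,
            "chainL": l.chain_id, "resL": l.author_number, "aaL": l.aa,
            "min_dist": pl.min_atom_distance, "y": pl.y,
        })
    return pd.DataFrame(rows)
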