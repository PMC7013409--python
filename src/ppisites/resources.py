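"""Loaders for the packaged reference tables.

All tables ship as plain TSV under ``ppisites/data``:

* ``rair_reference.tsv`` -- 20x20 residue-pair binding-propensity (RAIR) matrix
  estimated on a curated docking-benchmark dimer set.
* ``abundance_reference.tsv`` -- residue counts/abundances over whole proteins
  and the protein surface of the same reference set.
* ``max_asa.tsv`` -- per-residue maximum accessible surface area (A^2).
* ``residue_scales.tsv`` -- hydrophobicity and polarity scales.
* ``physchem_groups.tsv`` -- 24 physicochemical properties, each splitting the
  alphabet into three groups (encoded one-hot into 72 dimensions).

Loaders return numpy arrays aligned with :data:`ppisites.alphabet.AA_ALPHABET`.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources as _ir

import numpy as np
import pandas as pd

from .alphabet import AA_ALPHABET


def _read(name: str, **kw) -> pd.DataFrame:
    with _ir.files("ppisites.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", **kw)


@lru_cache(maxsize=None)
def load_rair_reference() -> np.ndarray:
    """Packaged RAIR matrix as a (20, 20) array in canonical alphabet order.

    ``rair[i, j]`` is the propensity of partner type *j* at interfaces of
    residue type *i*.
    """
    df = _read("rair_reference.tsv", index_col=0)
    mat = df.loc[list(AA_ALPHABET), list(AA_ALPHABET)].to_numpy(dtype=float)
    assert mat.shape == (20, 20)
    return mat


@lru_cache(maxsize=None)
def load_abundance_reference() -> pd.DataFrame:
    """Reference residue counts/abundances, indexed by one-letter code.

    Columns: ``n_whole``, ``ar_whole``, ``n_surface``, ``ar_surface``.
    """
    df = _read("abundance_reference.tsv", index_col=0)
    return df.loc[list(AA_ALPHABET)]


@lru_cache(maxsize=None)
def load_max_asa() -> dict[str, float]:
    """Maximum ASA (A^2) per residue type."""
    df = _read("max_asa.tsv", index_col=0)
    return {aa: float(df.loc[aa, "max_asa"]) for aa in AA_ALPHABET}


@lru_cache(maxsize=None)
def load_hydrophobicity() -> dict[str, float]:
    """Per-residue hydrophobicity scale used as the fifth structure feature."""
    df = _read("residue_scales.tsv", index_col=0)
    return {aa: float(df.loc[aa, "hydrophobicity"]) for aa in AA_ALPHABET}


@lru_cache(maxsize=None)
def load_polarity() -> dict[str, float]:
    df = _read("residue_scales.tsv", index_col=0)
    return {aa: float(df.loc[aa, "polarity"]) for aa in AA_ALPHABET}


@lru_cache(maxsize=None)
def load_physchem_groups() -> tuple[np.ndarray, list[str]]:
    """24-property grouping table.

    Returns ``(groups, names)`` where ``groups`` is a (24, 20) int array of
    group indices in {0, 1, 2}, columns in canonical alphabet order.
    """
    df = _read("physchem_groups.tsv", index_col=0)
    groups = df[list(AA_ALPHABET)].to_numpy(dtype=int)
    assert groups.shape == (24, 20)
    assert np.isin(groups, [0, 1, 2]).all()
    return groups, list(df.index)
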