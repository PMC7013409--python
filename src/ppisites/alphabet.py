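"""Canonical amino-acid alphabet and name conversions.

The fixed one-letter ordering below defines the layout of every 20-wide
encoding in this package (one-hot vectors, abundance tables, propensity
matrices). All modules index residue types through this module so that the
ordering is defined in exactly one place.
"""

from __future__ import annotations

from Bio.Data.IUPACData import protein_letters_3to1

#: Canonical ordering of the 20 standard amino acids.
AA_ALPHABET: str = "ARNDCQEGHILKMFPSTWYV"

#: One-letter code -> position in :data:`AA_ALPHABET`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: Upper-case three-letter PDB residue name -> one-letter code (standard 20 only).
THREE_TO_ONE: dict[str, str] = {
    three.upper(): one
    for three, one in protein_letters_3to1.items()
    if one in AA_INDEX
}

ONE_TO_THREE: dict[str, str] = {one: three for three, one in THREE_TO_ONE.items()}


def aa_index(aa: str) -> int:
    """Return the canonical alphabet position of one-letter code ``aa``.

    Raises ``KeyError`` with a helpful message for nonstandard codes.
    """
    try:
        return AA_INDEX[aa]
    except KeyError:
        raise KeyError(f"nonstandard amino-acid code {aa!r}; expected one of {AA_ALPHABET}") from None


def is_standard_resname(resname: str) -> bool:
    """True if ``resname`` (three-letter, any case) is one of the standard 20."""
    return resname.upper() in THREE_TO_ONE
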