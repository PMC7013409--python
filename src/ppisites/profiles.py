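"""Reading and writing sequence profiles in PSI-BLAST ASCII matrix layout.

The ASCII PSSM produced by ``psiblast -out_ascii_pssm`` has, per residue row:
a position number, the query residue, 20 integer log-odds scores (PSSM) and 20
weighted observed percentages (PSFM), followed by two per-position statistics.
This module parses that layout into raw log-odds and frequencies in [0, 1],
and can emit files in the same layout (used by the synthetic-data generator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AA_ALPHABET

#: Column order used by PSI-BLAST matrix files.
PSIBLAST_COLUMNS = list("ARNDCQEGHILKMFPSTWYV")


@dataclass
class ProfileMatrix:
    """Per-residue PSSM (log-odds) and PSFM (frequencies) rows.

    Both arrays are (length, 20) with columns in canonical alphabet order.
    """

    pssm: np.ndarray
    psfm: np.ndarray
    sequence: str = ""

    def __post_init__(self):
        self.pssm = np.asarray(self.pssm, dtype=float)
        self.psfm = np.asarray(self.psfm, dtype=float)
        if self.pssm.shape != self.psfm.shape or self.pssm.ndim != 2 or self.pssm.shape[1] != 20:
            raise ValueError("pssm/psfm must both be (length, 20)")
        if (self.psfm < 0).any() or (self.psfm.sum(axis=1) > 1.0 + 1e-6).any():
            raise ValueError("psfm rows must be frequencies summing to <= 1")

    @property
    def length(self) -> int:
        return self.pssm.shape[0]


def read_psiblast_profile(text: str) -> ProfileMatrix:
    """Parse PSI-BLAST ASCII matrix text into a :class:`ProfileMatrix`.

    Rows must carry a position index, a residue letter, 20 log-odds integers
    and 20 percentage columns; malformed rows raise with their line number.
    """
    pssm_rows, psfm_rows, seq = [], [], []
    expected_pos = 1
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if len(parts) < 2 or not parts[0].isdigit():
            continue  # headers, column labels, trailing statistics
        if int(parts[0]) != expected_pos:
            continue  # e.g. a lambda/K footer that happens to start with digits
        if len(parts) < 42:
            raise ValueError(f"line {lineno}: expected >= 42 fields in profile row, got {len(parts)}")
        try:
            scores = [float(x) for x in parts[2:22]]
            pcts = [float(x) for x in parts[22:42]]
        except ValueError as e:
            raise ValueError(f"line {lineno}: malformed profile row ({e})") from None
        seq.append(parts[1])
        pssm_rows.append(scores)
        psfm_rows.append([v / 100.0 for v in pcts])
        expected_pos += 1
    if not pssm_rows:
        raise ValueError("no profile rows found in input")
    return ProfileMatrix(np.array(pssm_rows), np.array(psfm_rows), sequence="".join(seq))


def write_psiblast_profile(pm: ProfileMatrix) -> str:
    """Emit a profile in PSI-BLAST ASCII matrix layout (round-trips via the reader)."""
    if len(pm.sequence) != pm.length:
        raise ValueError("profile needs a sequence of matching length to be written")
    hdr = ("\nLast position-specific scoring matrix computed, weighted observed "
           "percentages rounded down, information per position, and relative "
           "weight of gapless real matches to pseudocounts\n")
    cols = "            " + "   ".join(PSIBLAST_COLUMNS) + "    " + "   ".join(PSIBLAST_COLUMNS)
    lines = [hdr, cols]
    for i in range(pm.length):
        scores = "".join(f"{int(round(v)):4d}" for v in pm.pssm[i])
        pcts = "".join(f"{int(round(v * 100)):4d}" for v in pm.psfm[i])
        lines.append(f"{i + 1:5d} {pm.sequence[i]} {scores} {pcts}  0.00 0.00")
    lines.append("")
    lines.append("                      K         Lambda")
    lines.append("Standard Ungapped    0.1358     0.3173")
    return "\n".join(lines) + "\n"
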