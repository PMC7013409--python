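"""Per-residue 217-dimensional feature encoding and residue-pair assembly.

Each residue is encoded as the concatenation of four blocks:

* ``onehot``   (20)  -- residue identity;
* ``profile``  (120) -- a length-3 window of profile rows, each row the
  squashed PSSM (20) followed by the PSFM (20); chain ends are zero-padded;
* ``physchem`` (72)  -- 24 properties x 3-group one-hot;
* ``struct5``  (5)   -- [ASA, RASA, protrusion CX, depth DPX, hydrophobicity].

A residue pair is a 2 x 217 x 1 block: row 1 the chain-1 residue, row 2 the
chain-2 residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .alphabet import AA_ALPHABET, aa_index
from .profiles import ProfileMatrix
from .resources import load_hydrophobicity, load_physchem_groups
from .structure import AsaResult, Residue, Structure, SurfaceParams

FEATURE_LENGTH = 217
#: Start/stop offsets of the four blocks within the 217-vector.
BLOCK_LAYOUT = {
    "onehot": (0, 20),
    "profile": (20, 140),
    "physchem": (140, 212),
    "struct5": (212, 217),
}
PROFILE_SLICE = slice(*BLOCK_LAYOUT["profile"])
STRUCT5_SLICE = slice(*BLOCK_LAYOUT["struct5"])

#: Radius (A) of the sphere used for the protrusion index.
CX_SPHERE_RADIUS = 10.0


def onehot(aa: str) -> np.ndarray:
    """20-dim identity encoding in canonical alphabet order."""
    v = np.zeros(20)
    v[aa_index(aa)] = 1.0
    return v


def physchem_encode(aa: str, groups: np.ndarray | None = None) -> np.ndarray:
    """72-dim encoding: for each of 24 properties, a 3-slot one-hot of the group."""
    if groups is None:
        groups, _ = load_physchem_groups()
    j = aa_index(aa)
    v = np.zeros(72)
    for k in range(24):
        v[3 * k + int(groups[k, j])] = 1.0
    return v


def squash(x: np.ndarray) -> np.ndarray:
    """Logistic squashing of raw log-odds scores into (0, 1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def profile_window(pm: ProfileMatrix, i: int, window: int = 3, squash_pssm: bool = True) -> np.ndarray:
    """Flattened window of profile rows centred at residue ``i`` (120 dims for window 3).

    Each in-chain row contributes squashed-PSSM (20) followed by PSFM (20);
    out-of-chain rows are all-zero padding. Rows are concatenated in order
    i-1, i, i+1 (row-major).
    """
    if not 0 <= i < pm.length:
        raise IndexError(f"residue index {i} out of range for chain of length {pm.length}")
    half = window // 2
    rows = []
    for k in range(i - half, i + half + 1):
        if 0 <= k < pm.length:
            s = squash(pm.pssm[k]) if squash_pssm else pm.pssm[k]
            rows.append(np.concatenate([s, pm.psfm[k]]))
        else:
            rows.append(np.zeros(40))
    return np.concatenate(rows)


def protrusion_index(coords: np.ndarray, radii: np.ndarray, tree: cKDTree | None = None) -> np.ndarray:
    """Per-atom protrusion index CX = V_ext / V_int within a 10 A sphere.

    V_int is the summed van der Waals volume of atoms inside the sphere
    (including the centre atom); V_ext is the sphere volume minus V_int.
    """
    tree = tree or cKDTree(coords)
    vol = 4.0 / 3.0 * np.pi * radii ** 3
    sphere = 4.0 / 3.0 * np.pi * CX_SPHERE_RADIUS ** 3
    out = np.empty(len(coords))
    for k, nbrs in enumerate(tree.query_ball_point(coords, CX_SPHERE_RADIUS)):
        v_int = vol[nbrs].sum()
        out[k] = max(sphere - v_int, 0.0) / v_int
    return out


def depth_index(coords: np.ndarray, atom_areas: np.ndarray) -> np.ndarray:
    """Per-atom depth DPX: 0 for solvent-accessible atoms, else distance to
    the nearest accessible atom."""
    accessible = atom_areas > 0
    out = np.zeros(len(coords))
    if accessible.all():
        return out
    if not accessible.any():
        raise ValueError("no solvent-accessible atoms; depth index undefined")
    tree = cKDTree(coords[accessible])
    buried = ~accessible
    out[buried] = tree.query(coords[buried])[0]
    return out


def structure_features(r: Residue, s: Structure, asa: AsaResult,
                       p: SurfaceParams | None = None,
                       hydrophobicity: dict[str, float] | None = None) -> np.ndarray:
    """[ASA, RASA, CX, DPX, hydrophobicity] for one residue.

    CX and DPX are computed against the same atom context used for the ASA
    (the residue's own chain for isolated context, the dimer for complex).
    """
    p = p or SurfaceParams()
    hydrophobicity = hydrophobicity or load_hydrophobicity()
    chain_ids = list(s.chains) if p.asa_context == "complex" else [r.chain_id]
    residues = [x for cid in chain_ids for x in s.chains[cid]]
    coords = np.concatenate([x.coords() for x in residues])
    radii = np.concatenate([[p.vdw_radii[a.element] for a in x.atoms] for x in residues])
    areas = np.concatenate([asa.per_atom[x.key] for x in residues])

    offsets = np.cumsum([0] + [len(x.atoms) for x in residues])
    pos = residues.index(r)
    sl = slice(offsets[pos], offsets[pos + 1])

    cx = protrusion_index(coords, radii)[sl].mean()
    dpx = depth_index(coords, areas)[sl].mean()
    a = asa.per_residue[r.key]
    return np.array([a, a / p.max_asa[r.aa], cx, dpx, hydrophobicity[r.aa]])


def residue_feature_vector(r: Residue, s: Structure, pm: ProfileMatrix, asa: AsaResult,
                           p: SurfaceParams | None = None) -> np.ndarray:
    """Assemble the full 217-dim feature vector for one residue."""
    v = np.concatenate([
        onehot(r.aa),
        profile_window(pm, r.seq_index),
        physchem_encode(r.aa),
        structure_features(r, s, asa, p),
    ])
    assert v.shape == (FEATURE_LENGTH,)
    return v


@dataclass
class PairInput:
    block: np.ndarray  # (2, 217, 1)
    y: int


def assemble_pair(r_features: np.ndarray, l_features: np.ndarray, y: int) -> PairInput:
    """Stack two per-residue vectors into the 2 x 217 x 1 pair block (row order r, l)."""
    r_features = np.asarray(r_features, dtype=float)
    l_features = np.asarray(l_features, dtype=float)
    for v in (r_features, l_features):
        if v.shape != (FEATURE_LENGTH,):
            raise ValueError(f"per-residue feature vector must have length {FEATURE_LENGTH}, got {v.shape}")
    return PairInput(np.stack([r_features, l_features])[:, :, None], int(y))


class PairFeaturizer:
    """Compute per-residue features once per complex and gather pair blocks.

    Parameters mirror the encoding defaults; the featurizer is deterministic
    given structure, profiles and packaged tables.
    """

    def __init__(self, surface_params: SurfaceParams | None = None, squash_pssm: bool = True):
        self.surface_params = surface_params or SurfaceParams()
        self.squash_pssm = squash_pssm

    def residue_features(self, s: Structure, profiles: dict[str, ProfileMatrix],
                         asa: AsaResult | None = None) -> dict[tuple[str, int], np.ndarray]:
        from .structure import compute_asa
        asa = asa or compute_asa(s, self.surface_params)
        groups, _ = load_physchem_groups()
        hyd = load_hydrophobicity()
        out = {}
        for cid, residues in s.chains.items():
            pm = profiles[cid]
            if pm.length != len(residues):
                raise ValueError(f"profile length {pm.length} != chain {cid} length {len(residues)}")
            for r in residues:
                out[r.key] = np.concatenate([
                    onehot(r.aa),
                    profile_window(pm, r.seq_index, squash_pssm=self.squash_pssm),
                    physchem_encode(r.aa, groups),
                    structure_features(r, s, asa, self.surface_params, hyd),
                ])
        return out

    def featurize_pairs(self, s: Structure, profiles: dict[str, ProfileMatrix],
                        pairs, asa: AsaResult | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) arrays for a list of pair labels; X has shape (n, 2, 217, 1)."""
        feats = self.residue_features(s, profiles, asa)
        X = np.stack([np.stack([feats[pl.r_key], feats[pl.l_key]]) for pl in pairs])[:, :, :, None]
        y = np.array([pl.y for pl in pairs], dtype=int)
        return X, y
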