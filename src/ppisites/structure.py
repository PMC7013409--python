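"""PDB parsing, solvent-accessible surface area, and surface-residue calls.

Structures are reduced to a light in-memory model (chains -> residues ->
heavy atoms) sufficient for interface geometry and surface statistics.
Parsing is delegated to Biopython; ASA is computed natively with a
Shrake-Rupley sphere sampling so that no external binary is needed, and
precomputed per-residue ASA tables can be injected instead (``read_asa_tsv``).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .alphabet import THREE_TO_ONE
from .resources import load_max_asa

log = logging.getLogger(__name__)

#: Van der Waals radii (A) for the heavy elements found in standard residues.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) float, Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.isfinite(self.coord).all():
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")


@dataclass
class Residue:
    aa: str                 # one-letter code
    chain_id: str
    seq_index: int          # 0-based ordinal within the chain
    author_number: str      # PDB residue number + insertion code
    atoms: list[Atom] = field(default_factory=list)
    asa: float | None = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_index)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class Structure:
    pdb_id: str
    chains: dict[str, list[Residue]]  # ordered: chain id -> residues

    @property
    def partner_chains(self) -> tuple[str, str]:
        ids = list(self.chains)
        if len(ids) != 2:
            raise ValueError(f"expected a dimer with 2 partner chains, got {ids}")
        return ids[0], ids[1]

    def residues(self):
        for residues in self.chains.values():
            yield from residues

    def residue(self, key: tuple[str, int]) -> Residue:
        return self.chains[key[0]][key[1]]


@dataclass
class SurfaceParams:
    """Parameters for ASA computation and surface-residue classification.

    ``rasa_threshold`` is inclusive: RASA >= threshold marks a surface residue.
    ``asa_context`` selects whether each partner chain is stripped out of the
    complex before its ASA is computed (``"isolated"``, the default) or the
    whole bound complex occludes (``"complex"``).
    """

    rasa_threshold: float = 0.16
    max_asa: dict[str, float] = field(default_factory=load_max_asa)
    probe_radius: float = 1.4
    sphere_points: int = 960
    asa_context: str = "isolated"
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))

    def __post_init__(self):
        if not 0.0 < self.rasa_threshold < 1.0:
            raise ValueError("rasa_threshold must lie in (0, 1)")
        if any(v <= 0 for v in self.max_asa.values()):
            raise ValueError("all max_asa entries must be positive")
        if self.asa_context not in ("isolated", "complex"):
            raise ValueError("asa_context must be 'isolated' or 'complex'")


def parse_structure(pdb_text: str, partner_chains: tuple[str, str], pdb_id: str = "") -> Structure:
    """Parse PDB-format text into a two-chain :class:`Structure`.

    Only standard amino-acid residues of the two partner chains are kept;
    hydrogens, deuteriums and HETATM records are dropped, and for alternate
    locations only the highest-occupancy conformer of each atom is retained.
    Residues left with no atoms are dropped with a warning. Only the first
    model of a multi-model file is read.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = parser.get_structure(pdb_id or "pdb", io.StringIO(pdb_text))[0]

    present = {c.id for c in model}
    chains: dict[str, list[Residue]] = {}
    for cid in partner_chains:
        if cid not in present:
            raise ValueError(f"chain {cid!r} not found in structure (has {sorted(present)})")
        residues: list[Residue] = []
        for res in model[cid]:
            hetflag, resseq, icode = res.id
            if hetflag != " " or res.get_resname().upper() not in THREE_TO_ONE:
                continue
            atoms: list[Atom] = []
            for atom in res.get_unpacked_list():
                element = (atom.element or "").strip().upper()
                if element in ("H", "D", ""):
                    continue
                atoms.append(Atom(
                    name=atom.get_name(),
                    element=element,
                    coord=np.asarray(atom.get_coord(), dtype=float),
                    occupancy=float(atom.get_occupancy() or 1.0),
                    altloc=(atom.get_altloc() or "").strip(),
                ))
            atoms = _dedupe_altlocs(atoms)
            if not atoms:
                log.warning("residue %s %s%s has no retained atoms; dropped",
                            res.get_resname(), resseq, icode.strip())
                continue
            residues.append(Residue(
                aa=THREE_TO_ONE[res.get_resname().upper()],
                chain_id=cid,
                seq_index=len(residues),
                author_number=f"{resseq}{icode.strip()}",
                atoms=atoms,
            ))
        chains[cid] = residues
    return Structure(pdb_id=pdb_id, chains=chains)


def _dedupe_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy conformer per atom name (file order breaks ties)."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def chain_sequence(s: Structure, chain_id: str) -> str:
    return "".join(r.aa for r in s.chains[chain_id])


# ---------------------------------------------------------------------------
# Shrake-Rupley ASA
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Nearly uniform unit-sphere points via a golden-spiral (Fibonacci) lattice."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi),
    ])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom accessible surface areas (A^2).

    Each atom's solvent-extended sphere (vdW + probe radius) is sampled with a
    fixed point lattice; a point is accessible when it lies outside every
    neighbouring atom's extended sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    unit = _sphere_points(n_points)
    ext = radii + probe_radius

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2.0 * ext.max(), output_type="ndarray")
    occluded = np.zeros((n, n_points), dtype=bool)
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < ext[pairs[:, 0]] + ext[pairs[:, 1]]]
        ii = np.concatenate([pairs[:, 0], pairs[:, 1]])
        jj = np.concatenate([pairs[:, 1], pairs[:, 0]])
        order = np.argsort(ii, kind="stable")
        ii, jj = ii[order], jj[order]
        # blocked so the (pairs x points) distance tensor stays small
        block = max(1, 4_000_000 // max(n_points, 1))
        for start in range(0, len(ii), block):
            ib, jb = ii[start:start + block], jj[start:start + block]
            pts = coords[ib, None, :] + ext[ib, None, None] * unit[None, :, :]
            d2 = ((pts - coords[jb, None, :]) ** 2).sum(axis=2)
            inside = d2 < ext[jb, None] ** 2
            uniq, starts = np.unique(ib, return_index=True)
            occluded[uniq] |= np.logical_or.reduceat(inside, starts, axis=0)
    return 4.0 * np.pi * ext ** 2 * (~occluded).mean(axis=1)


@dataclass
class AsaResult:
    """Per-residue and per-atom accessible areas for one structure."""

    per_residue: dict[tuple[str, int], float]
    per_atom: dict[tuple[str, int], np.ndarray]

    def __getitem__(self, key):
        return self.per_residue[key]


def compute_asa(s: Structure, p: SurfaceParams | None = None) -> AsaResult:
    """Per-residue ASA, summed from Shrake-Rupley per-atom accessible areas.

    With ``p.asa_context == "isolated"`` each chain is treated alone (the
    partner does not occlude); with ``"complex"`` all atoms of the bound dimer
    occlude each other. Raises on elements missing from the radius table.
    """
    p = p or SurfaceParams()
    chain_groups = ([list(s.chains)] if p.asa_context == "complex"
                    else [[cid] for cid in s.chains])
    per_residue: dict[tuple[str, int], float] = {}
    per_atom: dict[tuple[str, int], np.ndarray] = {}
    for group in chain_groups:
        residues = [r for cid in group for r in s.chains[cid]]
        coords, radii = [], []
        for r in residues:
            for a in r.atoms:
                if a.element not in p.vdw_radii:
                    raise ValueError(f"no van der Waals radius for element {a.element!r}")
                coords.append(a.coord)
                radii.append(p.vdw_radii[a.element])
        if not coords:
            continue
        areas = shrake_rupley(np.array(coords), np.array(radii),
                              p.probe_radius, p.sphere_points)
        pos = 0
        for r in residues:
            k = len(r.atoms)
            per_atom[r.key] = areas[pos:pos + k]
            per_residue[r.key] = float(areas[pos:pos + k].sum())
            r.asa = per_residue[r.key]
            pos += k
    return AsaResult(per_residue, per_atom)


def surface_residues(s: Structure, asa: AsaResult | dict, p: SurfaceParams | None = None
                     ) -> set[tuple[str, int]]:
    """Keys of residues whose relative ASA meets the (inclusive) threshold."""
    p = p or SurfaceParams()
    per_residue = asa.per_residue if isinstance(asa, AsaResult) else asa
    out: set[tuple[str, int]] = set()
    for r in s.residues():
        if r.aa not in p.max_asa:
            raise KeyError(f"no max ASA entry for residue type {r.aa!r}")
        if per_residue[r.key] / p.max_asa[r.aa] >= p.rasa_threshold:
            out.add(r.key)
    return out


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

def asa_table(s: Structure, asa: AsaResult, p: SurfaceParams | None = None) -> pd.DataFrame:
    """Per-residue ASA/RASA table (pdb_id, chain, resnum, aa, asa, rasa, is_surface)."""
    p = p or SurfaceParams()
    surf = surface_residues(s, asa, p)
    rows = []
    for r in s.residues():
        a = asa.per_residue[r.key]
        rows.append({
            "pdb_id": s.pdb_id, "chain": r.chain_id, "resnum": r.author_number,
            "aa": r.aa, "asa": a, "rasa": a / p.max_asa[r.aa],
            "is_surface": r.key in surf,
        })
    return pd.DataFrame(rows)


def read_asa_tsv(path_or_buf) -> dict[tuple[str, str], float]:
    """Read a precomputed per-residue ASA table (chain, resnum, asa columns).

    Keys are (chain, author residue number as string), so externally computed
    areas can be matched onto a parsed structure.
    """
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype={"chain": str, "resnum": str})
    return {(row.chain, row.resnum): float(row.asa) for row in df.itertuples()}


def apply_precomputed_asa(s: Structure, table: dict[tuple[str, str], float]) -> AsaResult:
    """Map an external (chain, resnum) -> ASA table onto structure residue keys."""
    per_residue = {}
    for r in s.residues():
        try:
            per_residue[r.key] = table[(r.chain_id, r.author_number)]
        except KeyError:
            raise KeyError(f"no precomputed ASA for {r.chain_id}/{r.author_number}") from None
        r.asa = per_residue[r.key]
    return AsaResult(per_residue, per_atom={})
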