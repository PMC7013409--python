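"""Shared fixtures: small synthetic complexes and hand-written PDB snippets."""

from __future__ import annotations

import numpy as np
import pytest

from ppisites.profiles import read_psiblast_profile
from ppisites.structure import Atom, Residue, Structure, SurfaceParams
from ppisites.synth import SynthSpec, make_structure, profile_for_chain


@pytest.fixture(scope="session")
def small_spec() -> SynthSpec:
    return SynthSpec(n_complexes=2, chain_lengths=(12, 12), interface_size=3, seed=7)


@pytest.fixture(scope="session")
def small_dimer(small_spec):
    """One small synthetic dimer with its ground truth."""
    return make_structure(small_spec, 0)


@pytest.fixture(scope="session")
def small_profiles(small_spec, small_dimer):
    s, truth = small_dimer
    return {cid: read_psiblast_profile(profile_for_chain(small_spec, 0, cid, truth.sequences[cid]))
            for cid in s.chains}


@pytest.fixture(scope="session")
def coarse_surface_params() -> SurfaceParams:
    """Coarser sphere sampling for speed where ASA precision is irrelevant."""
    return SurfaceParams(sphere_points=120)


def single_atom_residue(aa: str, chain: str, idx: int, coord) -> Residue:
    return Residue(aa, chain, idx, str(idx + 1), [Atom("CA", "C", np.asarray(coord, float))])


@pytest.fixture
def toy_two_chain():
    """Three + four single-atom residues; one cross pair exactly at 6 A."""
    a = [single_atom_residue("A", "A", i, (i * 20.0, 0, 0)) for i in range(3)]
    b = [single_atom_residue("G", "B", j, (j * 20.0, 6.0, 0)) for j in range(4)]
    return Structure("TOY", {"A": a, "B": b})


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  H   ALA A   1       2.000   1.000   0.000  1.00  0.00           H
ATOM      4  CA AALA B   1      10.000   0.000   0.000  0.60  0.00           C
ATOM      5  CA BALA B   1      12.000   0.000   0.000  0.40  0.00           C
HETATM    6  O   HOH B   2      20.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def minimal_pdb_text() -> str:
    return MINIMAL_PDB
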