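"""Abundance, contact counting, RAIR propensity, tendency ratios, filtering."""

import numpy as np
import pytest

from ppisites.alphabet import AA_ALPHABET, AA_INDEX
from ppisites.interface import PairLabel
from ppisites.propensity import (AbundanceTable, ContactCounts, abundance,
                                 classify_high_propensity, contact_counts,
                                 filter_positives, high_propensity_partners,
                                 rair, reference_abundance,
                                 reference_propensity_matrix, tendency)
from ppisites.structure import Structure
from ppisites.synth import SynthSpec, make_structure
from tests.conftest import single_atom_residue


def pos_pair(aa_r, aa_l):
    return PairLabel(("A", 0), ("B", 0), aa_r, aa_l, 3.0, 1)


class TestAbundance:
    def test_single_type_structure(self):
        res = [single_atom_residue("A", "A", i, (i * 30.0, 0, 0)) for i in range(10)]
        other = [single_atom_residue("A", "B", 0, (500, 0, 0))]
        s = Structure("X", {"A": res, "B": other})
        t = abundance([s], "whole")
        assert t.ar_of("A") == 1.0
        assert t.total == 11

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            AbundanceTable(np.zeros(20, dtype=int), "whole")

    def test_law_of_large_numbers(self):
        """Composition recovery from ~10,000 generated residues."""
        comp = np.full(20, 0.02)
        comp[AA_INDEX["L"]] = 0.42
        comp[AA_INDEX["E"]] = 0.22
        spec = SynthSpec(n_complexes=50, chain_lengths=(100, 100), interface_size=1,
                         composition=comp, seed=9)
        structs = [make_structure(spec, i)[0] for i in range(50)]
        t = abundance(structs, "whole")
        np.testing.assert_allclose(t.ar, comp, atol=0.01)

    def test_reference_counts_reproduce_printed_abundance(self):
        t = reference_abundance("whole")
        assert t.total == 133_795
        assert round(t.ar_of("A"), 3) == 0.071


class TestContactCounts:
    def test_heterotypic_pair_counts_both_directions(self):
        c = contact_counts([[pos_pair("A", "L")]])
        a, l = AA_INDEX["A"], AA_INDEX["L"]
        assert c.m[a, l] == 1 and c.m[l, a] == 1

    def test_homotypic_conventions(self):
        single = contact_counts([[pos_pair("A", "A")]], homotypic="single")
        double = contact_counts([[pos_pair("A", "A")]], homotypic="double")
        a = AA_INDEX["A"]
        assert single.m[a, a] == 1
        assert double.m[a, a] == 2

    def test_totals_match_direct_recount(self):
        rng = np.random.default_rng(3)
        pairs = [pos_pair(AA_ALPHABET[i], AA_ALPHABET[j])
                 for i, j in rng.integers(0, 20, size=(100, 2))]
        het = sum(1 for pl in pairs if pl.aa_r != pl.aa_l)
        hom = len(pairs) - het
        single = contact_counts([pairs], homotypic="single")
        double = contact_counts([pairs], homotypic="double")
        assert single.m.sum() == 2 * het + hom
        assert double.m.sum() == 2 * len(pairs)
        assert (single.m == single.m.T).all()

    def test_negatives_rejected(self):
        bad = PairLabel(("A", 0), ("B", 0), "A", "L", 9.0, 0)
        with pytest.raises(ValueError):
            contact_counts([[bad]])


class TestRair:
    def test_composition_random_contacts_give_unit_rair(self):
        """With AIR rows equal to the background, enrichment is exactly 1."""
        n = np.array([10, 20, 5, 8, 40, 17, 3, 9, 11, 6, 30, 25, 2, 4, 13, 7, 19, 22, 1, 14])
        c = ContactCounts(np.outer(n, n))
        ar = AbundanceTable(n, "surface")
        pm = rair(c, ar)
        np.testing.assert_allclose(pm.rair, np.ones((20, 20)), atol=1e-12)

    def test_air_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 50, size=(20, 20))
        m = m + m.T
        pm = rair(ContactCounts(m), AbundanceTable(np.full(20, 100), "surface"))
        np.testing.assert_allclose(np.nansum(pm.air, axis=1), 1.0, atol=1e-12)

    def test_planted_enrichment_recovered(self):
        """Simulated contact draws with doubled (C,C) probability push RAIR[C,C] > 1."""
        comp = np.full(20, 0.05)
        c_idx = AA_INDEX["C"]
        w = np.outer(comp, comp)
        w[c_idx, c_idx] *= 2.0
        flat = w.ravel() / w.sum()
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            draws = rng.choice(400, size=5000, p=flat)
            pairs = [pos_pair(AA_ALPHABET[k // 20], AA_ALPHABET[k % 20]) for k in draws]
            pm = rair(contact_counts([pairs], "double"),
                      AbundanceTable((comp * 100000).astype(int), "surface"))
            hits += pm.rair[c_idx, c_idx] > 1
        assert hits >= 9

    def test_enrichment_ordering_recovered(self):
        """Recovered RAIR[C,C] orders consistently with the planted factor."""
        comp = np.full(20, 0.05)
        c_idx = AA_INDEX["C"]
        rec = []
        for factor in (0.5, 1.0, 2.0):
            w = np.outer(comp, comp)
            w[c_idx, c_idx] *= factor
            rng = np.random.default_rng(42)
            draws = rng.choice(400, size=5000, p=w.ravel() / w.sum())
            pairs = [pos_pair(AA_ALPHABET[k // 20], AA_ALPHABET[k % 20]) for k in draws]
            pm = rair(contact_counts([pairs], "double"),
                      AbundanceTable((comp * 100000).astype(int), "surface"))
            rec.append(pm.rair[c_idx, c_idx])
        assert rec[0] < rec[1] < rec[2]

    def test_reference_matrix_values(self):
        pm = reference_propensity_matrix()
        assert pm.rair[AA_INDEX["A"], AA_INDEX["L"]] == pytest.approx(1.58)
        assert pm.rair[AA_INDEX["A"], AA_INDEX["K"]] == pytest.approx(0.58)

    def test_zero_abundance_with_contacts_raises(self):
        m = np.zeros((20, 20), dtype=int)
        m[0, 1] = m[1, 0] = 1
        counts = np.full(20, 10)
        counts[1] = 0
        with pytest.raises(ValueError):
            rair(ContactCounts(m), AbundanceTable(counts, "surface"))


class TestHighPropensity:
    def test_reference_matrix_yields_221_ordered_pairs(self):
        high = classify_high_propensity(reference_propensity_matrix())
        assert len(high) == 221

    def test_all_ones_matrix_yields_400(self):
        from ppisites.propensity import PropensityMatrix
        pm = PropensityMatrix(air=np.full((20, 20), 0.05), rair=np.ones((20, 20)))
        assert len(classify_high_propensity(pm)) == 400

    def test_columnwise_majority_gives_ten_partner_residues(self):
        got = high_propensity_partners(reference_propensity_matrix())
        assert sorted(got) == sorted("LIVRHCMYWF")


class TestTendency:
    def test_printed_ratio_convention(self):
        t = tendency(reference_abundance("whole"), reference_abundance("surface"))
        assert t.of("C", printed=True) == pytest.approx(2.50)
        assert t.of("K", printed=True) == pytest.approx(0.66)
        # full precision differs from the printed convention for cysteine
        assert t.of("C") == pytest.approx(2.44, abs=0.01)

    def test_equal_abundances_give_unit_ratio(self):
        n = np.arange(1, 21) * 10
        t = tendency(AbundanceTable(n, "whole"), AbundanceTable(n, "surface"))
        np.testing.assert_allclose(t.ratio, 1.0)

    def test_universe_mismatch_raises(self):
        n = np.full(20, 5)
        with pytest.raises(ValueError):
            tendency(AbundanceTable(n, "surface"), AbundanceTable(n, "surface"))


class TestFilterPositives:
    def test_reference_high_set_keeps_al_drops_ak(self):
        high = classify_high_propensity(reference_propensity_matrix())
        pairs = [pos_pair("A", "L"), pos_pair("A", "K")]
        kept = filter_positives(pairs, high)
        assert [(p.aa_r, p.aa_l) for p in kept] == [("A", "L")]

    def test_empty_high_set_drops_all_positives_keeps_negatives(self):
        neg = PairLabel(("A", 0), ("B", 1), "A", "K", 9.0, 0)
        kept = filter_positives([pos_pair("A", "L"), neg], set())
        assert kept == [neg]

    def test_full_high_set_is_identity(self):
        full = {(a, b) for a in AA_ALPHABET for b in AA_ALPHABET}
        pairs = [pos_pair("A", "L"), pos_pair("W", "W")]
        assert filter_positives(pairs, full) == pairs

    def test_orientation_insensitive(self):
        kept = filter_positives([pos_pair("K", "A")], {("A", "K")})
        assert len(kept) == 1
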