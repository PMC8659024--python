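"""Mass calculus: composition arithmetic, fixed-charge bookkeeping, fragments."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pmass

from tagmrm.chem import (
    PROTON_MASS,
    TPP,
    OXIDATION,
    ElementalComposition,
    Modification,
    Peptide,
    fragment_mz,
    load_modifications,
    neutral_mass,
    precursor_mz,
    reporter_mz,
    round_half_away,
)

WATER = 18.0105646837
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def oracle_mass(sequence, mod_deltas=0.0):
    """Independent route: incremental residue-mass summation from pyteomics."""
    return sum(pmass.std_aa_mass[ch] for ch in sequence) + WATER + mod_deltas


class TestElementalComposition:
    def test_arithmetic_is_elementwise_and_associative(self):
        a = ElementalComposition(C=2, H=3)
        b = ElementalComposition(H=1, O=1)
        c = ElementalComposition(N=5)
        assert ((a + b) + c) == (a + (b + c))
        assert (a - b).counts == {"C": 2, "H": 2, "O": -1}

    def test_zero_counts_are_dropped(self):
        assert not (ElementalComposition(C=1) - ElementalComposition(C=1))

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="Xx"):
            ElementalComposition(Xx=1)


class TestNeutralMass:
    @pytest.mark.parametrize(
        "seq,expected",
        [("G", 75.03203), ("MIAAEAEK", 861.42658)],
    )
    def test_reference_values(self, seq, expected):
        assert neutral_mass(Peptide(seq)) == pytest.approx(expected, abs=1e-4)

    def test_tpp_adds_cation_atom_mass(self):
        tagged = Peptide("MIAAEAEK", ((8, TPP),))
        delta = neutral_mass(tagged) - neutral_mass(Peptide("MIAAEAEK"))
        assert delta == pytest.approx(ElementalComposition(C=23, H=15).mass(), abs=1e-9)
        assert neutral_mass(tagged) == pytest.approx(1152.5434, abs=1e-3)

    def test_element_counting_matches_residue_summation(self):
        rng = random.Random(20260922)
        for _ in range(1000):
            seq = "".join(rng.choices(RESIDUES, k=rng.randint(2, 30)))
            assert neutral_mass(Peptide(seq)) == pytest.approx(oracle_mass(seq), abs=1e-6)

    def test_positive_delta_mod_strictly_increases_mass(self):
        base = Peptide("MIAAEAEK")
        for pos, mod in [(1, OXIDATION), (8, TPP)]:
            assert neutral_mass(Peptide("MIAAEAEK", ((pos, mod),))) > neutral_mass(base)

    def test_unknown_residue_names_offender(self):
        with pytest.raises(ValueError, match="'B'"):
            Peptide("AAKBB")

    def test_zero_length_is_an_error(self):
        with pytest.raises(ValueError):
            Peptide("")


class TestPeptideValidation:
    def test_mod_site_rule_enforced(self):
        with pytest.raises(ValueError, match="Oxidation"):
            Peptide("MIAAEAEK", ((2, OXIDATION),))  # I is not a Met

    def test_one_mod_per_site(self):
        with pytest.raises(ValueError, match="position 1"):
            Peptide("MIAAEAEK", ((1, OXIDATION), (1, OXIDATION)))

    def test_mod_position_bounds(self):
        with pytest.raises(ValueError, match="out of range"):
            Peptide("MIAAEAEK", ((9, TPP),))

    def test_fixed_charge_totals(self):
        assert Peptide("MIAAEAEK", ((8, TPP),)).fixed_charge == 1
        assert Peptide("MIAAEAEK").fixed_charge == 0


class TestPrecursorMz:
    def test_native_singly_protonated(self):
        assert precursor_mz(Peptide("MIAAEAEK"), 1) == pytest.approx(862.434, abs=1e-3)

    def test_met_oxidized_matches_printed_value(self):
        p = Peptide("MIAAEAEK", ((1, OXIDATION),))
        assert round_half_away(precursor_mz(p, 1), 2) == 878.43

    def test_tagged_doubly_charged_matches_printed_value(self):
        p = Peptide("MIAAEAEK", ((8, TPP),))
        assert round_half_away(precursor_mz(p, 2), 2) == 576.78

    def test_charge_below_fixed_charge_rejected(self):
        doubly = Modification("ditag", ElementalComposition(C=2), fixed_charge_delta=2,
                              site_residues="K")
        p = Peptide("MIAAEAEK", ((8, doubly),))
        with pytest.raises(ValueError, match="fewer charges than fixed"):
            precursor_mz(p, 1)
        with pytest.raises(ValueError):
            precursor_mz(Peptide("MIAAEAEK"), 0)

    def test_all_fixed_charge_adds_no_protons(self):
        p = Peptide("MIAAEAEK", ((8, TPP),))
        assert precursor_mz(p, 1) == pytest.approx(neutral_mass(p) / 1, abs=0)


class TestFragmentMz:
    def test_native_y6(self):
        assert fragment_mz(Peptide("MIAAEAEK"), "y", 6, 1) == pytest.approx(618.309, abs=1e-3)

    def test_oxidized_b2_matches_printed_value(self):
        p = Peptide("MIAAEAEK", ((1, OXIDATION),))
        assert round_half_away(fragment_mz(p, "b", 2, 1), 2) == 261.13

    def test_tagged_y3_carries_fixed_charge_no_proton(self):
        p = Peptide("MIAAEAEK", ((8, TPP),))
        mz = fragment_mz(p, "y", 3, 1)
        assert round_half_away(mz, 2) == 637.30
        # identical to the unprotonated fragment composition mass
        native_y3 = fragment_mz(Peptide("MIAAEAEK"), "y", 3, 1)
        assert mz == pytest.approx(native_y3 - PROTON_MASS + TPP.delta.mass(), abs=1e-9)

    def test_mod_is_carried_only_by_containing_fragment(self):
        p = Peptide("MIAAEAEK", ((1, OXIDATION),))
        assert fragment_mz(p, "y", 3, 1) == pytest.approx(
            fragment_mz(Peptide("MIAAEAEK"), "y", 3, 1), abs=1e-9
        )

    def test_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            fragment_mz(Peptide("MIAAEAEK"), "y", 8, 1)

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet=RESIDUES, min_size=2, max_size=30), st.data())
    def test_by_complementarity(self, seq, data):
        """b_i + y_(N−i) at z=1 equals the protonated precursor plus one proton."""
        i = data.draw(st.integers(1, len(seq) - 1))
        p = Peptide(seq)
        total = fragment_mz(p, "b", i, 1) + fragment_mz(p, "y", len(seq) - i, 1)
        assert total == pytest.approx(precursor_mz(p, 1) + PROTON_MASS, abs=1e-6)


class TestReporter:
    def test_tpp_reporter_is_protonated_triphenylpyridine(self):
        assert reporter_mz(TPP) == pytest.approx(308.143, abs=2e-3)
        assert round_half_away(reporter_mz(TPP), 2) == 308.14

    def test_tag_without_reporter_errors(self):
        bare = Modification("bare", ElementalComposition(C=1), fixed_charge_delta=1)
        with pytest.raises(ValueError, match="reporter"):
            reporter_mz(bare)

    def test_single_charge_identity(self):
        cation = Modification(
            "toy", ElementalComposition(), fixed_charge_delta=1,
            reporter=ElementalComposition(C=6, H=6, N=1),
        )
        assert reporter_mz(cation) == pytest.approx(cation.reporter.mass(), abs=0)


def test_round_half_away():
    assert round_half_away(576.775, 2) == 576.78
    assert round_half_away(-59.5, 0) == -60
    assert round_half_away(11.499, 0) == 11


def test_load_modifications_yaml(tmp_path):
    cfg = tmp_path / "mods.yaml"
    cfg.write_text(
        "MyTag:\n"
        "  delta: {C: 23, H: 15}\n"
        "  fixed_charge: 1\n"
        "  sites: K\n"
        "  reporter: {C: 23, H: 18, N: 1}\n"
    )
    mods = load_modifications(cfg)
    tag = mods["MyTag"]
    assert tag.fixed_charge_delta == 1
    assert tag.delta == TPP.delta
    assert reporter_mz(tag) == pytest.approx(reporter_mz(TPP), abs=0)
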