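"""Chemistry: masses, precursor/isotope m/z, and cleavable fragment ions,
checked against hand-coded mass tables and a brute-force enumerator."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlpasef.chem_core import (
    DSBU,
    CO_MASS,
    PROTON_MASS,
    WATER_MASS,
    ChemistryError,
    CrossLink,
    ElementComposition,
    FragmentIon,
    LinkerSpec,
    Peptide,
    crosslink_mass,
    fragment_ions,
    isotope_mz,
    linker_from_dict,
    monoisotopic_mass,
    peptide_mass,
    precursor_mz,
)

from conftest import (
    PROTON,
    RESIDUE_MASS,
    WATER,
    oracle_formula_mass,
    oracle_peptide_mass,
)

FIG2_XL = CrossLink(Peptide("KQTALVELLK"), Peptide("KFWGK"), 1, 1)

peptide_seq = st.text(
    alphabet=sorted(set(RESIDUE_MASS) - {"C"}), min_size=2, max_size=15
)


class TestCompositions:
    @pytest.mark.parametrize(
        "formula,counts",
        [
            ("C4H7NO", {"C": 4, "H": 7, "N": 1, "O": 1}),  # Bu
            ("C5H5NO2", {"C": 5, "H": 5, "N": 1, "O": 2}),  # BuUr
            ("H2O", {"H": 2, "O": 1}),
        ],
    )
    def test_mass_matches_hand_sum(self, formula, counts):
        comp = ElementComposition.from_formula(formula)
        assert monoisotopic_mass(comp) == pytest.approx(
            oracle_formula_mass(counts), abs=1e-5
        )

    def test_signature_fragment_values(self):
        assert DSBU.fragment_a.mass == pytest.approx(85.05276, abs=1e-5)
        assert DSBU.fragment_b.mass == pytest.approx(111.03203, abs=1e-5)

    def test_empty_composition_is_massless(self):
        assert monoisotopic_mass(ElementComposition({})) == 0.0

    def test_additivity(self):
        a = ElementComposition.from_formula("C4H7NO")
        b = ElementComposition.from_formula("C5H5NO2")
        assert (a + b).mass == pytest.approx(a.mass + b.mass, abs=1e-9)

    def test_unknown_element_rejected_by_name(self):
        with pytest.raises(ChemistryError, match="Xx"):
            ElementComposition({"Xx": 1})

    def test_negative_count_rejected(self):
        with pytest.raises(ChemistryError):
            ElementComposition({"C": -1})


class TestLinker:
    def test_dsbu_cleavable_conservation(self):
        assert DSBU.intact_mass == pytest.approx(
            DSBU.fragment_a.mass + DSBU.fragment_b.mass, abs=1e-4
        )

    def test_dsbu_reactive_set(self):
        assert DSBU.reactive_residues == frozenset("KSTY")
        assert DSBU.reacts_with_nterm

    def test_inconsistent_intact_mass_rejected(self):
        with pytest.raises(ChemistryError):
            LinkerSpec(
                name="bad",
                fragment_a_name="Bu",
                fragment_a=ElementComposition.from_formula("C4H7NO"),
                fragment_b_name="BuUr",
                fragment_b=ElementComposition.from_formula("C5H5NO2"),
                intact_mass=200.0,
            )

    def test_linker_from_config_dict(self):
        spec = linker_from_dict(
            {
                "name": "DSBU",
                "fragment_a": {"name": "Bu", "formula": "C4H7NO"},
                "fragment_b": {"name": "BuUr", "formula": "C5H5NO2"},
                "reactive_residues": "KSTY",
            }
        )
        assert spec.intact_mass == pytest.approx(DSBU.intact_mass, abs=1e-9)


class TestPeptideMass:
    @pytest.mark.parametrize("seq", ["KFWGK", "KQTALVELLK", "G", "ACDEK"])
    def test_matches_residue_table_oracle(self, seq):
        assert peptide_mass(Peptide(seq)) == pytest.approx(
            oracle_peptide_mass(seq), abs=1e-4
        )

    def test_reference_values(self):
        assert peptide_mass(Peptide("KFWGK")) == pytest.approx(664.36967, abs=1e-4)
        assert peptide_mass(Peptide("KQTALVELLK")) == pytest.approx(
            1141.70704, abs=1e-4
        )

    def test_variable_oxidation(self):
        plain = peptide_mass(Peptide("AMK"))
        oxidised = peptide_mass(Peptide("AMK", variable_mods=((2, 15.99491),)))
        assert oxidised - plain == pytest.approx(15.99491, abs=1e-9)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ChemistryError):
            Peptide("AXZ")

    def test_bad_mod_position_rejected(self):
        with pytest.raises(ChemistryError):
            Peptide("AK", variable_mods=((5, 15.99491),))


class TestCrossLink:
    def test_fig2_crosslink_mass(self):
        assert crosslink_mass(FIG2_XL) == pytest.approx(2002.16150, abs=1e-3)

    def test_conservation_identity(self):
        expected = (
            peptide_mass(FIG2_XL.alpha)
            + peptide_mass(FIG2_XL.beta)
            + DSBU.fragment_a.mass
            + DSBU.fragment_b.mass
        )
        assert crosslink_mass(FIG2_XL) == pytest.approx(expected, abs=1e-9)

    def test_swap_symmetry(self):
        assert crosslink_mass(FIG2_XL.swapped()) == pytest.approx(
            crosslink_mass(FIG2_XL), abs=1e-12
        )

    def test_nonreactive_position_rejected(self):
        with pytest.raises(ChemistryError):
            CrossLink(Peptide("AGLK"), Peptide("KFWGK"), 2, 1)

    def test_nterm_flag_allows_position_one(self):
        xl = CrossLink(Peptide("AGLK"), Peptide("KFWGK"), 1, 1, nterm_alpha=True)
        assert xl.link_pos_alpha == 1


class TestMz:
    def test_fig2_triply_protonated(self):
        assert precursor_mz(crosslink_mass(FIG2_XL), 3) == pytest.approx(
            668.39444, abs=1e-3
        )

    @pytest.mark.parametrize(
        "mass,z,expected",
        [(1000.0, 1, 1001.00728), (1000.0, 2, 501.00728)],
    )
    def test_protonation_arithmetic(self, mass, z, expected):
        assert precursor_mz(mass, z) == pytest.approx(expected, abs=1e-5)

    def test_charge_below_one_rejected(self):
        with pytest.raises(ChemistryError):
            precursor_mz(1000.0, 0)

    def test_isotope_spacing(self):
        assert isotope_mz(668.39444, 3, 1) == pytest.approx(668.72890, abs=1e-5)
        assert isotope_mz(500.0, 2, 2) == pytest.approx(501.00335, abs=1e-5)
        assert isotope_mz(432.1, 5, 0) == 432.1

    @given(st.floats(200, 2000), st.integers(1, 8))
    def test_precursor_mz_decreasing_in_charge(self, mass, z):
        assert precursor_mz(mass, z) > precursor_mz(mass, z + 1)

    @given(st.integers(1, 8), st.integers(0, 5))
    def test_isotope_mz_increasing_in_k(self, z, k):
        assert isotope_mz(500.0, z, k + 1) > isotope_mz(500.0, z, k)


# ---------------------------------------------------------------------------
# Brute-force fragment oracle: written from the sequence slices directly,
# independent of the implementation's prefix-sum route.
# ---------------------------------------------------------------------------


def oracle_fragments(xl: CrossLink, max_z: int) -> dict:
    out = {}
    bu = oracle_formula_mass({"C": 4, "H": 7, "N": 1, "O": 1})
    buur = oracle_formula_mass({"C": 5, "H": 5, "N": 1, "O": 2})
    sides = [
        ("alpha", xl.alpha.sequence, xl.link_pos_alpha, oracle_peptide_mass(xl.beta.sequence)),
        ("beta", xl.beta.sequence, xl.link_pos_beta, oracle_peptide_mass(xl.alpha.sequence)),
    ]
    co = oracle_formula_mass({"C": 1, "O": 1})
    for label, seq, link, partner in sides:
        n = len(seq)
        for i in range(1, n):
            pieces = {
                "a": (seq[:i], sum(RESIDUE_MASS[r] for r in seq[:i]) - co),
                "b": (seq[:i], sum(RESIDUE_MASS[r] for r in seq[:i])),
                "y": (seq[n - i:], sum(RESIDUE_MASS[r] for r in seq[n - i:]) + WATER),
            }
            for series, (piece, neutral) in pieces.items():
                if series in ("a", "b"):
                    spans = link <= i
                else:
                    spans = link > n - i
                if spans:
                    states = [
                        ("intact", neutral + bu + buur + partner),
                        ("retains_Bu", neutral + bu),
                        ("retains_BuUr", neutral + buur),
                    ]
                else:
                    states = [("none", neutral)]
                for state, m in states:
                    for z in range(1, max_z + 1):
                        out[(label, series, i, state, z)] = (m + z * PROTON) / z
    return out


def impl_fragment_map(xl: CrossLink, max_z: int) -> dict:
    return {
        (f.source_peptide, f.series, f.ordinal, f.linker_state, f.charge): f.mz
        for f in fragment_ions(xl, max_z)
    }


def assert_fragment_maps_match(impl: dict, oracle: dict, tol: float = 2e-3):
    assert set(impl) == set(oracle)
    for key, mz in impl.items():
        assert mz == pytest.approx(oracle[key], abs=tol), key


class TestFragmentIons:
    def test_nonspanning_y4_of_kfwgk(self):
        frags = fragment_ions(FIG2_XL, 1)
        y4 = [
            f for f in frags
            if f.source_peptide == "beta" and f.series == "y" and f.ordinal == 4
        ]
        assert len(y4) == 1 and y4[0].linker_state == "none"
        expected = sum(RESIDUE_MASS[r] for r in "FWGK") + WATER + PROTON
        assert y4[0].mz == pytest.approx(expected, abs=1e-4)

    def test_matches_bruteforce_on_fig2_pair(self):
        assert_fragment_maps_match(
            impl_fragment_map(FIG2_XL, 2), oracle_fragments(FIG2_XL, 2)
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(peptide_seq, peptide_seq, st.data())
    def test_by_complementarity(self, seq_a, seq_b, data):
        """Neutral b_i + y_(n-i) equals the peptide neutral mass at every split."""
        from xlpasef.chem_core import _neutral_series_masses

        pep = Peptide(seq_a + "K" + seq_b)
        masses = _neutral_series_masses(pep.residue_masses())
        n = len(pep)
        for i in range(1, n):
            assert masses["b"][i - 1] + masses["y"][n - i - 1] == pytest.approx(
                peptide_mass(pep), abs=1e-9
            )

    def test_count_matches_exhaustive_enumeration(self):
        # 5-mer / 10-mer pair linked at 1,1 with max charge 2
        xl = CrossLink(Peptide("KAGLR"), Peptide("KQTALVELLK"), 1, 1)
        assert len(fragment_ions(xl, 2)) == len(oracle_fragments(xl, 2))

    def test_swap_invariance_up_to_relabeling(self):
        original = impl_fragment_map(FIG2_XL, 2)
        swapped = impl_fragment_map(FIG2_XL.swapped(), 2)
        relabel = {"alpha": "beta", "beta": "alpha"}
        assert {(relabel[s], *rest): mz for (s, *rest), mz in swapped.items()} == original

    def test_deterministic_ordering(self):
        frags = fragment_ions(FIG2_XL, 2)
        assert [f.sort_key() for f in frags] == sorted(f.sort_key() for f in frags)
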