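"""MIDA label-incorporation model and turnover kinetics checks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fluxprot.isotopes import ElementalFormula, isotope_table, natural_distribution, peptide_formula
from fluxprot.kinetics import (
    DEFAULT_STAGES,
    PeptideSpec,
    StageDesign,
    dna_fraction_new,
    em0_asymptote,
    em0_polynomial_fit,
    fraction_new,
    labeled_distribution,
    n_labeling_sites,
    protein_rollup,
    rate_constant,
)
from oracles import enumerate_envelope


class TestLabelingSites:
    def test_empty_sequence_is_zero(self):
        assert n_labeling_sites("") == 0.0

    @pytest.mark.parametrize(
        "seq, table, expected",
        [("AA", {"A": 4.0}, 8.0), ("AG", {"A": 4.0, "G": 2.1}, 6.1)],
    )
    def test_additivity(self, seq, table, expected):
        assert n_labeling_sites(seq, table) == pytest.approx(expected)

    def test_order_independent(self):
        assert n_labeling_sites("AGPK") == pytest.approx(n_labeling_sites("KPGA"))

    def test_missing_residue_rejected(self):
        with pytest.raises(ValueError, match="'G'"):
            n_labeling_sites("AG", {"A": 4.0})


class TestLabeledDistribution:
    def test_no_label_equals_natural(self):
        f = peptide_formula("GAK")
        np.testing.assert_array_equal(
            labeled_distribution(f, 5.0, 0.0), natural_distribution(f)
        )

    def test_two_hydrogens_one_site_matches_enumeration(self):
        env = labeled_distribution(ElementalFormula(H=2), 1, 0.05, k=3)
        slow = enumerate_envelope({"H": 2}, k=3, labeled_sites=1, p=0.05)
        assert env == pytest.approx(slow, abs=1e-12)

    @pytest.mark.parametrize("formula", [{"C": 1, "H": 3}, {"H": 2, "O": 1}, {"C": 2, "H": 2, "S": 1}])
    def test_integer_sites_match_enumeration(self, formula):
        env = labeled_distribution(ElementalFormula(formula), 2, 0.08, k=4)
        slow = enumerate_envelope(formula, k=4, labeled_sites=2, p=0.08)
        assert env == pytest.approx(slow, abs=1e-12)

    def test_m0_strictly_decreasing_in_p(self):
        f = peptide_formula("GAK")
        m0 = [labeled_distribution(f, 6.0, p)[0] for p in np.linspace(0.0, 0.2, 9)]
        assert all(b < a for a, b in zip(m0, m0[1:]))

    def test_at_natural_abundance_recovers_natural(self):
        a_h = dict(isotope_table()["H"])[1]
        f = peptide_formula("PEPTIDEK")
        env = labeled_distribution(f, 10.0, a_h)
        assert env == pytest.approx(natural_distribution(f), abs=1e-12)

    def test_fractional_sites_interpolate(self):
        f = peptide_formula("GAK")
        lo = labeled_distribution(f, 3, 0.05, renormalize=False)
        hi = labeled_distribution(f, 4, 0.05, renormalize=False)
        mid_raw = 0.6 * lo + 0.4 * hi
        mid = labeled_distribution(f, 3.4, 0.05)
        assert mid == pytest.approx(mid_raw / mid_raw.sum(), abs=1e-14)

    def test_rejects_bad_inputs(self):
        f = ElementalFormula(H=2)
        with pytest.raises(ValueError):
            labeled_distribution(f, 3, 0.05)  # n exceeds H count
        with pytest.raises(ValueError):
            labeled_distribution(f, 1, 0.6)  # p out of range


class TestEm0Asymptote:
    def test_zero_iff_no_label_or_no_sites(self):
        f = peptide_formula("GAK")
        assert em0_asymptote(f, 5.0, 0.0) == 0.0
        assert em0_asymptote(f, 0.0, 0.05) == 0.0
        assert em0_asymptote(f, 5.0, 0.05) < 0.0

    def test_matches_enumeration(self):
        formula = {"C": 1, "H": 3, "O": 1}
        lab = enumerate_envelope(formula, k=4, labeled_sites=2, p=0.06)
        nat = enumerate_envelope(formula, k=4)
        fast = em0_asymptote(ElementalFormula(formula), 2, 0.06, k=4)
        assert fast == pytest.approx(lab[0] - nat[0], abs=1e-12)

    def test_polynomial_fit_tracks_exact_values(self):
        f = peptide_formula("GLSDGEWQQVLNVWGK")
        n = 30.0
        coef = em0_polynomial_fit(f, n)
        for p in (0.02, 0.05, 0.08):
            approx = float(np.polyval(coef[::-1], p))
            exact = em0_asymptote(f, n, p)
            assert approx == pytest.approx(exact, rel=2e-2)


class TestFractionNew:
    def test_mixture_endpoints_and_midpoint(self):
        assert fraction_new(0.6, 0.6, 0.4) == (0.0, False)
        assert fraction_new(0.4, 0.6, 0.4) == (1.0, False)
        assert fraction_new(0.5, 0.6, 0.4) == (0.5, False)

    def test_clamps_and_flags(self):
        f, clamped = fraction_new(0.65, 0.6, 0.4)
        assert f == 0.0 and clamped
        f, clamped = fraction_new(0.35, 0.6, 0.4, f_cap=0.99)
        assert f == 0.99 and clamped

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fraction_new(0.5, 0.6, 0.6)

    @given(
        f_true=st.floats(0.0, 1.0),
        p=st.floats(0.01, 0.12),
    )
    def test_noiseless_round_trip(self, f_true, p):
        """Mixture envelopes recover the planted fraction to 1e-10."""
        formula = peptide_formula("GAGSSEPVTGLDAK")
        n = n_labeling_sites("GAGSSEPVTGLDAK")
        nat = natural_distribution(formula)
        lab = labeled_distribution(formula, n, p)
        measured = f_true * lab + (1 - f_true) * nat
        f_hat, clamped = fraction_new(measured[0], nat[0], lab[0])
        assert not clamped
        assert f_hat == pytest.approx(f_true, abs=1e-10)


class TestRateConstant:
    def test_identities(self):
        assert rate_constant(0.0, 4.0) == (0.0, 0.0, False)
        k, fsr, capped = rate_constant(0.5, 7.0)
        assert k == pytest.approx(math.log(2) / 7, abs=1e-12)
        assert fsr == pytest.approx(100 * k)
        assert not capped

    def test_small_f_limit(self):
        for f in (1e-4, 1e-6, 1e-8):
            k, _, _ = rate_constant(f, 1.0)
            assert k / f == pytest.approx(1.0, rel=1e-3)

    def test_monotone_in_f_and_halves_with_doubled_t(self):
        ks = [rate_constant(f, 3.0)[0] for f in np.linspace(0.0, 0.9, 10)]
        assert all(b > a for a, b in zip(ks, ks[1:]))
        _, fsr_t, _ = rate_constant(0.4, 3.0)
        _, fsr_2t, _ = rate_constant(0.4, 6.0)
        assert fsr_2t == pytest.approx(fsr_t / 2)

    def test_cap_flags(self):
        k, fsr, capped = rate_constant(0.999, 3.0)
        assert capped
        assert k == pytest.approx(-math.log1p(-0.99) / 3.0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            rate_constant(0.5, 0.0)
        with pytest.raises(ValueError):
            rate_constant(-0.1, 1.0)


class TestStageDesign:
    def test_default_windows(self):
        assert DEFAULT_STAGES["Proliferation"].t == 4.0
        assert DEFAULT_STAGES["Differentiation"].t == 3.0
        assert DEFAULT_STAGES["Maturation"].t == 4.0
        assert DEFAULT_STAGES["Control"].t == 3.0

    def test_rejects_empty_window(self):
        with pytest.raises(ValueError):
            StageDesign("x", 2.0, 2.0)


class TestPeptideSpec:
    def test_site_count_bounded_by_hydrogens(self):
        with pytest.raises(ValueError):
            PeptideSpec("GG", peptide_formula("GG"), n_sites=9.0)

    def test_from_sequence(self):
        spec = PeptideSpec.from_sequence("AG", site_table={"A": 4.0, "G": 2.1})
        assert spec.n_sites == pytest.approx(6.1)
        assert spec.formula == peptide_formula("AG")


class TestProteinRollup:
    def test_filters_and_ledger(self, toy_peptide_kinetics):
        res = protein_rollup(toy_peptide_kinetics)
        assert set(res.proteins["protein_accession"]) == {"PASS"}
        row = res.proteins.iloc[0]
        # animal-level means 3.0 and 4.0 -> protein mean 3.5
        assert row["mean_fsr_pct_per_day"] == pytest.approx(3.5)
        assert row["n_animals"] == 2

        rules = dict(zip(res.rejects["protein_accession"], res.rejects["rule"]))
        assert "peptide" in rules["ONEPEP"]
        assert "animals" in rules["ONEANIMAL"]

        led = res.ledger
        assert led["proteins_in"] == (
            led["compared"] + led["excluded_peptide_filter"] + led["excluded_animal_filter"]
        )
        assert led["compared"] == 1

    def test_animal_mean_is_unweighted_peptide_mean(self, toy_peptide_kinetics):
        res = protein_rollup(toy_peptide_kinetics)
        samples = res.samples
        a1 = samples[
            (samples["protein_accession"] == "PASS") & (samples["animal_id"] == "a1")
        ]
        assert a1["fsr_pct_per_day"].iloc[0] == pytest.approx(3.0)  # mean of 2 and 4


class TestDnaFractionNew:
    def test_endpoints_and_ratio(self):
        assert dna_fraction_new(0.0, 0.02) == 0.0
        assert dna_fraction_new(0.02, 0.02) == 100.0
        assert dna_fraction_new(0.44 * 0.02, 0.02) == pytest.approx(44.0)

    def test_zero_asymptote_rejected(self):
        with pytest.raises(ValueError):
            dna_fraction_new(0.01, 0.0)
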