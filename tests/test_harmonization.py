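"""Allele harmonization: pairwise rules, set aggregation, orientation."""

import numpy as np
import pytest

from twosample_mr import (
    ConfigurationError,
    EmptySetError,
    HarmonizationError,
    InstrumentSet,
    SimulationConfig,
    harmonize_pair,
    harmonize_set,
    ivw,
    orient_exposure_positive,
    scramble_alleles,
    simulate_two_sample_study,
)

from conftest import make_record


def pair(x_alleles, y_alleles, eaf_x=0.30, eaf_y=0.31, bx=0.05, by=0.02):
    x = make_record(
        rsid="rs1", effect_allele=x_alleles[0], other_allele=x_alleles[1],
        eaf=eaf_x, beta=bx,
    )
    y = make_record(
        rsid="rs1", effect_allele=y_alleles[0], other_allele=y_alleles[1],
        eaf=eaf_y, beta=by, se=0.004,
    )
    return x, y


class TestHarmonizePair:
    def test_identical_alleles_unchanged(self):
        hv = harmonize_pair(*pair("AG", "AG"))
        assert hv.action == "unchanged" and hv.by == 0.02

    def test_allele_swap_negates_beta_and_inverts_eaf(self):
        hv = harmonize_pair(*pair("AG", "GA", eaf_y=0.69))
        assert hv.action == "allele_swap"
        assert hv.by == -0.02
        assert hv.eaf_y == pytest.approx(0.31)

    @pytest.mark.parametrize(
        "y_alleles,expected_action,expected_by",
        [("TC", "strand_flip", 0.02), ("CT", "strand_flip_and_swap", -0.02)],
    )
    def test_strand_complement_resolution(self, y_alleles, expected_action, expected_by):
        hv = harmonize_pair(*pair("AG", y_alleles, eaf_y=0.31 if expected_by > 0 else 0.69))
        assert hv.action == expected_action and hv.by == expected_by

    def test_palindromic_oriented_by_eaf_concordance(self):
        """A/T with eaf .10 vs .88: frequencies straddle 0.5, so the outcome
        effect refers to the opposite allele and must be negated."""
        hv = harmonize_pair(*pair("AT", "AT", eaf_x=0.10, eaf_y=0.88))
        assert hv.action == "palindromic_aligned"
        assert hv.by == -0.02
        assert hv.eaf_y == pytest.approx(0.12)

    def test_palindromic_concordant_kept_as_is(self):
        hv = harmonize_pair(*pair("CG", "GC", eaf_x=0.10, eaf_y=0.12))
        assert hv.action == "palindromic_aligned" and hv.by == 0.02

    @pytest.mark.parametrize("eaf_x,eaf_y", [(0.50, 0.10), (0.10, 0.45), (0.42, 0.58)])
    def test_palindromic_in_ambiguity_band_dropped(self, eaf_x, eaf_y):
        hv = harmonize_pair(*pair("AT", "TA", eaf_x=eaf_x, eaf_y=eaf_y))
        assert hv.action == "dropped:ambiguous_palindrome"

    def test_palindromic_missing_eaf_dropped(self):
        hv = harmonize_pair(*pair("AT", "AT", eaf_x=0.10, eaf_y=None))
        assert hv.action == "dropped:ambiguous_palindrome"

    def test_eaf_discordance_drops_pair(self):
        hv = harmonize_pair(*pair("AG", "AG", eaf_x=0.25, eaf_y=0.60))
        assert hv.action == "dropped:eaf_discordant"

    def test_irreconcilable_alleles_dropped(self):
        hv = harmonize_pair(*pair("AG", "AC"))
        assert hv.action == "dropped:allele_mismatch"

    def test_rsid_mismatch_is_usage_error(self):
        x, y = pair("AG", "AG")
        y = make_record(rsid="rs2", eaf=0.3)
        with pytest.raises(HarmonizationError):
            harmonize_pair(x, y)

    def test_missing_eaf_nonpalindromic_aligns_on_alleles(self):
        hv = harmonize_pair(*pair("AG", "GA", eaf_x=None, eaf_y=None))
        assert hv.action == "allele_swap" and hv.by == -0.02


class TestHarmonizeSet:
    def _records(self, k=4):
        exp = [make_record(rsid=f"rs{i}", beta=0.05 + 0.01 * i) for i in range(k)]
        out = [
            make_record(rsid=f"rs{i}", beta=0.01 + 0.002 * i, se=0.004)
            for i in range(k)
        ]
        return exp, out

    def test_identical_files_fully_retained(self):
        exp, out = self._records()
        inst = InstrumentSet(label="x", members=[r.rsid for r in exp])
        hset = harmonize_set(exp, out, inst)
        assert hset.k == 4
        assert all(a == "unchanged" for _, a in hset.audit)

    def test_swapped_outcome_row_gives_identical_ivw(self):
        exp, out = self._records()
        inst = InstrumentSet(label="x", members=[r.rsid for r in exp])
        baseline = ivw(harmonize_set(exp, out, inst))
        swapped = list(out)
        r = swapped[2]
        swapped[2] = make_record(
            rsid=r.rsid, effect_allele=r.other_allele, other_allele=r.effect_allele,
            eaf=1 - r.eaf, beta=-r.beta, se=r.se,
        )
        rerun = ivw(harmonize_set(exp, swapped, inst))
        assert rerun.beta == baseline.beta and rerun.se == baseline.se

    def test_member_missing_from_outcome_dropped_with_audit(self):
        exp, out = self._records()
        inst = InstrumentSet(label="x", members=[r.rsid for r in exp])
        hset = harmonize_set(exp, out[:-1], inst)
        assert hset.k == 3
        assert ("rs3", "dropped:not_in_outcome") in hset.audit

    def test_member_missing_from_exposure_is_config_error(self):
        exp, out = self._records()
        inst = InstrumentSet(label="x", members=["rs0", "rs999"])
        with pytest.raises(ConfigurationError, match="rs999"):
            harmonize_set(exp, out, inst)

    def test_zero_retained_raises_naming_reasons(self):
        exp, out = self._records(k=1)
        out[0] = make_record(rsid="rs0", effect_allele="A", other_allele="C", se=0.004)
        inst = InstrumentSet(label="x", members=["rs0"])
        with pytest.raises(EmptySetError, match="allele_mismatch"):
            harmonize_set(exp, out, inst)


class TestOrientation:
    def test_positive_set_unchanged_and_ratios_invariant(self):
        study = simulate_two_sample_study(SimulationConfig(k=12, seed=5))
        hset = study.to_harmonized()
        oriented = orient_exposure_positive(hset)
        ratios_before = sorted(v.by / v.bx for v in hset.variants)
        ratios_after = sorted(v.by / v.bx for v in oriented.variants)
        assert ratios_before == pytest.approx(ratios_after, abs=0)
        assert all(v.bx >= 0 for v in oriented.variants)

    def test_ivw_identical_after_orientation(self):
        """Joint sign flips leave the IVW estimate unchanged to the last bit."""
        study = simulate_two_sample_study(SimulationConfig(k=15, seed=6))
        hset = study.to_harmonized()
        flipped = scramble_alleles(study, swap_probability=1.0, flip_probability=0.0, seed=0)
        hset2 = flipped.to_harmonized()
        assert ivw(orient_exposure_positive(hset)).beta == ivw(hset).beta
        assert ivw(hset2).beta == ivw(hset).beta


def test_scramble_fuzz_preserves_estimates_bitwise():
    """Random swaps/flips of outcome codings never change downstream IVW."""
    study = simulate_two_sample_study(
        SimulationConfig(k=25, seed=42, palindromic_fraction=0.2)
    )
    baseline = ivw(study.to_harmonized())
    for seed in range(20):
        scrambled = scramble_alleles(
            study, swap_probability=0.5, flip_probability=0.5, seed=seed
        )
        est = ivw(scrambled.to_harmonized())
        assert est.beta == baseline.beta and est.se == baseline.se
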