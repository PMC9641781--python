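"""Panel loading, proxy rules, allele harmonization and the HWE exact test."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from endomr.instruments import (
    InstrumentPanel, InstrumentRecord, PanelValidationError,
    DEFAULT_PROXY_WHITELIST, load_summary_stats, filter_gw_significant,
    substitute_proxy, harmonize_alleles, hwe_exact_test, effect_allele_freq,
)


def rec(rsid="rs1", ea="A", oa="G", beta=0.05, se=0.005, pval=1e-10, eaf=None):
    return InstrumentRecord(rsid=rsid, effect_allele=ea, other_allele=oa,
                            beta_x=beta, se_x=se, pval=pval, eaf=eaf)


def write_panel_tsv(path, rows):
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class TestLoad:
    def test_round_trip(self, tmp_path):
        rows = [{"rsid": f"rs{i}", "effect_allele": "A", "other_allele": "G",
                 "beta": 0.05, "se": 0.005, "pval": 1e-10, "eaf": 0.3}
                for i in range(20)]
        f = tmp_path / "ss.tsv"
        write_panel_tsv(f, rows)
        panel = load_summary_stats(f)
        assert len(panel) == 20
        assert panel.get("rs3").eaf == 0.3

    def test_zero_se_reported_with_rsid(self, tmp_path):
        rows = [{"rsid": "rsBAD", "effect_allele": "A", "other_allele": "G",
                 "beta": 0.05, "se": 0.0, "pval": 1e-10}]
        f = tmp_path / "ss.tsv"
        write_panel_tsv(f, rows)
        with pytest.raises(PanelValidationError, match="rsBAD"):
            load_summary_stats(f)

    def test_duplicate_rsid_lists_line_numbers(self, tmp_path):
        rows = [{"rsid": "rsDUP", "effect_allele": "A", "other_allele": "G",
                 "beta": 0.05, "se": 0.005, "pval": 1e-10}] * 2
        f = tmp_path / "ss.tsv"
        write_panel_tsv(f, rows)
        with pytest.raises(PanelValidationError, match=r"rsDUP.*\[1, 2\]"):
            load_summary_stats(f)

    def test_column_map(self, tmp_path):
        rows = [{"variant_id": "rs1", "EA": "A", "OA": "G",
                 "b": 0.05, "standard_error": 0.005, "p_value": 1e-10}]
        f = tmp_path / "ss.tsv"
        write_panel_tsv(f, rows)
        panel = load_summary_stats(f, column_map={
            "rsid": "variant_id", "effect_allele": "EA", "other_allele": "OA",
            "beta": "b", "se": "standard_error", "pval": "p_value"})
        assert panel.rsids == ["rs1"]

    def test_missing_column_named(self, tmp_path):
        f = tmp_path / "ss.tsv"
        write_panel_tsv(f, [{"rsid": "rs1", "beta": 0.05}])
        with pytest.raises(PanelValidationError, match="missing required"):
            load_summary_stats(f)


class TestFilter:
    def test_strict_inequality_at_threshold(self):
        panel = InstrumentPanel(records=(
            rec("a", pval=1e-9), rec("b", pval=4.9e-8), rec("c", pval=5e-8)))
        kept = filter_gw_significant(panel, 5e-8)
        assert kept.rsids == ["a", "b"]

    def test_empty_result_allowed(self):
        panel = InstrumentPanel(records=(rec("a", pval=0.5),))
        assert len(filter_gw_significant(panel, 5e-8)) == 0

    def test_threshold_one_is_identity(self):
        panel = InstrumentPanel(records=(rec("a", pval=0.99), rec("b", pval=1e-9)))
        assert filter_gw_significant(panel, 1.0).rsids == panel.rsids


class TestProxy:
    def panel(self):
        return InstrumentPanel(records=(rec("rsA"), rec("rsB", ea="C", oa="T")))

    def test_accepted_above_threshold(self):
        out = substitute_proxy(self.panel(), "rsA", rec("rsP"), r2=0.92)
        p = out.get("rsP")
        assert p.proxy_of == "rsA" and p.proxy_r2 == 0.92
        assert "rsA" not in out.rsids

    def test_whitelisted_exception_accepted(self):
        out = substitute_proxy(self.panel(), "rsA", rec("rs7705526"), r2=0.79)
        assert out.get("rs7705526").proxy_r2 == 0.79
        assert DEFAULT_PROXY_WHITELIST["rs7705526"] == 0.79

    def test_unlisted_low_r2_rejected(self):
        with pytest.raises(PanelValidationError, match="rejected"):
            substitute_proxy(self.panel(), "rsA", rec("rsP"), r2=0.5)

    def test_proxy_already_in_panel_rejected(self):
        with pytest.raises(PanelValidationError, match="already present"):
            substitute_proxy(self.panel(), "rsA", rec("rsB", ea="C", oa="T"), r2=0.95)


class TestHarmonize:
    def alleles(self, rows):
        return pd.DataFrame(rows)

    def test_match_swap_flip(self):
        panel = InstrumentPanel(records=(
            rec("r1", "A", "G"), rec("r2", "A", "G"), rec("r3", "A", "G")))
        info = self.alleles([
            {"rsid": "r1", "counted_allele": "A", "other_allele": "G"},
            {"rsid": "r2", "counted_allele": "G", "other_allele": "A"},
            {"rsid": "r3", "counted_allele": "T", "other_allele": "C"},
        ])
        out, log = harmonize_alleles(panel, info)
        actions = dict(zip(log["rsid"], log["action"]))
        assert actions == {"r1": "match", "r2": "swap", "r3": "strand_flip"}
        assert log.set_index("rsid")["flip_dosage"].to_dict() == {
            "r1": False, "r2": True, "r3": False}
        assert len(out) == 3

    def test_irreconcilable_dropped(self):
        panel = InstrumentPanel(records=(rec("r1", "A", "G"),))
        info = self.alleles([
            {"rsid": "r1", "counted_allele": "A", "other_allele": "C"}])
        out, log = harmonize_alleles(panel, info)
        assert len(out) == 0
        assert log["action"].iloc[0] == "drop"

    def test_ambiguous_without_eaf_dropped(self):
        panel = InstrumentPanel(records=(rec("r1", "A", "T"),))
        info = self.alleles([
            {"rsid": "r1", "counted_allele": "A", "other_allele": "T"}])
        out, log = harmonize_alleles(panel, info)
        assert log["action"].iloc[0] == "drop"

    def test_ambiguous_resolved_by_frequency(self):
        panel = InstrumentPanel(records=(rec("r1", "A", "T", eaf=0.1),))
        same = self.alleles([{"rsid": "r1", "counted_allele": "A",
                              "other_allele": "T", "eaf": 0.12}])
        flipped = self.alleles([{"rsid": "r1", "counted_allele": "A",
                                 "other_allele": "T", "eaf": 0.88}])
        _, log1 = harmonize_alleles(panel, same)
        _, log2 = harmonize_alleles(panel, flipped)
        assert log1["action"].iloc[0] == "match"
        assert log2["action"].iloc[0] == "strand_flip_swap"
        assert bool(log2["flip_dosage"].iloc[0])

    def test_ambiguous_band_dropped(self):
        panel = InstrumentPanel(records=(rec("r1", "C", "G", eaf=0.5),))
        info = self.alleles([{"rsid": "r1", "counted_allele": "C",
                              "other_allele": "G", "eaf": 0.5}])
        _, log = harmonize_alleles(panel, info)
        assert log["action"].iloc[0] == "drop"

    def test_idempotent(self):
        panel = InstrumentPanel(records=(
            rec("r1", "A", "G"), rec("r2", "T", "C")))
        info = self.alleles([
            {"rsid": "r1", "counted_allele": "G", "other_allele": "A"},
            {"rsid": "r2", "counted_allele": "A", "other_allele": "G"},
        ])
        out, log1 = harmonize_alleles(panel, info)
        # after applying the log, the cohort counts the effect allele everywhere
        aligned = self.alleles([
            {"rsid": r.rsid, "counted_allele": r.effect_allele,
             "other_allele": r.other_allele} for r in out])
        _, log2 = harmonize_alleles(out, aligned)
        assert (log2["action"] == "match").all()


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_AA + n_Aa
    n_b = 2 * n - n_a
    rare = min(n_a, n_b)
    probs = {}
    denom = comb(2 * n, n_a)
    for h in range(rare % 2, rare + 1, 2):
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        num = Fraction(
            comb(n, naa) * comb(n - naa, h) * 2 ** h, denom)
        probs[h] = num
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHWE:
    def test_monomorphic(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_small_table_vs_oracle(self):
        assert hwe_exact_test(5, 10, 5) == pytest.approx(
            hwe_enumeration_oracle(5, 10, 5), abs=1e-12)

    def test_strong_violation(self):
        assert hwe_exact_test(50, 0, 50) < 1e-10

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_agrees_with_enumeration(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_test(a, h, b) == pytest.approx(
            hwe_enumeration_oracle(a, h, b), abs=1e-12)


class TestEAF:
    def test_all_homozygous(self):
        assert effect_allele_freq([2, 2, 2]) == 1.0

    def test_hand_mean(self):
        assert effect_allele_freq([0, 1, 2, 1]) == 0.5

    def test_missing_excluded(self):
        assert effect_allele_freq([0.0, np.nan, 2.0]) == 0.5

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            effect_allele_freq([np.nan, np.nan])


def test_dosage_recode_sign_consistency(rng):
    """Recoding dosage 2-g with the allele-swapped record leaves the MR
    estimate unchanged end to end."""
    from endomr.endophenotypes import snp_outcome_regression
    from endomr.mr_core import MRInput, ivw_estimate

    n = 300
    g = rng.binomial(2, 0.4, n).astype(float)
    cov = pd.DataFrame({"age": rng.uniform(45, 74, n),
                        "sex": rng.integers(0, 2, n).astype(float)})
    y = 0.1 * g + rng.normal(0, 1, n)

    a = snp_outcome_regression(g, y, cov, rsid="rs1")
    b = snp_outcome_regression(2.0 - g, y, cov, rsid="rs1")
    assert b.beta_y == pytest.approx(-a.beta_y, rel=1e-9)
    assert b.se_y == pytest.approx(a.se_y, rel=1e-9)

    # allele-swapped exposure record has beta_x of opposite orientation
    def est(beta_x, beta_y):
        return ivw_estimate(MRInput(rsid=("rs1", "rs2"),
                                    beta_x=[beta_x, 0.05], se_x=[0.005] * 2,
                                    beta_y=[beta_y, 0.01], se_y=[a.se_y, 0.01]),
                            model="fixed").beta

    assert est(0.06, a.beta_y) == pytest.approx(est(-0.06, b.beta_y), rel=1e-12)
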