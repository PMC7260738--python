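"""Association layer: collapsing, eligibility, exact/regression tests, FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from cpg import (ClassifiedVariant, ValidationError, bh_adjust,
                 build_carrier_matrix, fit_logistic_association,
                 gene_level_af_summary, pc_variance_summary, run_associations,
                 tft_test)
from cpg.association import tft_from_counts
from cpg.association import test_eligibility as check_eligibility

from conftest import make_sample

import pandas as pd


def cv(sample, gene, classification="likely_pathogenic", key="13:1:C:T"):
    return ClassifiedVariant(key, sample, gene, 10, classification)


def cohort(n_cases, n_controls, carrier_case_ids=(), carrier_control_ids=()):
    """An afr cohort of LUSC cases vs BRCA controls with chosen carriers."""
    samples = [make_sample(f"C{i}", cancer="LUSC") for i in range(n_cases)]
    samples += [make_sample(f"N{i}", cancer="BRCA") for i in range(n_controls)]
    classified = [cv(sid, "BRCA2", key=f"13:{i}:C:T")
                  for i, sid in enumerate(list(carrier_case_ids)
                                          + list(carrier_control_ids))]
    carriers = build_carrier_matrix(classified, samples)
    if "BRCA2" not in carriers.columns:
        carriers["BRCA2"] = False
    return samples, carriers


class TestCarrierMatrix:
    def test_single_lp_variant_makes_carrier(self):
        samples = [make_sample("S1")]
        m = build_carrier_matrix([cv("S1", "BRCA2")], samples)
        assert bool(m.loc["S1", "BRCA2"])

    def test_two_variants_one_gene_single_carrier_entry(self):
        samples = [make_sample("S1")]
        m = build_carrier_matrix([cv("S1", "ATM", key="11:1:C:T"),
                                  cv("S1", "ATM", key="11:2:C:T")], samples)
        assert int(m.sum().sum()) == 1

    def test_uncertain_variant_does_not_collapse(self):
        samples = [make_sample("S1")]
        m = build_carrier_matrix([cv("S1", "ATM", classification="uncertain")],
                                 samples)
        assert "ATM" not in m.columns

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            build_carrier_matrix([cv("GHOST", "ATM")], [make_sample("S1")])


class TestEligibility:
    @pytest.mark.parametrize("n_cases,n_carr,method,eligible", [
        (19, 5, "logistic", False),
        (25, 1, "logistic", False),
        (25, 1, "tft", True),
        (25, 2, "logistic", True),
        (25, 2, "tft", True),
    ])
    def test_rules(self, n_cases, n_carr, method, eligible):
        carrier_ids = [f"C{i}" for i in range(n_carr)]
        samples, carriers = cohort(n_cases, 50, carrier_case_ids=carrier_ids)
        ok, _ = check_eligibility(samples, carriers, "afr", "LUSC", "BRCA2",
                                  method=method)
        assert ok is eligible


class TestLogistic:
    def test_matches_closed_form_2x2(self):
        samples, carriers = cohort(10, 10,
                                   carrier_case_ids=["C0", "C1", "C2", "C3"],
                                   carrier_control_ids=["N0"])
        res = fit_logistic_association(samples, carriers, "afr", "LUSC", "BRCA2",
                                       covariates=())
        assert res.or_estimate == pytest.approx(6.0, abs=1e-6)
        woolf_se = math.sqrt(1 / 4 + 1 / 6 + 1 / 1 + 1 / 9)
        z = math.log(6.0) / woolf_se
        from scipy.stats import norm
        assert res.p_value == pytest.approx(2 * norm.sf(abs(z)), abs=1e-6)
        assert res.ci_low <= res.or_estimate <= res.ci_high

    def test_constant_carrier_flag_non_estimable(self):
        samples, carriers = cohort(10, 10)
        res = fit_logistic_association(samples, carriers, "afr", "LUSC", "BRCA2",
                                       covariates=())
        assert res.status == "non_estimable"

    def test_separation_flagged_with_infinite_or(self):
        samples, carriers = cohort(25, 25,
                                   carrier_case_ids=[f"C{i}" for i in range(10)])
        res = fit_logistic_association(samples, carriers, "afr", "LUSC", "BRCA2",
                                       covariates=())
        assert res.status == "separation" and math.isinf(res.or_estimate)

    def test_missing_covariates_dropped(self):
        samples, carriers = cohort(30, 30,
                                   carrier_case_ids=["C0", "C1", "C2"],
                                   carrier_control_ids=["N0", "N1"])
        samples[0].age_years = None  # C0 must be excluded from the fit
        res = fit_logistic_association(samples, carriers, "afr", "LUSC", "BRCA2",
                                       covariates=("age",))
        assert res.n_cases == 29 and res.carriers_cases == 2


class TestTft:
    @staticmethod
    def hypergeom_tail_oracle(a, n_cases, b, n_controls):
        """One-sided enumeration: P[case alleles >= a | margins]."""
        k_total = a + b
        n1, n2 = 2 * n_cases, 2 * n_controls
        denom = comb(n1 + n2, k_total, exact=True)
        num = sum(comb(n1, x, exact=True) * comb(n2, k_total - x, exact=True)
                  for x in range(a, min(k_total, n1) + 1))
        return num / denom

    def test_matches_worked_cohort(self):
        # 29 cases with 2 pathogenic alleles vs 937 controls with 1
        res = tft_from_counts(2, 29, 1, 937)
        assert res.p_value == pytest.approx(
            self.hypergeom_tail_oracle(2, 29, 1, 937), rel=1e-12)

    def test_minimal_table_exact_value(self):
        res = tft_from_counts(2, 1, 0, 1)  # C(2,2)C(2,0)/C(4,2) = 1/6
        assert res.p_value == pytest.approx(1 / 6, rel=1e-12)

    def test_no_carriers_p_one(self):
        res = tft_from_counts(0, 25, 0, 100)
        assert res.p_value == 1.0

    def test_zero_group_rejected(self):
        with pytest.raises(ValidationError):
            tft_from_counts(0, 0, 1, 10)

    @given(st.integers(1, 15), st.integers(1, 15),
           st.integers(0, 8), st.integers(0, 8))
    @settings(deadline=None, max_examples=60)
    def test_matches_enumeration_oracle(self, n_cases, n_controls, a, b):
        a = min(a, 2 * n_cases)
        b = min(b, 2 * n_controls)
        res = tft_from_counts(a, n_cases, b, n_controls)
        assert res.p_value == pytest.approx(
            self.hypergeom_tail_oracle(a, n_cases, b, n_controls), rel=1e-9)

    def test_full_interface_counts_carriers(self):
        samples, carriers = cohort(25, 100, carrier_case_ids=["C0", "C1"],
                                   carrier_control_ids=["N0"])
        res = tft_test(samples, carriers, "afr", "LUSC", "BRCA2")
        assert (res.carriers_cases, res.carriers_controls) == (2, 1)
        assert res.method == "tft"


class TestBhAdjust:
    @staticmethod
    def naive_oracle(p):
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        q = [None] * m
        best = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            best = min(best, p[i] * m / rank)
            q[i] = best
        return q

    @pytest.mark.parametrize("p,expected", [
        ([0.01], [0.01]),
        ([0.01, 0.04, 0.03, 0.02], [0.04, 0.04, 0.04, 0.04]),
        ([0.2] * 5, [0.2] * 5),
    ])
    def test_known_vectors(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            p = rng.random(int(rng.integers(1, 25))).tolist()
            assert bh_adjust(p) == pytest.approx(self.naive_oracle(p), rel=1e-12)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(200)
        ours = bh_adjust(p.tolist())
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs.tolist(), rel=1e-12)


class TestGeneAfSummary:
    def test_single_variant_worked_example(self):
        df = pd.DataFrame([{"gene": "ATM", "group": "afr", "ac": 1, "an": 14878}])
        out = gene_level_af_summary(df)
        freq = out.loc[0, "frequency"]
        assert 100 * freq == pytest.approx(0.0067, abs=5e-4)

    def test_sum_ac_over_max_an(self):
        df = pd.DataFrame([
            {"gene": "G", "group": "afr", "ac": 1, "an": 14878},
            {"gene": "G", "group": "afr", "ac": 3, "an": 14900},
        ])
        out = gene_level_af_summary(df)
        assert out.loc[0, "frequency"] == pytest.approx(4 / 14900)

    def test_rarity_prefilter_excludes_common(self):
        df = pd.DataFrame([
            {"gene": "G", "group": "afr", "ac": 1, "an": 1000},     # 0.1%
            {"gene": "G", "group": "afr", "ac": 100, "an": 1000},   # 10%: excluded
        ])
        out = gene_level_af_summary(df, max_group_maf=0.005)
        assert out.loc[0, "frequency"] == pytest.approx(1 / 1000)

    def test_ac_above_an_rejected(self):
        df = pd.DataFrame([{"gene": "G", "group": "afr", "ac": 5, "an": 2}])
        with pytest.raises(ValidationError):
            gene_level_af_summary(df)


class TestPcVariance:
    def test_worked_shares(self):
        # eigenvalues proportional to the printed shares
        lam = [51.6, 29.2] + [19.2 / 18] * 18
        summary = pc_variance_summary(lam)
        assert summary.shares_percent[0] == pytest.approx(51.6)
        assert summary.first_two_percent == pytest.approx(80.8)

    @pytest.mark.parametrize("lam,shares", [
        ([2.0, 2.0, 2.0, 2.0], [25.0] * 4),
        ([7.5], [100.0]),
    ])
    def test_simple_cases(self, lam, shares):
        assert pc_variance_summary(lam).shares_percent == pytest.approx(shares)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            pc_variance_summary([0.0, 0.0])


class TestRunAssociations:
    def test_fdr_attached_within_ancestry_family(self):
        samples, carriers = cohort(25, 100, carrier_case_ids=["C0", "C1"],
                                   carrier_control_ids=["N0"])
        results = run_associations(samples, carriers, method="tft")
        assert results and all(math.isfinite(r.fdr) for r in results)
        lusc = [r for r in results if r.cancer == "LUSC" and r.gene == "BRCA2"]
        assert len(lusc) == 1

    def test_controls_exclude_tested_cancer(self):
        samples, carriers = cohort(25, 100, carrier_case_ids=["C0", "C1"])
        res = tft_test(samples, carriers, "afr", "LUSC", "BRCA2")
        assert res.n_cases == 25 and res.n_controls == 100
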