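"""LOH allelic-imbalance testing and biallelic second-hit detection."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from cpg import categorize_loh, find_biallelic, loh_test
from cpg.two_hit import LohResult

from conftest import make_variant


def fisher_two_sided_oracle(ta, tr, na, nr):
    """Exhaustive conditional two-sided p over all tables with the margins."""
    row1, col1, n = ta + tr, ta + na, ta + tr + na + nr

    def prob(x):
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > n - row1:
            return 0.0
        return (comb(row1, x, exact=True)
                * comb(n - row1, col1 - x, exact=True)
                / comb(n, col1, exact=True))

    p_obs = prob(ta)
    return sum(prob(x) for x in range(0, col1 + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestLohTest:
    def test_worked_table(self):
        v = make_variant(normal_depth=4, normal_alt=2, tumor_depth=4, tumor_alt=4)
        res = loh_test(v)
        assert res.p_value == pytest.approx(30 / 70, rel=1e-12)
        assert res.direction == "toward_variant"

    def test_identical_vafs_symmetric(self):
        v = make_variant(normal_depth=40, normal_alt=20, tumor_depth=40, tumor_alt=20)
        res = loh_test(v)
        assert res.p_value == 1.0 and res.direction == "none"

    def test_loss_of_variant_allele(self):
        v = make_variant(normal_depth=50, normal_alt=25, tumor_depth=50, tumor_alt=0)
        res = loh_test(v)
        assert res.direction == "toward_reference" and res.p_value < 1e-6

    def test_missing_tumor_counts(self):
        v = make_variant(tumor_depth=None, tumor_alt=None)
        res = loh_test(v)
        assert res.status == "no tumor data" and res.category == "none"
        assert math.isnan(res.p_value)

    @given(st.integers(0, 20), st.integers(0, 20),
           st.integers(0, 20), st.integers(0, 20))
    @settings(deadline=None, max_examples=80)
    def test_matches_enumeration_oracle(self, ta, tr, na, nr):
        # totals <= 40 reads split across tumor and normal
        if ta + tr == 0 or na + nr == 0:
            return
        v = make_variant(normal_depth=na + nr, normal_alt=na,
                         tumor_depth=ta + tr, tumor_alt=ta)
        assert loh_test(v).p_value == pytest.approx(
            fisher_two_sided_oracle(ta, tr, na, nr), rel=1e-9)


class TestCategorizeLoh:
    def loh(self, key, p, tumor_vaf, direction="toward_variant"):
        return LohResult(variant_key=key, sample_id="S1", gene="G",
                         normal_vaf=0.5, tumor_vaf=tumor_vaf, p_value=p,
                         fdr=math.nan, direction=direction)

    def test_categories(self):
        results = [
            self.loh("v1", 1e-6, 0.9),                # significant + deletion
            self.loh("v2", 1e-5, 0.9),                # significant, no deletion
            self.loh("v3", 0.5, 0.65),                # suggestive via tumor VAF
            self.loh("v4", 0.9, 0.50),                # nothing
            self.loh("v5", 1e-6, 0.1, "toward_reference"),  # wrong direction
        ]
        out = categorize_loh(results, {("S1", "v1"): True})
        cats = {r.variant_key: r.category for r in out}
        assert cats == {"v1": "loh_with_deletion", "v2": "other_loh",
                        "v3": "suggestive", "v4": "none", "v5": "none"}

    def test_suggestive_via_fdr_band(self):
        # single test: fdr == p = 0.10 < 0.15, not < 0.05
        out = categorize_loh([self.loh("v1", 0.10, 0.55)])
        assert out[0].category == "suggestive"
        assert out[0].fdr == pytest.approx(0.10)

    def test_fdr_family_spans_all_tested(self):
        results = [self.loh(f"v{i}", p, 0.9) for i, p in enumerate([0.01, 0.02, 0.8])]
        out = categorize_loh(results)
        assert out[0].fdr == pytest.approx(0.03)  # BH over 3 tests


class TestFindBiallelic:
    @staticmethod
    def carriers_frame():
        return pd.DataFrame({"ATM": [True, True], "VHL": [False, True]},
                            index=["S1", "S2"])

    def test_nonsilent_same_gene_is_biallelic(self):
        somatic = pd.DataFrame([{"sample_id": "S1", "gene": "ATM",
                                 "consequence": "missense", "hgvs": "ATM:p.E2164K"}])
        recs = find_biallelic(self.carriers_frame(), somatic)
        by = {(r.sample_id, r.gene): r for r in recs}
        assert by[("S1", "ATM")].biallelic
        assert by[("S1", "ATM")].somatic_hgvs == "ATM:p.E2164K"
        assert not by[("S2", "ATM")].biallelic

    def test_other_gene_not_biallelic(self):
        somatic = pd.DataFrame([{"sample_id": "S2", "gene": "TP53",
                                 "consequence": "nonsense", "hgvs": "x"}])
        recs = find_biallelic(self.carriers_frame(), somatic)
        assert not any(r.biallelic for r in recs)

    def test_synonymous_not_biallelic(self):
        somatic = pd.DataFrame([{"sample_id": "S1", "gene": "ATM",
                                 "consequence": "synonymous", "hgvs": "x"}])
        recs = find_biallelic(self.carriers_frame(), somatic)
        assert not any(r.biallelic for r in recs)

    def test_one_record_per_carrier_gene_pair(self):
        recs = find_biallelic(self.carriers_frame(),
                              pd.DataFrame(columns=["sample_id", "gene",
                                                    "consequence", "hgvs"]))
        assert {(r.sample_id, r.gene) for r in recs} == \
            {("S1", "ATM"), ("S2", "ATM"), ("S2", "VHL")}
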