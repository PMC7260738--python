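"""Gene-level collapsing and ancestry-stratified case-control association.

Predisposing (pathogenic + likely pathogenic) variants are collapsed to a
boolean sample x gene carrier matrix. Within each ancestry, each cancer
type is tested against all other cancer cohorts of the same ancestry as
controls, by either

* multivariate logistic regression of case status on carrier status,
  adjusted for age at diagnosis, sex and the first two genotype principal
  components, with Wald tests (eligibility: >= 20 cases and >= 2 carriers
  in the ancestry cohort); or
* the Total Frequency Test (TFT): pooled pathogenic allele counts versus
  the remaining alleles (2N - count) in a 2x2 table, with a one-sided
  exact conditional (hypergeometric) p-value for enrichment in cases
  (eligibility: >= 20 cases and >= 1 carrier).

P-values are adjusted per ancestry with the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SampleRecord, ValidationError, log
from .pathogenicity import ClassifiedVariant

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class AssociationResult:
    """One (ancestry, cancer, gene) association test."""

    ancestry: str
    cancer: str
    gene: str
    n_cases: int
    n_controls: int
    carriers_cases: int
    carriers_controls: int
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    fdr: float
    method: str  # "logistic" / "tft"
    status: str = "ok"  # "ok" / "separation" / "non_estimable" / "not_converged"


@dataclass
class PcVarianceSummary:
    """Variance shares of the leading principal components."""

    shares_percent: list[float]
    cumulative_percent: list[float]

    @property
    def first_two_percent(self) -> float:
        return self.cumulative_percent[1] if len(self.cumulative_percent) > 1 else \
            self.cumulative_percent[0]


# ---------------------------------------------------------------------------
# Carrier matrix
# ---------------------------------------------------------------------------

def build_carrier_matrix(classified: list[ClassifiedVariant],
                         samples: list[SampleRecord]) -> pd.DataFrame:
    """Collapse P/LP variants to a boolean sample x gene carrier matrix.

    Multiple predisposing variants of one gene in one sample still count
    as a single carrier. A variant referencing an unknown sample is a
    validation error. Genes with no predisposing variant anywhere simply
    do not appear as columns.
    """
    sample_ids = [s.sample_id for s in samples]
    known = set(sample_ids)
    predisposing = [c for c in classified if c.is_predisposing]
    for c in predisposing:
        if c.sample_id not in known:
            raise ValidationError(f"variant {c.variant_key} references unknown "
                                  f"sample {c.sample_id!r}")
    genes = sorted({c.gene for c in predisposing})
    matrix = pd.DataFrame(False, index=sample_ids, columns=genes, dtype=bool)
    for c in predisposing:
        matrix.loc[c.sample_id, c.gene] = True
    return matrix


def _cohort_frame(samples: list[SampleRecord], carriers: pd.DataFrame,
                  ancestry: str, cancer: str, gene: str) -> pd.DataFrame:
    rows = []
    for s in samples:
        if s.analysis_group != ancestry:
            continue
        rows.append({
            "sample_id": s.sample_id,
            "case": s.cancer_type == cancer,
            "carrier": bool(carriers.loc[s.sample_id, gene]) if gene in carriers.columns else False,
            "age": s.age_years,
            "sex": s.sex,
            "pc1": s.pc1,
            "pc2": s.pc2,
        })
    return pd.DataFrame(rows)


def test_eligibility(samples: list[SampleRecord], carriers: pd.DataFrame,
                     ancestry: str, cancer: str, gene: str,
                     method: str = "logistic",
                     min_cases: int = 20) -> tuple[bool, str]:
    """Apply the cohort-size and carrier-count eligibility rules.

    Logistic regression needs >= ``min_cases`` cases and >= 2 carriers in
    the ancestry cohort; the TFT needs >= ``min_cases`` cases and >= 1
    carrier. Returns (eligible, reason).
    """
    df = _cohort_frame(samples, carriers, ancestry, cancer, gene)
    n_cases = int(df["case"].sum()) if len(df) else 0
    n_carriers = int(df["carrier"].sum()) if len(df) else 0
    if n_cases < min_cases:
        return False, f"cases={n_cases}<{min_cases}"
    min_carriers = 2 if method == "logistic" else 1
    if n_carriers < min_carriers:
        return False, f"carriers={n_carriers}<{min_carriers}"
    return True, "eligible"


# ---------------------------------------------------------------------------
# Logistic association
# ---------------------------------------------------------------------------

def fit_logistic_association(samples: list[SampleRecord], carriers: pd.DataFrame,
                             ancestry: str, cancer: str, gene: str,
                             covariates: Sequence[str] = ("age", "sex", "pc1", "pc2"),
                             separation_coef: float = 10.0) -> AssociationResult:
    """Logistic regression of case status on gene carrier status.

    Uses all other cancer cohorts of the same ancestry as controls and
    adjusts for the requested covariates. Samples missing a required
    covariate are dropped (logged with counts); a single-sex cohort drops
    the sex covariate to avoid collinearity. The odds ratio is
    exp(carrier coefficient) with a 95% Wald interval and Wald-z p-value.
    Complete or quasi-complete separation (|coefficient| above
    ``separation_coef``) is flagged rather than reported as a finite
    estimate.
    """
    import statsmodels.api as sm

    df = _cohort_frame(samples, carriers, ancestry, cancer, gene)
    covariates = list(covariates)
    if "sex" in covariates:
        observed_sexes = df["sex"].dropna().unique()
        if len(observed_sexes) < 2:
            covariates.remove("sex")
            log.debug("%s/%s/%s: single-sex cohort, sex covariate dropped",
                      ancestry, cancer, gene)
    needed = [c for c in covariates]
    before = len(df)
    df = df.dropna(subset=needed) if needed else df
    if len(df) < before:
        log.info("%s/%s/%s: dropped %d samples with missing covariates",
                 ancestry, cancer, gene, before - len(df))

    n_cases = int(df["case"].sum())
    n_controls = len(df) - n_cases
    carriers_cases = int((df["case"] & df["carrier"]).sum())
    carriers_controls = int((~df["case"] & df["carrier"]).sum())

    base = dict(ancestry=ancestry, cancer=cancer, gene=gene,
                n_cases=n_cases, n_controls=n_controls,
                carriers_cases=carriers_cases, carriers_controls=carriers_controls,
                method="logistic", fdr=math.nan)

    nan = math.nan
    if df["carrier"].nunique() < 2 or df["case"].nunique() < 2:
        return AssociationResult(**base, or_estimate=nan, ci_low=nan, ci_high=nan,
                                 p_value=nan, status="non_estimable")

    X = pd.DataFrame({"carrier": df["carrier"].astype(float)})
    for cov in covariates:
        X[cov] = (df[cov] == "male").astype(float) if cov == "sex" else df[cov].astype(float)
    X = sm.add_constant(X, has_constant="add")
    y = df["case"].astype(float).to_numpy()

    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    def _separated() -> AssociationResult:
        case_rate = carriers_cases / n_cases if n_cases else 0.0
        ctrl_rate = carriers_controls / n_controls if n_controls else 0.0
        or_est = math.inf if case_rate >= ctrl_rate else 0.0
        return AssociationResult(**base, or_estimate=or_est, ci_low=nan,
                                 ci_high=nan, p_value=nan, status="separation")

    n_carriers = carriers_cases + carriers_controls
    one_sided_carriers = n_carriers > 0 and (carriers_cases == 0
                                             or carriers_controls == 0)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except PerfectSeparationError:
        return _separated()
    except Exception:
        # a singular Hessian under one-sided carrier counts is
        # quasi-separation: the carrier coefficient diverges
        if one_sided_carriers:
            return _separated()
        return AssociationResult(**base, or_estimate=nan, ci_low=nan, ci_high=nan,
                                 p_value=nan, status="not_converged")

    coef = float(fit.params["carrier"])
    se = float(fit.bse["carrier"])
    if abs(coef) > separation_coef or not np.isfinite(se):
        return _separated()
    if not fit.mle_retvals.get("converged", True):
        status = "not_converged"
    else:
        status = "ok"
    z = coef / se
    p = 2 * stats.norm.sf(abs(z))
    return AssociationResult(**base,
                             or_estimate=math.exp(coef),
                             ci_low=math.exp(coef - Z_95 * se),
                             ci_high=math.exp(coef + Z_95 * se),
                             p_value=float(p), status=status)


# ---------------------------------------------------------------------------
# Total Frequency Test
# ---------------------------------------------------------------------------

def tft_test(samples: list[SampleRecord], carriers: pd.DataFrame,
             ancestry: str, cancer: str, gene: str,
             two_sided: bool = False) -> AssociationResult:
    """Exact burden test of pooled pathogenic allele counts.

    Each carrier contributes one pathogenic allele (predisposing variants
    are rare and heterozygous); each group of N samples contributes 2N
    alleles. The 2x2 table of pathogenic vs remaining alleles in cases vs
    controls is tested with the exact conditional hypergeometric test,
    one-sided toward enrichment in cases by default. The odds ratio is
    the sample odds ratio of the allele table.
    """
    df = _cohort_frame(samples, carriers, ancestry, cancer, gene)
    n_cases = int(df["case"].sum())
    n_controls = len(df) - n_cases
    a_case = int((df["case"] & df["carrier"]).sum())      # pathogenic alleles, cases
    a_ctrl = int((~df["case"] & df["carrier"]).sum())
    return tft_from_counts(a_case, n_cases, a_ctrl, n_controls,
                           ancestry=ancestry, cancer=cancer, gene=gene,
                           two_sided=two_sided)


def tft_from_counts(carriers_cases: int, n_cases: int,
                    carriers_controls: int, n_controls: int,
                    ancestry: str = "", cancer: str = "", gene: str = "",
                    two_sided: bool = False) -> AssociationResult:
    """TFT on pre-tabulated carrier counts (one pathogenic allele each)."""
    if n_cases == 0 or n_controls == 0:
        raise ValidationError(f"{ancestry}/{cancer}: empty case or control group")
    a_case, a_ctrl = carriers_cases, carriers_controls
    table = [[a_case, 2 * n_cases - a_case],
             [a_ctrl, 2 * n_controls - a_ctrl]]
    alternative = "two-sided" if two_sided else "greater"
    p = float(stats.fisher_exact(table, alternative=alternative).pvalue)
    num = table[0][0] * table[1][1]
    den = table[0][1] * table[1][0]
    or_est = math.inf if den == 0 and num > 0 else (math.nan if den == 0 else num / den)
    # Woolf interval on the allele table (with Haldane correction on zeros)
    cells = [table[0][0], table[0][1], table[1][0], table[1][1]]
    if all(c > 0 for c in cells):
        se = math.sqrt(sum(1 / c for c in cells))
        log_or = math.log(num / den)
        ci_low, ci_high = math.exp(log_or - Z_95 * se), math.exp(log_or + Z_95 * se)
    else:
        ci_low = ci_high = math.nan
    return AssociationResult(
        ancestry=ancestry, cancer=cancer, gene=gene,
        n_cases=n_cases, n_controls=n_controls,
        carriers_cases=a_case, carriers_controls=a_ctrl,
        or_estimate=or_est, ci_low=ci_low, ci_high=ci_high,
        p_value=p, fdr=math.nan, method="tft")


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at
    1; tied p-values share the same q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def run_associations(samples: list[SampleRecord], carriers: pd.DataFrame,
                     method: str = "logistic",
                     family: str = "per-ancestry",
                     min_cases: int = 20,
                     covariates: Sequence[str] = ("age", "sex", "pc1", "pc2"),
                     ) -> list[AssociationResult]:
    """Test every eligible (ancestry, cancer, gene) triple and attach FDR.

    The BH family is per ancestry by default (each ancestry's eligible
    cancer-gene pairs form one family), or ``"global"`` for a single
    family over all tests. Results with a non-finite p (flagged fits) do
    not enter the FDR family.
    """
    if method not in ("logistic", "tft"):
        raise ValueError(f"unknown association method {method!r}")
    if family not in ("per-ancestry", "global"):
        raise ValueError(f"unknown FDR family {family!r}")
    ancestries = sorted({s.analysis_group for s in samples})
    results: list[AssociationResult] = []
    for ancestry in ancestries:
        cancers = sorted({s.cancer_type for s in samples if s.analysis_group == ancestry})
        for cancer in cancers:
            for gene in carriers.columns:
                ok, _ = test_eligibility(samples, carriers, ancestry, cancer, gene,
                                         method=method, min_cases=min_cases)
                if not ok:
                    continue
                if method == "logistic":
                    res = fit_logistic_association(samples, carriers, ancestry,
                                                   cancer, gene, covariates=covariates)
                else:
                    res = tft_test(samples, carriers, ancestry, cancer, gene)
                results.append(res)

    def _attach_fdr(group: list[AssociationResult]) -> None:
        testable = [r for r in group if math.isfinite(r.p_value)]
        fdrs = bh_adjust([r.p_value for r in testable])
        for r, q in zip(testable, fdrs):
            r.fdr = q

    if family == "global":
        _attach_fdr(results)
    else:
        for ancestry in ancestries:
            _attach_fdr([r for r in results if r.ancestry == ancestry])
    return results


# ---------------------------------------------------------------------------
# Gene-level allele-frequency and PC summaries
# ---------------------------------------------------------------------------

def gene_level_af_summary(variants: pd.DataFrame,
                          max_group_maf: Optional[float] = 0.005) -> pd.DataFrame:
    """Summarize allele frequencies at gene level within each group.

    ``variants`` needs columns gene, group, ac (allele count) and an
    (allele number). Per variant, rows with AC > AN are invalid. Variants
    at or above ``max_group_maf`` within their group are excluded first
    (rarity pre-filter; pass None to disable). The gene-level frequency is
    (sum of AC) / (max AN) within the (gene, group) cell; AN of 0 yields a
    missing frequency.
    """
    df = variants.copy()
    if (df["ac"] > df["an"]).any():
        raise ValidationError("allele count exceeds allele number")
    if max_group_maf is not None:
        with np.errstate(invalid="ignore"):
            maf = np.where(df["an"] > 0, df["ac"] / df["an"], np.nan)
        df = df[(maf < max_group_maf) | np.isnan(maf)]
    out = []
    for (gene, group), sub in df.groupby(["gene", "group"], sort=True):
        an_max = int(sub["an"].max()) if len(sub) else 0
        freq = math.nan if an_max == 0 else float(sub["ac"].sum()) / an_max
        out.append({"gene": gene, "group": group,
                    "ac_total": int(sub["ac"].sum()), "an_max": an_max,
                    "frequency": freq})
    return pd.DataFrame(out, columns=["gene", "group", "ac_total", "an_max", "frequency"])


def pc_variance_summary(eigenvalues: Sequence[float]) -> PcVarianceSummary:
    """Percent variance shares of the leading PCs and their cumulative sum.

    Shares are relative to the total over the supplied eigenvalues (e.g.
    the first 20 PCs), in percent.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0 or np.any(lam < 0):
        raise ValidationError("eigenvalues must be a non-empty non-negative list")
    total = lam.sum()
    if total == 0:
        raise ValidationError("all eigenvalues are zero")
    shares = (100.0 * lam / total).tolist()
    return PcVarianceSummary(shares_percent=shares,
                             cumulative_percent=np.cumsum(shares).tolist())
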