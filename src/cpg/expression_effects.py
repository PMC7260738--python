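"""Transcriptional effects of predisposing variants in carrier tumors.

Covers five measurements:

* cohort expression percentile of the affected gene in the carrier's
  tumor, via the right-continuous empirical CDF within the same cancer
  cohort, with extreme flags (> 80th or < 20th percentile, strict);
* allele-specific expression: RNA variant allele fraction at the
  heterozygous site with a two-sided exact binomial test against 0.5 —
  a low RNA VAF indicates degradation of the mutant transcript;
* mis-splicing fraction from junction-spanning read counts at a splice
  variant (cryptic / (consensus + cryptic));
* nonsense-mediated-decay competence of a premature termination codon by
  the canonical 50-nucleotide rule relative to the last exon-exon
  junction;
* a two-sample Kolmogorov-Smirnov comparison of carrier expression
  percentiles between tumor suppressors and oncogenes, exact by
  exhaustive label permutation for small groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, SampleRecord, ValidationError


@dataclass
class ExpressionRecord:
    sample_id: str
    gene: str
    cancer: str
    expression: float
    percentile: float  # in (0, 1], right-continuous ecdf within cohort
    extreme: str  # high / low / none
    gene_role: str  # tsg / oncogene / other


@dataclass
class AseRecord:
    sample_id: str
    variant_key: str
    rna_alt: int
    rna_total: int
    rna_vaf: Optional[float]
    binomial_p: Optional[float]


@dataclass
class SpliceRecord:
    sample_id: str
    variant_key: str
    consensus_reads: int
    cryptic_reads: int
    missplice_fraction: float


def expression_percentile(values: Sequence[float], x: float) -> float:
    """Right-continuous ecdf: the proportion of cohort values <= x."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty expression cohort")
    return float(np.mean(arr <= x))


def flag_extreme(percentile: float, high: float = 0.80, low: float = 0.20) -> str:
    """Extreme-expression flag; boundaries are strict (> high, < low)."""
    if percentile > high:
        return "high"
    if percentile < low:
        return "low"
    return "none"


def ase_test(rna_alt: int, rna_total: int, sample_id: str = "",
             variant_key: str = "") -> AseRecord:
    """RNA VAF with a two-sided exact binomial test against 0.5.

    Zero RNA coverage yields missing VAF and p rather than an error: an
    unexpressed site carries no allele-specific information.
    """
    if rna_alt < 0 or rna_total < 0 or rna_alt > rna_total:
        raise ValidationError(f"invalid RNA counts {rna_alt}/{rna_total}")
    if rna_total == 0:
        return AseRecord(sample_id, variant_key, rna_alt, rna_total, None, None)
    p = float(stats.binomtest(rna_alt, rna_total, 0.5).pvalue)
    return AseRecord(sample_id, variant_key, rna_alt, rna_total,
                     rna_alt / rna_total, p)


def missplice_fraction(consensus_reads: int, cryptic_reads: int) -> float:
    """Fraction of transcripts using the cryptic splice site."""
    if consensus_reads < 0 or cryptic_reads < 0:
        raise ValidationError("negative junction read counts")
    total = consensus_reads + cryptic_reads
    if total == 0:
        raise ValidationError("no junction-spanning reads")
    return cryptic_reads / total


def nmd_competence(ptc_offset_from_last_junction: Optional[int],
                   in_last_exon: bool, boundary_nt: int = 50) -> str:
    """Classify a premature termination codon as NMD competent or escaping.

    The canonical rule: a PTC in the last exon, or within ``boundary_nt``
    nucleotides upstream of the last exon-exon junction, escapes decay.
    """
    if in_last_exon:
        return "escape"
    if ptc_offset_from_last_junction is None or ptc_offset_from_last_junction < 0:
        raise ValidationError("PTC offset must be >= 0 outside the last exon")
    return "competent" if ptc_offset_from_last_junction >= boundary_nt else "escape"


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    pooled.sort(kind="mergesort")
    cdf_a = np.searchsorted(np.sort(a), pooled, side="right") / a.size
    cdf_b = np.searchsorted(np.sort(b), pooled, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


def ks_compare(group_a: Sequence[float], group_b: Sequence[float],
               exact_max_nm: int = 100) -> tuple[float, float]:
    """Two-sample KS test of two percentile distributions.

    For small samples (n*m <= ``exact_max_nm``) the p-value is exact by
    exhaustive enumeration of all label assignments of the pooled values
    (ties handled naturally); larger samples use the asymptotic
    distribution.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    d_obs = _ks_statistic(a, b)
    n, m = a.size, b.size
    if n * m <= exact_max_nm:
        pooled = np.concatenate([a, b])
        idx = range(n + m)
        count = total = 0
        for pick in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(pick)] = True
            d = _ks_statistic(pooled[mask], pooled[~mask])
            total += 1
            if d >= d_obs - 1e-12:
                count += 1
        return d_obs, count / total
    res = stats.ks_2samp(a, b, method="asymp")
    return d_obs, float(res.pvalue)


def annotate_expression(matrix: ExpressionMatrix, samples: list[SampleRecord],
                        carriers: pd.DataFrame,
                        gene_roles: Optional[dict[str, str]] = None,
                        ) -> list[ExpressionRecord]:
    """Percentile and extreme-flag annotation for every carrier.

    Percentiles are computed within the carrier's cancer cohort (all
    samples of that cancer type present in the expression matrix, the
    carrier included) for the affected gene.
    """
    gene_roles = gene_roles or {}
    cancer_of = {s.sample_id: s.cancer_type for s in samples}
    cohorts: dict[str, list[str]] = {}
    for sid in matrix.samples:
        if sid in cancer_of:
            cohorts.setdefault(cancer_of[sid], []).append(sid)

    out = []
    for sample_id in carriers.index:
        if sample_id not in cancer_of or sample_id not in matrix.values.columns:
            continue
        cancer = cancer_of[sample_id]
        cohort_ids = cohorts.get(cancer, [])
        for gene in carriers.columns:
            if not carriers.loc[sample_id, gene] or gene not in matrix.values.index:
                continue
            cohort_values = matrix.values.loc[gene, cohort_ids].to_numpy(dtype=float)
            x = float(matrix.values.loc[gene, sample_id])
            pct = expression_percentile(cohort_values, x)
            out.append(ExpressionRecord(
                sample_id=sample_id, gene=gene, cancer=cancer,
                expression=x, percentile=pct, extreme=flag_extreme(pct),
                gene_role=gene_roles.get(gene, "other")))
    return out


def compare_roles(records: list[ExpressionRecord]) -> Optional[tuple[float, float]]:
    """KS comparison of carrier percentiles, tumor suppressors vs oncogenes.

    Returns (D, p) or None when either role group is empty.
    """
    tsg = [r.percentile for r in records if r.gene_role == "tsg"]
    onc = [r.percentile for r in records if r.gene_role == "oncogene"]
    if not tsg or not onc:
        return None
    return ks_compare(tsg, onc)
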