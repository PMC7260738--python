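"""Somatic second-hit analysis: allelic-imbalance LOH and biallelic events.

A germline predisposing variant can be accompanied by loss of the wild-type
allele in the tumor (loss of heterozygosity, seen as the tumor variant
allele fraction rising above the ~0.5 expected for a heterozygous site) or
by an independent somatic mutation of the same gene (a biallelic event).

LOH is tested per variant with a two-sided exact conditional
(hypergeometric) test on the 2x2 table of tumor alt/ref vs normal alt/ref
read counts; p-values are BH-adjusted across all tested variants.
Categories follow the study's thresholds: significant imbalance (FDR <
0.05) toward the variant allele is LOH, split by whether external
copy-number evidence shows deletion of the wild-type copy; non-significant
variants with FDR < 0.15 or tumor VAF > 0.6 are suggestive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from scipy import stats

from .association import bh_adjust
from .io_formats import VariantObservation


@dataclass
class LohResult:
    """Allelic-imbalance test for one variant in one sample."""

    variant_key: str
    sample_id: str
    gene: str
    normal_vaf: float
    tumor_vaf: Optional[float]
    p_value: float
    fdr: float
    direction: str  # toward_variant / toward_reference / none
    deletion_evidence: bool = False
    category: str = "none"  # loh_with_deletion / other_loh / suggestive / none
    status: str = "ok"


@dataclass
class TwoHitRecord:
    """Per-(carrier, gene) somatic second-hit summary."""

    sample_id: str
    gene: str
    variant_key: str
    loh_category: str
    somatic_hgvs: Optional[str]
    somatic_consequence: Optional[str]
    biallelic: bool


def loh_test(v: VariantObservation) -> LohResult:
    """Exact test of tumor-vs-normal allelic imbalance for one variant.

    Two-sided conditional test on [[tumor_alt, tumor_ref],
    [normal_alt, normal_ref]]; the direction is the sign of
    tumor VAF - normal VAF. Observations without tumor counts come back
    with category "none" and status "no tumor data".
    """
    nan = math.nan
    if v.tumor_depth is None or v.tumor_alt is None or v.tumor_depth == 0:
        return LohResult(variant_key=v.key(), sample_id=v.sample_id, gene=v.gene,
                         normal_vaf=v.normal_vaf, tumor_vaf=None,
                         p_value=nan, fdr=nan, direction="none",
                         status="no tumor data")
    table = [[v.tumor_alt, v.tumor_depth - v.tumor_alt],
             [v.normal_alt, v.normal_depth - v.normal_alt]]
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    tumor_vaf = v.tumor_alt / v.tumor_depth
    delta = tumor_vaf - v.normal_vaf
    direction = "toward_variant" if delta > 0 else (
        "toward_reference" if delta < 0 else "none")
    return LohResult(variant_key=v.key(), sample_id=v.sample_id, gene=v.gene,
                     normal_vaf=v.normal_vaf, tumor_vaf=tumor_vaf,
                     p_value=p, fdr=nan, direction=direction)


def categorize_loh(results: list[LohResult],
                   deletion_evidence: Optional[dict[tuple[str, str], bool]] = None,
                   fdr_significant: float = 0.05,
                   fdr_suggestive: float = 0.15,
                   suggestive_tumor_vaf: float = 0.6) -> list[LohResult]:
    """Attach BH-FDR over all tested variants and assign LOH categories.

    ``deletion_evidence`` maps (sample_id, variant_key) to a wild-type
    copy-loss flag derived upstream from copy-number segments. Calls in
    the significant and suggestive categories additionally require the
    imbalance to point toward the variant allele — loss of the wild-type
    copy is the second-hit mechanism under test. Results are returned in
    input order with ``fdr`` and ``category`` populated.
    """
    deletion_evidence = deletion_evidence or {}
    tested = [r for r in results if math.isfinite(r.p_value)]
    for r, q in zip(tested, bh_adjust([r.p_value for r in tested])):
        r.fdr = q
    for r in results:
        r.deletion_evidence = bool(
            deletion_evidence.get((r.sample_id, r.variant_key), r.deletion_evidence))
        if not math.isfinite(r.p_value) or r.direction != "toward_variant":
            r.category = "none"
            continue
        if r.fdr < fdr_significant:
            r.category = "loh_with_deletion" if r.deletion_evidence else "other_loh"
        elif r.fdr < fdr_suggestive or (r.tumor_vaf is not None
                                        and r.tumor_vaf > suggestive_tumor_vaf):
            r.category = "suggestive"
        else:
            r.category = "none"
    return results


SILENT_CONSEQUENCES = {"synonymous", "silent"}


def find_biallelic(carriers: pd.DataFrame, somatic: pd.DataFrame,
                   carrier_variants: Optional[dict[tuple[str, str], str]] = None,
                   loh_categories: Optional[dict[tuple[str, str], str]] = None,
                   ) -> list[TwoHitRecord]:
    """Pair germline carriers with somatic second mutations of the same gene.

    ``somatic`` needs columns sample_id, gene, consequence and (optionally)
    hgvs. A carrier is biallelic iff the same sample harbors at least one
    non-silent somatic mutation of the same gene; synonymous changes do
    not count. One record is emitted per (carrier sample, gene).
    """
    carrier_variants = carrier_variants or {}
    loh_categories = loh_categories or {}
    by_pair: dict[tuple[str, str], list] = {}
    for _, row in somatic.iterrows():
        if str(row["consequence"]) in SILENT_CONSEQUENCES:
            continue
        by_pair.setdefault((str(row["sample_id"]), str(row["gene"])), []).append(row)

    out = []
    for sample_id in carriers.index:
        for gene in carriers.columns:
            if not carriers.loc[sample_id, gene]:
                continue
            hits = by_pair.get((sample_id, gene), [])
            first = hits[0] if hits else None
            variant_key = carrier_variants.get((sample_id, gene), "")
            out.append(TwoHitRecord(
                sample_id=sample_id, gene=gene,
                variant_key=variant_key,
                loh_category=loh_categories.get((sample_id, variant_key), "none"),
                somatic_hgvs=(str(first.get("hgvs", "")) or None) if first is not None else None,
                somatic_consequence=str(first["consequence"]) if first is not None else None,
                biallelic=bool(hits),
            ))
    return out
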