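"""Sample- and variant-level quality filters and ancestry group assignment.

The filters reproduce the cohort's inclusion rules: samples need >= 60%
genotype concordance between sequencing calls and SNP-array genotypes;
germline variant observations need caller consensus (SNVs from the
varscan/GATK union; indels from >= 2 of 3 callers or high-confidence
pindel-unique calls), >= 5 alt reads at >= 20% alt fraction in the normal,
and rarity (<= 0.05% in every populated reference panel).

Boundary semantics are literal: concordance of exactly 0.60 is kept
("less than 60%" drops), alt fraction of exactly 0.20 is kept ("at least
20%"), and panel AF of exactly 0.0005 is kept ("<= 0.05%").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .io_formats import ANCESTRY_CODES, SampleRecord, VariantObservation, log


@dataclass(frozen=True)
class QcThresholds:
    """Tunable QC cutoffs; defaults are the study's stated rules."""

    min_concordance: float = 0.60
    min_alt_depth: int = 5
    min_alt_fraction: float = 0.20
    max_population_af: float = 0.0005
    pindel_min_depth: int = 30
    pindel_min_vaf: float = 0.20
    admix_secondary_threshold: float = 0.20


def sample_qc(samples: list[SampleRecord],
              t: QcThresholds = QcThresholds(),
              ) -> tuple[list[SampleRecord], list[tuple[SampleRecord, str]]]:
    """Partition samples into kept and (dropped, reason) by concordance.

    A sample with concordance strictly below ``min_concordance`` is dropped
    with reason ``"concordance"``; exactly at the threshold it is kept.
    """
    kept, dropped = [], []
    for s in samples:
        if s.genotype_concordance < t.min_concordance:
            dropped.append((s, "concordance"))
        else:
            kept.append(s)
    if dropped:
        log.info("sample_qc: dropped %d of %d samples (low concordance)",
                 len(dropped), len(samples))
    return kept, dropped


def assign_analysis_group(fractions: dict[str, float],
                          t: QcThresholds = QcThresholds()) -> tuple[str, str]:
    """Derive (consensus_group, analysis_group) from admixture fractions.

    The consensus group is the primary (largest-fraction) ancestry, with an
    ``_admix`` suffix when the second-largest fraction exceeds the
    admixture threshold. Admixed samples are merged to their nearest group
    for analysis, so the analysis group is always the primary base code.
    Ties on the primary ancestry break by the fixed code order
    afr, eur, eas, sas, amr.
    """
    ordered = sorted(
        ANCESTRY_CODES,
        key=lambda c: (-fractions.get(c, 0.0), ANCESTRY_CODES.index(c)),
    )
    primary, secondary = ordered[0], ordered[1]
    if fractions.get(primary, 0.0) == fractions.get(secondary, 0.0):
        log.debug("ancestry tie between %s and %s broken by code order",
                  primary, secondary)
    consensus = primary
    if fractions.get(secondary, 0.0) > t.admix_secondary_threshold:
        consensus = f"{primary}_admix"
    return consensus, primary


def caller_consensus(v: VariantObservation,
                     t: QcThresholds = QcThresholds()) -> tuple[bool, Optional[str]]:
    """Caller-consensus keep/drop rule; returns (keep, drop_reason).

    SNVs: union of varscan and GATK calls (any one suffices). Indels:
    >= 2 of the 3 callers, or pindel-unique with >= 30x normal coverage
    and >= 20% normal VAF.
    """
    if not v.caller_set:
        return False, "no_caller"
    if v.variant_class == "snv":
        if v.caller_set & {"varscan", "gatk"}:
            return True, None
        return False, "caller_consensus"
    # indel
    if len(v.caller_set) >= 2:
        return True, None
    if v.caller_set == {"pindel"}:
        if (v.normal_depth >= t.pindel_min_depth
                and v.normal_depth > 0
                and v.normal_alt / v.normal_depth >= t.pindel_min_vaf):
            return True, None
        return False, "pindel_low_confidence"
    return False, "caller_consensus"


def variant_filters(v: VariantObservation,
                    t: QcThresholds = QcThresholds()) -> tuple[bool, Optional[str]]:
    """Read-support and rarity filters; returns (keep, drop_reason).

    Keep iff normal alt reads >= ``min_alt_depth``, normal alt fraction
    >= ``min_alt_fraction``, and every populated panel AF
    <= ``max_population_af``. The first failing rule (coverage, alt depth,
    alt fraction, rarity — in that order) is the single primary reason.
    """
    if v.normal_depth == 0:
        return False, "no coverage"
    if v.normal_alt < t.min_alt_depth:
        return False, "alt_depth"
    if v.normal_alt / v.normal_depth < t.min_alt_fraction:
        return False, "alt_fraction"
    if any(af > t.max_population_af for af in v.population_af.values()):
        return False, "common"
    return True, None


def apply_variant_qc(variants: list[VariantObservation],
                     t: QcThresholds = QcThresholds(),
                     ) -> tuple[list[VariantObservation],
                                list[tuple[VariantObservation, str]]]:
    """Run caller consensus then read/rarity filters over a variant list.

    The two filters are independent predicates, so the composition is
    order-independent; this helper fixes the reporting order so each
    dropped observation carries exactly one primary reason.
    """
    kept, dropped = [], []
    for v in variants:
        ok, reason = caller_consensus(v, t)
        if ok:
            ok, reason = variant_filters(v, t)
        if ok:
            kept.append(v)
        else:
            dropped.append((v, reason))
    if dropped:
        counts: dict[str, int] = {}
        for _, reason in dropped:
            counts[reason] = counts.get(reason, 0) + 1
        log.info("variant QC: dropped %d of %d observations (%s)",
                 len(dropped), len(variants),
                 ", ".join(f"{k}={n}" for k, n in sorted(counts.items())))
    return kept, dropped
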