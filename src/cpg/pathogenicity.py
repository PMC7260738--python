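"""Point-based germline variant classification (ACMG/AMP-style scoring).

Each variant arrives with a set of pre-assigned evidence tags. Pathogenic
evidence adds points, benign evidence subtracts them, and the summed score
plus the variant's ClinVar review status determines the class:

* ``pathogenic`` — reviewed-pathogenic in ClinVar (conflicting
  interpretations do not qualify), regardless of score;
* ``likely_pathogenic`` — score strictly greater than 8;
* ``uncertain`` — everything else.

The default points table encodes the stated weights: loss-of-function in a
dominant-mechanism gene (PVS1) +8, the recessive counterpart (PSC1) +4,
same-peptide-change-as-known-pathogenic (PS1) +7; every other pathogenic
module contributes at most +2 and every benign module -2 (the benign
magnitude is a configurable package default). The table is fully
overridable through configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

CLINVAR_STATUSES = ("pathogenic_reviewed", "conflicting", "other", "absent")

#: 12 pathogenic + 4 benign evidence modules with default point weights.
DEFAULT_POINTS: dict[str, int] = {
    "PVS1": 8,   # truncation, dominant loss-of-function mechanism
    "PSC1": 4,   # truncation, recessive mechanism
    "PS1": 7,    # same peptide change as an established pathogenic variant
    "PS2": 2, "PS3": 2, "PS4": 2,
    "PM1": 2, "PM2": 2, "PM4": 2, "PM5": 2, "PM6": 2,
    "PP2": 2,
    "BA1": -2, "BSC1": -2, "BP1": -2, "BP2": -2,
}


class ConfigurationError(ValueError):
    """An evidence tag or points table violates the scoring contract."""


def validate_points_table(table: Mapping[str, int]) -> None:
    """Check sign and magnitude constraints on a points table.

    Pathogenic-type labels must be positive, benign-type negative, and
    every label other than PVS1/PSC1/PS1 is capped at |2| points.
    """
    for label, points in table.items():
        if points == 0:
            raise ConfigurationError(f"label {label!r} has 0 points; use a signed weight")
        if label not in ("PVS1", "PSC1", "PS1") and abs(points) > 2:
            raise ConfigurationError(
                f"label {label!r} has |points|={abs(points)} > 2; only "
                "PVS1/PSC1/PS1 may exceed the 2-point cap")


@dataclass
class EvidenceAssignment:
    """Pre-assigned evidence for one variant in one sample."""

    variant_key: str
    tags: frozenset[str]
    clinvar_status: str = "absent"
    sample_id: str = ""
    gene: str = ""
    points: dict[str, int] = field(default_factory=dict)  # per-label overrides

    def __post_init__(self) -> None:
        if self.clinvar_status not in CLINVAR_STATUSES:
            raise ConfigurationError(
                f"unknown ClinVar status {self.clinvar_status!r}")


@dataclass
class ClassifiedVariant:
    """A variant with its integer evidence score and class label."""

    variant_key: str
    sample_id: str
    gene: str
    score: int
    classification: str  # pathogenic / likely_pathogenic / uncertain

    @property
    def is_predisposing(self) -> bool:
        """Pathogenic and likely-pathogenic variants collapse to carriers."""
        return self.classification in ("pathogenic", "likely_pathogenic")


def score_variant(e: EvidenceAssignment,
                  table: Mapping[str, int] | None = None) -> int:
    """Sum configured points over the assigned evidence tags.

    Per-assignment point overrides (``e.points``) take precedence over the
    table. An unknown tag is a configuration error naming the tag.
    """
    table = DEFAULT_POINTS if table is None else table
    validate_points_table({**table, **e.points})
    score = 0
    for tag in e.tags:
        if tag in e.points:
            score += e.points[tag]
        elif tag in table:
            score += table[tag]
        else:
            raise ConfigurationError(f"evidence tag {tag!r} not in points table")
    return score


def classify_variant(score: int, clinvar_status: str = "absent",
                     likely_pathogenic_threshold: int = 8) -> str:
    """Map (score, ClinVar status) to a class label.

    Reviewed-pathogenic ClinVar status alone grants ``pathogenic``;
    conflicting interpretations do not. Otherwise a score strictly above
    the threshold (default 8) gives ``likely_pathogenic``.
    """
    if clinvar_status == "pathogenic_reviewed":
        return "pathogenic"
    if score > likely_pathogenic_threshold:
        return "likely_pathogenic"
    return "uncertain"


def classify_variants(evidence: list[EvidenceAssignment],
                      table: Mapping[str, int] | None = None) -> list[ClassifiedVariant]:
    """Score and classify a batch of evidence assignments."""
    out = []
    for e in evidence:
        score = score_variant(e, table)
        out.append(ClassifiedVariant(
            variant_key=e.variant_key,
            sample_id=e.sample_id,
            gene=e.gene,
            score=score,
            classification=classify_variant(score, e.clinvar_status),
        ))
    return out


def read_evidence_table(path) -> list[EvidenceAssignment]:
    """Read a TSV of pre-assigned evidence (variant_key, sample_id, gene,
    tags as comma-joined labels, clinvar_status)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        out.append(EvidenceAssignment(
            variant_key=row["variant_key"],
            tags=frozenset(t for t in row["tags"].split(",") if t),
            clinvar_status=row["clinvar_status"] or "absent",
            sample_id=row.get("sample_id", ""),
            gene=row.get("gene", ""),
        ))
    return out
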