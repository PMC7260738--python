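"""Domain record types and tabular I/O for the predisposition pipeline.

Everything downstream operates on the flat record types defined here:
cohort members (:class:`SampleRecord`), per-sample germline variant
observations with paired normal/tumor read counts
(:class:`VariantObservation`), and a gene x sample expression matrix.
Readers accept tab-separated tables and, for germline variants, VCF 4.x;
writers emit deterministic TSV (fixed column order, sorted rows, floats at
6 significant digits) so that repeated runs are byte-identical.

Coordinates are 1-based (VCF convention) throughout. Missing covariates are
preserved at load time; they are only dropped, with logging, where a model
actually requires them.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import typing
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

log = logging.getLogger("cpg")

#: The five base ancestry codes, in fixed tie-break order.
ANCESTRY_CODES = ("afr", "eur", "eas", "sas", "amr")

CONSEQUENCES = ("missense", "nonsense", "frameshift", "splice_site", "other")
CALLERS = ("varscan", "gatk", "pindel")


class FormatError(ValueError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(ValueError):
    """A parsed value violates a record invariant."""


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger once, idempotently."""
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SampleRecord:
    """One cohort member with covariates and ancestry assignment.

    ``ancestry_fractions`` maps each of the five base codes to a global
    admixture fraction (summing to 1). ``consensus_group`` is the primary
    ancestry, suffixed ``_admix`` when the secondary fraction exceeds the
    admixture threshold; ``analysis_group`` is always the primary base code
    (admixed samples are analyzed with their nearest ancestry group).
    """

    sample_id: str
    cancer_type: str
    age_years: Optional[float]
    sex: Optional[str]  # "male" / "female" / None
    ancestry_fractions: dict[str, float]
    consensus_group: str
    analysis_group: str
    pc1: float
    pc2: float
    genotype_concordance: float
    qc_pass: bool = True

    def __post_init__(self) -> None:
        total = sum(self.ancestry_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValidationError(
                f"sample {self.sample_id}: ancestry fractions sum to {total:.6f}, not 1"
            )
        for code, frac in self.ancestry_fractions.items():
            if not 0.0 <= frac <= 1.0 + 1e-12:
                raise ValidationError(f"sample {self.sample_id}: fraction {code}={frac}")
        if self.analysis_group not in ANCESTRY_CODES:
            raise ValidationError(
                f"sample {self.sample_id}: analysis_group {self.analysis_group!r}"
            )


@dataclass
class VariantObservation:
    """One germline variant observed in one sample, with read support.

    Read counts are from the paired normal and tumor sequencing of the same
    individual; ``population_af`` maps reference-panel names (e.g. ``1kg``,
    ``exac``) to allele frequencies. Panels absent from the input default to
    0 and are flagged ``af_imputed`` — absence from a panel is treated as
    evidence of rarity, so the rarity filter stays conservative in the keep
    direction.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    hgvs: str
    caller_set: frozenset[str]
    variant_class: str  # "snv" / "indel"
    normal_depth: int
    normal_alt: int
    tumor_depth: Optional[int]
    tumor_alt: Optional[int]
    population_af: dict[str, float] = field(default_factory=dict)
    af_imputed: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.key()}: position must be >= 1")
        if not self.ref or not self.alt:
            raise ValidationError(f"{self.key()}: empty allele")
        if not 0 <= self.normal_alt <= self.normal_depth:
            raise ValidationError(
                f"{self.key()} in {self.sample_id}: normal_alt {self.normal_alt} "
                f"outside [0, depth={self.normal_depth}]"
            )
        if self.tumor_depth is not None and self.tumor_alt is not None:
            if not 0 <= self.tumor_alt <= self.tumor_depth:
                raise ValidationError(
                    f"{self.key()} in {self.sample_id}: tumor_alt {self.tumor_alt} "
                    f"outside [0, depth={self.tumor_depth}]"
                )

    def key(self) -> str:
        """Variant identity ``chrom:pos:ref:alt`` (shared across carriers)."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else float("nan")

    @property
    def tumor_vaf(self) -> Optional[float]:
        if self.tumor_depth is None or self.tumor_alt is None or self.tumor_depth == 0:
            return None
        return self.tumor_alt / self.tumor_depth


class ExpressionMatrix:
    """Non-negative normalized expression, genes x samples.

    Thin wrapper over a pandas DataFrame that enforces unique gene and
    sample keys and non-negative values.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            raise ValidationError("duplicated gene keys in expression matrix")
        if values.columns.duplicated().any():
            raise ValidationError("duplicated sample keys in expression matrix")
        if (values.to_numpy() < 0).any():
            raise ValidationError("negative expression values")
        self.values = values

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self.values.equals(other.values)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = (
    "sample_id", "cancer_type", "age_years", "sex",
    "afr", "eur", "eas", "sas", "amr",
    "pc1", "pc2", "genotype_concordance",
)


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read a tab-separated sample sheet into :class:`SampleRecord` objects.

    Ancestry fractions are renormalized when their sum falls in
    [0.99, 1.01]; outside that tolerance the row is rejected. Missing age
    or sex values are preserved as missing. Consensus and analysis ancestry
    groups are (re)derived from the fractions.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet {path}: missing required column(s) {missing}")

    from .germline_qc import QcThresholds, assign_analysis_group

    thresholds = QcThresholds()
    records: list[SampleRecord] = []
    for _, row in df.iterrows():
        fractions = {code: float(row[code]) for code in ANCESTRY_CODES}
        total = sum(fractions.values())
        if not 0.99 <= total <= 1.01:
            raise ValidationError(
                f"sample {row['sample_id']}: ancestry fractions sum to {total:.4f}"
            )
        fractions = {c: v / total for c, v in fractions.items()}
        consensus, analysis = assign_analysis_group(fractions, thresholds)
        age = None if pd.isna(row["age_years"]) else float(row["age_years"])
        sex = None if pd.isna(row["sex"]) or row["sex"] == "" else str(row["sex"])
        records.append(SampleRecord(
            sample_id=str(row["sample_id"]),
            cancer_type=str(row["cancer_type"]),
            age_years=age,
            sex=sex,
            ancestry_fractions=fractions,
            consensus_group=consensus,
            analysis_group=analysis,
            pc1=float(row["pc1"]),
            pc2=float(row["pc2"]),
            genotype_concordance=float(row["genotype_concordance"]),
            qc_pass=bool(row["qc_pass"]) if "qc_pass" in df.columns else True,
        ))
    return records


def write_sample_sheet(samples: list[SampleRecord], path: str | Path) -> None:
    rows = []
    for s in sorted(samples, key=lambda s: s.sample_id):
        row = {
            "sample_id": s.sample_id,
            "cancer_type": s.cancer_type,
            "age_years": s.age_years,
            "sex": s.sex,
            **{c: s.ancestry_fractions.get(c, 0.0) for c in ANCESTRY_CODES},
            "consensus_group": s.consensus_group,
            "analysis_group": s.analysis_group,
            "pc1": s.pc1,
            "pc2": s.pc2,
            "genotype_concordance": s.genotype_concordance,
            "qc_pass": s.qc_pass,
        }
        rows.append(row)
    _write_tsv(pd.DataFrame(rows, columns=list(rows[0]) if rows else
                            list(_SAMPLE_COLUMNS) + ["consensus_group", "analysis_group", "qc_pass"]),
               path)


# ---------------------------------------------------------------------------
# Variant tables (MAF-like TSV and VCF)
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = (
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence", "hgvs",
    "callers", "variant_class", "normal_depth", "normal_alt",
    "tumor_depth", "tumor_alt",
)


def read_variant_table(path: str | Path, dialect: str = "maf_like") -> list[VariantObservation]:
    """Read per-sample germline variant observations.

    dialect "maf_like": tab-separated with the count columns named
    explicitly plus any number of ``af_<panel>`` columns.
    dialect "vcf": VCF 4.x with one record per (sample, variant)
    observation carried in INFO fields (parsed with cyvcf2).
    """
    if dialect == "maf_like":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown variant-table dialect {dialect!r}")


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return int(value)


def _read_variants_tsv(path: str | Path) -> list[VariantObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant table {path}: missing required column(s) {missing}")
    af_cols = [c for c in df.columns if c.startswith("af_") and c != "af_imputed"]

    out = []
    for _, row in df.iterrows():
        pop_af = {}
        imputed = False
        for col in af_cols:
            panel = col[3:]
            if pd.isna(row[col]):
                pop_af[panel] = 0.0
                imputed = True
            else:
                pop_af[panel] = float(row[col])
        if not af_cols:
            imputed = True
        out.append(VariantObservation(
            sample_id=str(row["sample_id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            gene=str(row["gene"]),
            consequence=str(row["consequence"]),
            hgvs=str(row["hgvs"]),
            caller_set=frozenset(str(row["callers"]).split(",")) - {"", "nan"},
            variant_class=str(row["variant_class"]),
            normal_depth=int(row["normal_depth"]),
            normal_alt=int(row["normal_alt"]),
            tumor_depth=_opt_int(row["tumor_depth"]),
            tumor_alt=_opt_int(row["tumor_alt"]),
            population_af=pop_af,
            af_imputed=imputed,
        ))
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SID,Number=1,Type=String,Description="Sample id of this observation">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=HGVS,Number=1,Type=String,Description="HGVS label">
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Callers reporting the variant">
##INFO=<ID=VCLASS,Number=1,Type=String,Description="snv or indel">
##INFO=<ID=NDP,Number=1,Type=Integer,Description="Normal depth">
##INFO=<ID=NALT,Number=1,Type=Integer,Description="Normal alt read count">
##INFO=<ID=TDP,Number=1,Type=Integer,Description="Tumor depth">
##INFO=<ID=TALT,Number=1,Type=Integer,Description="Tumor alt read count">
##INFO=<ID=PAF,Number=.,Type=String,Description="Population AFs as panel:af">
##INFO=<ID=AFIMP,Number=0,Type=Flag,Description="Population AF imputed as 0">
"""


def _read_variants_vcf(path: str | Path) -> list[VariantObservation]:
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        paf = {}
        if "PAF" in info:
            for item in str(info["PAF"]).split(","):
                panel, _, value = item.partition(":")
                paf[panel] = float(value)
        callers = frozenset(str(info.get("CALLERS", "")).split(",")) - {""}
        out.append(VariantObservation(
            sample_id=str(info["SID"]),
            chrom=rec.CHROM,
            pos=rec.POS,
            ref=rec.REF,
            alt=rec.ALT[0],
            gene=str(info.get("GENE", "")),
            consequence=str(info.get("CSQ", "other")),
            hgvs=str(info.get("HGVS", "")),
            caller_set=callers,
            variant_class=str(info.get("VCLASS", "snv")),
            normal_depth=int(info["NDP"]),
            normal_alt=int(info["NALT"]),
            tumor_depth=_opt_int(info.get("TDP")),
            tumor_alt=_opt_int(info.get("TALT")),
            population_af=paf,
            af_imputed="AFIMP" in info,
        ))
    return out


def write_variant_table(variants: list[VariantObservation], path: str | Path,
                        dialect: str = "maf_like") -> None:
    """Write observations as MAF-like TSV or single-allele VCF 4.2 text."""
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt, v.sample_id))
    if dialect == "maf_like":
        panels = sorted({p for v in variants for p in v.population_af})
        rows = []
        for v in ordered:
            row = {c: getattr(v, c) for c in
                   ("sample_id", "chrom", "pos", "ref", "alt", "gene",
                    "consequence", "hgvs")}
            row["callers"] = ",".join(sorted(v.caller_set))
            row["variant_class"] = v.variant_class
            row["normal_depth"] = v.normal_depth
            row["normal_alt"] = v.normal_alt
            row["tumor_depth"] = v.tumor_depth
            row["tumor_alt"] = v.tumor_alt
            for p in panels:
                row[f"af_{p}"] = v.population_af.get(p)  # absent -> empty cell
            rows.append(row)
        cols = list(_VARIANT_COLUMNS) + [f"af_{p}" for p in panels]
        _write_tsv(pd.DataFrame(rows, columns=cols), path)
    elif dialect == "vcf":
        contigs = sorted({v.chrom for v in ordered})
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for v in ordered:
                info = [
                    f"SID={v.sample_id}", f"GENE={v.gene}", f"CSQ={v.consequence}",
                    f"HGVS={v.hgvs}", f"CALLERS={','.join(sorted(v.caller_set))}",
                    f"VCLASS={v.variant_class}",
                    f"NDP={v.normal_depth}", f"NALT={v.normal_alt}",
                ]
                if v.tumor_depth is not None:
                    info.append(f"TDP={v.tumor_depth}")
                if v.tumor_alt is not None:
                    info.append(f"TALT={v.tumor_alt}")
                if v.population_af:
                    paf = ",".join(f"{p}:{_fmt(a)}" for p, a in sorted(v.population_af.items()))
                    info.append(f"PAF={paf}")
                if v.af_imputed:
                    info.append("AFIMP")
                fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                         + ";".join(info) + "\n")
    else:
        raise ValueError(f"unknown variant-table dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.sort_index()
    df = df[sorted(df.columns)]
    df = df.map(_fmt)
    df.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Generic result writer/reader
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    """Render a value for TSV: floats at 6 significant digits, None empty."""
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        if math.isinf(value):
            return "inf" if value > 0 else "-inf"
        return f"{value:.6g}"
    if isinstance(value, frozenset):
        return ",".join(sorted(value))
    return str(value)


_SORT_PRIORITY = ("ancestry", "cancer", "gene", "sample_id", "sample", "variant_key")


def write_results(records: list, path: str | Path, record_type: type | None = None) -> None:
    """Write a homogeneous list of result dataclasses as deterministic TSV.

    Column order follows field declaration order; rows sort by ancestry,
    cancer, gene, then record ids, then the full rendered row, so identical
    inputs always give byte-identical files. An empty list needs
    ``record_type`` to emit the header.
    """
    if not records and record_type is None:
        raise ValueError("empty record list requires record_type for the header")
    cls = record_type or type(records[0])
    if not dataclasses.is_dataclass(cls):
        raise TypeError(f"{cls} is not a dataclass record type")
    names = [f.name for f in dataclasses.fields(cls)]
    rendered = []
    for rec in records:
        if type(rec) is not cls:
            raise ValueError("heterogeneous record list")
        rendered.append({n: _fmt(getattr(rec, n)) for n in names})
    keys = [n for n in _SORT_PRIORITY if n in names]
    rendered.sort(key=lambda r: tuple(r[k] for k in keys) + tuple(r[n] for n in names))
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for row in rendered:
            fh.write("\t".join(row[n] for n in names) + "\n")


def _parse_field(text: str, annotation) -> object:
    origin = typing.get_origin(annotation)
    if origin is typing.Union:  # Optional[...]
        args = [a for a in typing.get_args(annotation) if a is not type(None)]
        if text == "":
            return None
        return _parse_field(text, args[0])
    if annotation is float:
        return float(text)
    if annotation is int:
        return int(text)
    if annotation is bool:
        return text == "True"
    if origin in (frozenset, set):
        return frozenset(t for t in text.split(",") if t)
    return text


def read_results(path: str | Path, record_type: type) -> list:
    """Inverse of :func:`write_results` for flat dataclass records."""
    hints = typing.get_type_hints(record_type)
    names = [f.name for f in dataclasses.fields(record_type)]
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != names:
            raise FormatError(f"{path}: header does not match {record_type.__name__}")
        for line in fh:
            values = line.rstrip("\n").split("\t")
            kwargs = {n: _parse_field(v, hints[n]) for n, v in zip(names, values)}
            out.append(record_type(**kwargs))
    return out


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV dump: 6 significant digits, stable row order."""
    df = df.copy()
    for col in df.columns:
        df[col] = df[col].map(_fmt)
    df.to_csv(path, sep="\t", index=False)
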