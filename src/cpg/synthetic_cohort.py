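"""Synthetic multi-ancestry cohort generator with planted effects.

Generates everything the pipeline consumes — sample sheet, per-sample
germline variant observations with paired normal/tumor read counts,
evidence tags, somatic mutations, an expression matrix and RNA counts —
plus a ground-truth record, so every downstream stage can be tested for
parameter recovery without any external data.

The generative model, stage by stage:

* cohort layout: configurable (ancestry, cancer) cell sizes; ages from a
  Normal(60, 10) truncated to [20, 90]; sex Bernoulli(0.5); ancestry
  admixture fractions with a configurable share of admixed samples
  (secondary fraction > 20%); genotype PCs drawn around ancestry-specific
  centers, which deliberately confounds ancestry with the covariates the
  regression must correct for;
* carrier status per (sample, gene) from a logistic model: the planted
  log odds ratio applies to the case cancer within the planted ancestry,
  on top of a baseline carrier frequency; carriers are heterozygous with
  one pathogenic variant each (rare-variant regime);
* read counts: sequencing depth Poisson around the configured means;
  normal alt reads Binomial(depth, 0.5); tumor alt reads
  Binomial(depth, 0.5), or Binomial(depth, loh_tumor_vaf) when the tumor
  lost the wild-type allele (per-carrier LOH probability);
* somatic second hits: carriers gain a non-silent somatic mutation of the
  same gene with probability ``biallelic_prob``; background somatic
  mutations (including synonymous ones) are sprinkled across the cohort;
* expression: per-gene log-normal; carriers of tumor-suppressor genes are
  multiplied by the suppression factor, oncogene carriers by its inverse;
* RNA counts: truncating variants without LOH are transcribed at the
  degraded-allele RNA VAF (allele-specific expression), LOH variants at
  the LOH VAF, everything else at 0.5; splice variants also get
  consensus/cryptic junction read counts.

Identical seeds give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .germline_qc import QcThresholds, assign_analysis_group
from .io_formats import (ANCESTRY_CODES, ExpressionMatrix, SampleRecord,
                         VariantObservation, write_expression_matrix,
                         write_sample_sheet, write_variant_table, _write_tsv)
from .pathogenicity import EvidenceAssignment

TRUNCATING = ("frameshift", "nonsense", "splice_site")

_PC_CENTERS = {
    "afr": (0.080, 0.020), "eur": (-0.040, 0.050), "eas": (-0.020, -0.090),
    "sas": (0.000, -0.030), "amr": (0.030, -0.010),
}


class ConfigError(ValueError):
    """A simulation configuration violates its own constraints."""


def load_gene_table() -> pd.DataFrame:
    """The bundled curated predisposition gene list (synthetic fixture).

    Columns: gene, role (tsg/oncogene), chrom, base_pos. A stand-in for a
    user-supplied curated gene list; fully overridable.
    """
    path = resources.files("cpg.data") / "cpg_genes.tsv"
    return pd.read_csv(str(path), sep="\t", dtype={"chrom": str})


def default_cohort_sizes() -> dict[tuple[str, str], int]:
    """A scaled-down multi-ancestry, multi-cancer pan-cancer cohort layout."""
    return {
        ("eur", "BRCA"): 300, ("eur", "LUSC"): 150, ("eur", "OV"): 100,
        ("eur", "PRAD"): 150, ("eur", "KIRC"): 100,
        ("afr", "BRCA"): 60, ("afr", "LUSC"): 30, ("afr", "OV"): 40,
        ("afr", "PRAD"): 50, ("afr", "KIRC"): 30,
        ("eas", "LIHC"): 80, ("eas", "STAD"): 60,
    }


@dataclass(frozen=True)
class PlantedEffect:
    """A true (ancestry, cancer, gene) association to recover downstream."""

    ancestry: str
    cancer: str
    gene: str
    odds_ratio: float
    baseline_carrier_freq: float


@dataclass
class SimulationConfig:
    seed: int = 0
    cohort_sizes: dict[tuple[str, str], int] = field(default_factory=default_cohort_sizes)
    planted_effects: list[PlantedEffect] = field(default_factory=lambda: [
        PlantedEffect("afr", "LUSC", "BRCA2", odds_ratio=10.0,
                      baseline_carrier_freq=0.005),
        PlantedEffect("eas", "STAD", "BRIP1", odds_ratio=8.0,
                      baseline_carrier_freq=0.005),
    ])
    background_carrier_freq: float = 0.002
    genes: Optional[tuple[str, ...]] = None  # default: bundled gene list
    normal_depth_mean: float = 60.0
    tumor_depth_mean: float = 60.0
    loh_prob: float = 0.5
    loh_tumor_vaf: float = 0.8
    mutant_allele_loss: bool = False  # LOH removes the mutant, not wild-type, allele
    biallelic_prob: float = 0.1
    expression_effect: float = 0.3   # multiplicative suppression for TSG carriers
    ase_rna_vaf: float = 0.1         # RNA VAF of a degraded mutant allele
    rna_depth_mean: float = 50.0
    missplice_mean_fraction: float = 0.28
    admix_fraction: float = 0.1
    qc_fail_fraction: float = 0.02   # samples planted below the concordance cutoff
    missing_covariate_fraction: float = 0.02
    decoy_fraction: float = 0.1      # extra non-pathogenic observations per sample

    def validate(self) -> None:
        for name in ("loh_prob", "loh_tumor_vaf", "biallelic_prob",
                     "expression_effect", "ase_rna_vaf", "admix_fraction",
                     "background_carrier_freq", "qc_fail_fraction",
                     "missing_covariate_fraction", "missplice_mean_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        for (ancestry, cancer), n in self.cohort_sizes.items():
            if n < 0:
                raise ConfigError(f"cohort size {ancestry}/{cancer} is negative")
        for eff in self.planted_effects:
            if eff.odds_ratio <= 0:
                raise ConfigError(f"planted OR must be > 0 ({eff})")
            if not 0 < eff.baseline_carrier_freq < 1:
                raise ConfigError(f"baseline carrier frequency out of range ({eff})")
            if self.cohort_sizes.get((eff.ancestry, eff.cancer), 0) == 0:
                raise ConfigError(
                    f"planted effect {eff.ancestry}/{eff.cancer}/{eff.gene} targets "
                    "an empty cohort cell")


@dataclass
class SyntheticTruth:
    """Ground truth backing every emitted table."""

    carrier_matrix: pd.DataFrame          # samples x genes, bool
    variant_truth: pd.DataFrame           # per emitted observation
    gene_or: pd.DataFrame                 # (ancestry, cancer, gene) true OR


@dataclass
class SimulatedCohort:
    samples: list[SampleRecord]
    variants: list[VariantObservation]
    evidence: list[EvidenceAssignment]
    somatic: pd.DataFrame
    expression: ExpressionMatrix
    rna_counts: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Stage 1: samples
# ---------------------------------------------------------------------------

def _draw_samples(config: SimulationConfig, rng: np.random.Generator,
                  thresholds: QcThresholds) -> list[SampleRecord]:
    samples: list[SampleRecord] = []
    counter = 0
    for (ancestry, cancer) in sorted(config.cohort_sizes):
        n = config.cohort_sizes[(ancestry, cancer)]
        if n == 0:
            continue
        ages = truncnorm.rvs((20 - 60) / 10, (90 - 60) / 10, loc=60, scale=10,
                             size=n, random_state=rng)
        sexes = rng.random(n) < 0.5
        admixed = rng.random(n) < config.admix_fraction
        secondary_frac = np.where(admixed,
                                  rng.uniform(0.21, 0.45, n),
                                  rng.uniform(0.0, 0.15, n))
        cx, cy = _PC_CENTERS[ancestry]
        pc1 = rng.normal(cx, 0.01, n)
        pc2 = rng.normal(cy, 0.01, n)
        concordance = np.minimum(1.0, 1.0 - np.abs(rng.normal(0.0, 0.01, n)))
        qc_fail = rng.random(n) < config.qc_fail_fraction
        concordance = np.where(qc_fail, rng.uniform(0.30, 0.55, n), concordance)
        age_missing = rng.random(n) < config.missing_covariate_fraction
        others = [c for c in ANCESTRY_CODES if c != ancestry]
        secondary_idx = rng.integers(0, len(others), n)
        for i in range(n):
            counter += 1
            fractions = {c: 0.0 for c in ANCESTRY_CODES}
            fractions[ancestry] = 1.0 - secondary_frac[i]
            fractions[others[secondary_idx[i]]] = secondary_frac[i]
            consensus, analysis = assign_analysis_group(fractions, thresholds)
            samples.append(SampleRecord(
                sample_id=f"S{counter:05d}",
                cancer_type=cancer,
                age_years=None if age_missing[i] else round(float(ages[i]), 1),
                sex="male" if sexes[i] else "female",
                ancestry_fractions=fractions,
                consensus_group=consensus,
                analysis_group=analysis,
                pc1=float(pc1[i]), pc2=float(pc2[i]),
                genotype_concordance=float(concordance[i]),
            ))
    return samples


# ---------------------------------------------------------------------------
# Stage 2: carrier status
# ---------------------------------------------------------------------------

def draw_carrier_status(config: SimulationConfig, samples: list[SampleRecord],
                        rng: np.random.Generator,
                        genes: list[str]) -> pd.DataFrame:
    """Draw the true carrier matrix from the logistic planted-effect model.

    For a sample of ancestry a with cancer c, the carrier probability for
    gene g is expit(logit(baseline) + log(OR) * 1[(a, c, g) planted]),
    where baseline is the planted effect's baseline within its ancestry
    and the background frequency elsewhere. Exposed separately so
    calibration tests can exercise the carrier model at scale.
    """
    by_gene_anc = {(e.ancestry, e.gene): e for e in config.planted_effects}
    sample_ids = [s.sample_id for s in samples]
    groups = np.array([s.analysis_group for s in samples])
    cancers = np.array([s.cancer_type for s in samples])
    matrix = pd.DataFrame(False, index=sample_ids, columns=genes, dtype=bool)
    for gene in genes:
        probs = np.full(len(samples), config.background_carrier_freq)
        for (ancestry, g), eff in by_gene_anc.items():
            if g != gene:
                continue
            in_ancestry = groups == ancestry
            probs[in_ancestry] = eff.baseline_carrier_freq
            is_case = in_ancestry & (cancers == eff.cancer)
            probs[is_case] = expit(logit(eff.baseline_carrier_freq)
                                   + math.log(eff.odds_ratio))
        matrix[gene] = rng.random(len(samples)) < probs
    return matrix


# ---------------------------------------------------------------------------
# Stage 3-6: variants, somatic hits, expression, RNA
# ---------------------------------------------------------------------------

def _poisson_at_least(rng: np.random.Generator, mean: float, floor: int = 10) -> int:
    return int(max(floor, rng.poisson(mean)))


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Run the full generator; see the module docstring for the model."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    thresholds = QcThresholds()
    gene_table = load_gene_table()
    if config.genes is not None:
        gene_table = gene_table[gene_table["gene"].isin(config.genes)]
        missing = set(config.genes) - set(gene_table["gene"])
        for g in sorted(missing):  # unknown genes default to TSG on chr1
            gene_table = pd.concat([gene_table, pd.DataFrame(
                [{"gene": g, "role": "tsg", "chrom": "1",
                  "base_pos": 1_000_000 + 10_000 * len(gene_table)}])],
                ignore_index=True)
    gene_table = gene_table.sort_values("gene").reset_index(drop=True)
    genes = gene_table["gene"].tolist()
    roles = dict(zip(gene_table["gene"], gene_table["role"]))
    chrom_of = dict(zip(gene_table["gene"], gene_table["chrom"]))
    pos_of = dict(zip(gene_table["gene"], gene_table["base_pos"]))

    samples = _draw_samples(config, rng, thresholds)
    carrier_matrix = draw_carrier_status(config, samples, rng, genes)

    variants: list[VariantObservation] = []
    evidence: list[EvidenceAssignment] = []
    truth_rows: list[dict] = []
    somatic_rows: list[dict] = []
    rna_rows: list[dict] = []

    csq_choices = np.array(["frameshift", "nonsense", "splice_site", "missense"])
    csq_probs = np.array([0.4, 0.3, 0.1, 0.2])

    for gene in genes:
        carrier_ids = [sid for sid in carrier_matrix.index if carrier_matrix.loc[sid, gene]]
        n_alleles = max(2, (len(carrier_ids) + 1) // 2)  # partial variant recurrence
        for sid in carrier_ids:
            csq = str(rng.choice(csq_choices, p=csq_probs))
            allele_idx = int(rng.integers(0, n_alleles))
            pos = int(pos_of[gene]) + allele_idx * 3
            if csq == "frameshift":
                ref, alt, vclass = "AT", "A", "indel"
            else:
                ref, alt, vclass = "C", "T", "snv"
            if vclass == "snv":
                caller_set = frozenset({"varscan", "gatk"}) if rng.random() < 0.95 \
                    else frozenset({"gatk"})
            else:
                u = rng.random()
                if u < 0.6:
                    caller_set = frozenset({"varscan", "gatk", "pindel"})
                elif u < 0.9:
                    caller_set = frozenset({"gatk", "pindel"})
                else:
                    caller_set = frozenset({"pindel"})
            ndp = _poisson_at_least(rng, config.normal_depth_mean)
            nalt = int(rng.binomial(ndp, 0.5))
            loh = bool(rng.random() < config.loh_prob)
            if loh:
                tumor_p = (1 - config.loh_tumor_vaf) if config.mutant_allele_loss \
                    else config.loh_tumor_vaf
            else:
                tumor_p = 0.5
            tdp = _poisson_at_least(rng, config.tumor_depth_mean)
            talt = int(rng.binomial(tdp, tumor_p))
            obs = VariantObservation(
                sample_id=sid, chrom=str(chrom_of[gene]), pos=pos, ref=ref, alt=alt,
                gene=gene, consequence=csq,
                hgvs=f"{gene}:c.{pos % 5000}{ref}>{alt}",
                caller_set=caller_set, variant_class=vclass,
                normal_depth=ndp, normal_alt=nalt,
                tumor_depth=tdp, tumor_alt=talt,
                population_af={"1kg": 0.0, "exac": 0.0}, af_imputed=False)
            variants.append(obs)

            tags = {"PVS1", "PM2"} if csq in TRUNCATING else {"PS1", "PM2"}
            clinvar = "pathogenic_reviewed" if rng.random() < 0.2 else "absent"
            evidence.append(EvidenceAssignment(
                variant_key=obs.key(), tags=frozenset(tags),
                clinvar_status=clinvar, sample_id=sid, gene=gene))

            biallelic = bool(rng.random() < config.biallelic_prob)
            if biallelic:
                som_csq = "missense" if rng.random() < 0.5 else "nonsense"
                somatic_rows.append({
                    "sample_id": sid, "gene": gene, "chrom": str(chrom_of[gene]),
                    "pos": pos + 5000, "consequence": som_csq,
                    "hgvs": f"{gene}:p.E{(pos % 900) + 100}"
                            + ("K" if som_csq == "missense" else "*")})

            degraded = (csq in TRUNCATING) and not loh
            if loh and not config.mutant_allele_loss:
                rna_p = config.loh_tumor_vaf
            elif degraded:
                rna_p = config.ase_rna_vaf
            else:
                rna_p = 0.5
            rna_total = int(rng.poisson(config.rna_depth_mean))
            rna_alt = int(rng.binomial(rna_total, rna_p)) if rna_total else 0
            rna_row = {"sample_id": sid, "variant_key": obs.key(),
                       "rna_alt": rna_alt, "rna_total": rna_total,
                       "consensus_reads": None, "cryptic_reads": None}
            if csq == "splice_site":
                junction_total = _poisson_at_least(rng, 95, floor=20)
                cryptic = int(rng.binomial(junction_total, config.missplice_mean_fraction))
                rna_row["consensus_reads"] = junction_total - cryptic
                rna_row["cryptic_reads"] = cryptic
            rna_rows.append(rna_row)

            truth_rows.append({
                "sample_id": sid, "gene": gene, "variant_key": obs.key(),
                "carrier": True, "loh": loh, "biallelic": biallelic,
                "degraded": degraded, "decoy": False})

    # Decoy observations: common-AF or low-support variants in non-carriers,
    # classified as uncertain — fodder for the QC and classification filters.
    n_decoys = int(config.decoy_fraction * len(samples))
    sample_ids = [s.sample_id for s in samples]
    for d in range(n_decoys):
        sid = sample_ids[int(rng.integers(0, len(sample_ids)))]
        gene = genes[int(rng.integers(0, len(genes)))]
        pos = int(pos_of[gene]) + 90_000 + d
        common = rng.random() < 0.5
        ndp = _poisson_at_least(rng, config.normal_depth_mean)
        nalt = int(rng.binomial(ndp, 0.5)) if common else int(rng.integers(0, 4))
        tdp = _poisson_at_least(rng, config.tumor_depth_mean)
        talt = int(rng.binomial(tdp, 0.5))
        obs = VariantObservation(
            sample_id=sid, chrom=str(chrom_of[gene]), pos=pos, ref="G", alt="A",
            gene=gene, consequence="missense", hgvs=f"{gene}:c.{pos % 5000}G>A",
            caller_set=frozenset({"varscan", "gatk"}), variant_class="snv",
            normal_depth=ndp, normal_alt=nalt, tumor_depth=tdp, tumor_alt=talt,
            population_af={"1kg": 0.01 if common else 0.0,
                           "exac": 0.012 if common else 0.0},
            af_imputed=False)
        variants.append(obs)
        evidence.append(EvidenceAssignment(
            variant_key=obs.key(), tags=frozenset({"PM2"}),
            clinvar_status="absent", sample_id=sid, gene=gene))
        truth_rows.append({"sample_id": sid, "gene": gene, "variant_key": obs.key(),
                           "carrier": False, "loh": False, "biallelic": False,
                           "degraded": False, "decoy": True})

    # background somatic mutations, including silent ones
    n_background = len(samples) // 2
    bg_csq = np.array(["missense", "synonymous", "nonsense"])
    for b in range(n_background):
        sid = sample_ids[int(rng.integers(0, len(sample_ids)))]
        gene = genes[int(rng.integers(0, len(genes)))]
        csq = str(rng.choice(bg_csq, p=[0.5, 0.35, 0.15]))
        somatic_rows.append({
            "sample_id": sid, "gene": gene, "chrom": str(chrom_of[gene]),
            "pos": int(pos_of[gene]) + 40_000 + b, "consequence": csq,
            "hgvs": f"{gene}:p.A{100 + b}" + ("V" if csq != "nonsense" else "*")})

    # expression matrix
    gene_mu = rng.uniform(3.0, 7.0, len(genes))
    log_expr = rng.normal(gene_mu[:, None], 0.5, (len(genes), len(samples)))
    expr = np.exp(log_expr)
    for gi, gene in enumerate(genes):
        for si, sid in enumerate(sample_ids):
            if carrier_matrix.loc[sid, gene]:
                if roles.get(gene) == "oncogene":
                    expr[gi, si] /= config.expression_effect
                else:
                    expr[gi, si] *= config.expression_effect
    expression = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=sample_ids))

    somatic_cols = ["sample_id", "gene", "chrom", "pos", "consequence", "hgvs"]
    truth = SyntheticTruth(
        carrier_matrix=carrier_matrix,
        variant_truth=pd.DataFrame(
            truth_rows, columns=["sample_id", "gene", "variant_key", "carrier",
                                 "loh", "biallelic", "degraded", "decoy"]),
        gene_or=pd.DataFrame(
            [{"ancestry": e.ancestry, "cancer": e.cancer, "gene": e.gene,
              "true_or": e.odds_ratio} for e in config.planted_effects],
            columns=["ancestry", "cancer", "gene", "true_or"]),
    )
    return SimulatedCohort(
        samples=samples, variants=variants, evidence=evidence,
        somatic=pd.DataFrame(somatic_rows, columns=somatic_cols),
        expression=expression,
        rna_counts=pd.DataFrame(
            rna_rows, columns=["sample_id", "variant_key", "rna_alt", "rna_total",
                               "consensus_reads", "cryptic_reads"]),
        truth=truth, config=config)


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

def emit_fixture(sim: SimulatedCohort, out_dir: str | Path, force: bool = False) -> None:
    """Write every table of a simulated cohort as a pipeline-ready fixture.

    Refuses to write into a non-empty directory unless ``force`` is set.
    Re-emitting the same simulation gives a byte-identical directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")

    write_sample_sheet(sim.samples, out / "samples.tsv")
    write_variant_table(sim.variants, out / "variants.vcf", dialect="vcf")
    write_variant_table(sim.variants, out / "variants.tsv", dialect="maf_like")
    ev_rows = [{"variant_key": e.variant_key, "sample_id": e.sample_id,
                "gene": e.gene, "tags": ",".join(sorted(e.tags)),
                "clinvar_status": e.clinvar_status}
               for e in sorted(sim.evidence, key=lambda e: (e.variant_key, e.sample_id))]
    _write_tsv(pd.DataFrame(ev_rows, columns=["variant_key", "sample_id", "gene",
                                              "tags", "clinvar_status"]),
               out / "evidence.tsv")
    _write_tsv(sim.somatic.sort_values(["sample_id", "gene", "pos"]),
               out / "somatic.tsv")
    write_expression_matrix(sim.expression, out / "expression.tsv")
    _write_tsv(sim.rna_counts.sort_values(["sample_id", "variant_key"]),
               out / "rna_counts.tsv")
    _write_tsv(sim.truth.variant_truth.sort_values(["sample_id", "variant_key"]),
               out / "truth_variants.tsv")
    carrier_long = (sim.truth.carrier_matrix.stack().rename("carrier")
                    .reset_index().rename(columns={"level_0": "sample_id",
                                                   "level_1": "gene"}))
    _write_tsv(carrier_long[carrier_long["carrier"]]
               .sort_values(["sample_id", "gene"]), out / "truth_carriers.tsv")
    _write_tsv(sim.truth.gene_or, out / "truth_gene_or.tsv")
    gene_table = load_gene_table()
    _write_tsv(gene_table[["gene", "role"]], out / "gene_roles.tsv")


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration with every planted odds ratio forced to 1."""
    config = SimulationConfig(seed=seed, **overrides)
    config.planted_effects = [replace(e, odds_ratio=1.0)
                              for e in config.planted_effects]
    return config
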