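"""Shared fixtures: small hand-built cohorts and a session-wide simulation."""

import numpy as np
import pytest
from hypothesis import settings

from cpg import (SampleRecord, SimulationConfig, VariantObservation,
                 simulate_cohort)
from cpg.synthetic_cohort import PlantedEffect

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


def make_sample(sample_id, cancer="LUSC", ancestry="afr", age=60.0, sex="female",
                pc1=0.0, pc2=0.0, concordance=0.99, secondary=0.0):
    """A SampleRecord with a pure (or two-way) ancestry composition."""
    others = [c for c in ("afr", "eur", "eas", "sas", "amr") if c != ancestry]
    fractions = {c: 0.0 for c in ("afr", "eur", "eas", "sas", "amr")}
    fractions[ancestry] = 1.0 - secondary
    fractions[others[0]] = secondary
    return SampleRecord(
        sample_id=sample_id, cancer_type=cancer, age_years=age, sex=sex,
        ancestry_fractions=fractions,
        consensus_group=ancestry if secondary <= 0.2 else f"{ancestry}_admix",
        analysis_group=ancestry, pc1=pc1, pc2=pc2,
        genotype_concordance=concordance)


def make_variant(sample_id="S1", chrom="13", pos=32_900_000, ref="C", alt="T",
                 gene="BRCA2", consequence="nonsense", callers=("varscan", "gatk"),
                 variant_class="snv", normal_depth=60, normal_alt=30,
                 tumor_depth=60, tumor_alt=30, population_af=None):
    return VariantObservation(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=consequence, hgvs=f"{gene}:c.{pos % 1000}{ref}>{alt}",
        caller_set=frozenset(callers), variant_class=variant_class,
        normal_depth=normal_depth, normal_alt=normal_alt,
        tumor_depth=tumor_depth, tumor_alt=tumor_alt,
        population_af=population_af if population_af is not None else {"1kg": 0.0})


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration synthetic cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=20240901))


@pytest.fixture(scope="session")
def small_config():
    """A compact single-ancestry layout used by faster end-to-end tests."""
    return SimulationConfig(
        seed=7,
        cohort_sizes={("afr", "LUSC"): 60, ("afr", "BRCA"): 80, ("afr", "OV"): 60},
        planted_effects=[PlantedEffect("afr", "LUSC", "BRCA2", 20.0, 0.02)],
        genes=("BRCA2", "ATM", "TP53", "FH", "VHL", "RET"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
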