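"""Rare-variant association power simulation and downsampling design.

``simulate_power`` is a Monte-Carlo power calculation for a gene-region
burden test: each replicate draws a set of rare variants (allele
frequencies uniform below the MAF bound, a configurable fraction causal),
draws genotypes binomially, assigns case status through a logistic model
whose log odds ratio applies per causal allele, and tests pooled rare
alleles in cases vs controls with the exact Total Frequency Test. Power is
the fraction of replicates rejected at the significance level
alpha (default 0.05, a per-region test level for a targeted burden
analysis).

``downsample_discovery`` reruns the burden association on random case
subsets of increasing size to show how discoveries accumulate with cohort
size; each size is repeated over several iterations and summarized by the
per-size mean and range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .association import bh_adjust, run_associations
from .io_formats import SampleRecord


@dataclass
class PowerResult:
    n_total: int
    case_fraction: float
    maf: float
    causal_fraction: float
    odds_ratio: float
    alpha: float
    replicates: int
    power: float
    seed: int


@dataclass
class DownsampleCurve:
    sizes: list[int]
    mean_genes: list[float]
    min_genes: list[int]
    max_genes: list[int]
    iterations: int
    seed: int


def _one_replicate(rng: np.random.Generator, n_total: int, case_fraction: float,
                   maf: float, causal_fraction: float, odds_ratio: float,
                   region_variants: int) -> float:
    """Simulate one region and return the one-sided burden-test p-value."""
    mafs = rng.uniform(0.0, maf, region_variants)
    n_causal = int(round(causal_fraction * region_variants))
    causal = np.zeros(region_variants, dtype=bool)
    causal[rng.choice(region_variants, n_causal, replace=False)] = True
    genotypes = rng.binomial(2, mafs, size=(n_total, region_variants))
    causal_alleles = genotypes[:, causal].sum(axis=1)
    eta = logit(case_fraction) + math.log(odds_ratio) * causal_alleles
    case = rng.random(n_total) < expit(eta)
    n_cases = int(case.sum())
    n_controls = n_total - n_cases
    if n_cases == 0 or n_controls == 0:
        return 1.0
    alt_total = genotypes.sum(axis=1)
    a_case = int(alt_total[case].sum())
    a_ctrl = int(alt_total[~case].sum())
    table = [[a_case, 2 * region_variants * n_cases - a_case],
             [a_ctrl, 2 * region_variants * n_controls - a_ctrl]]
    return float(stats.fisher_exact(table, alternative="greater").pvalue)


def simulate_power(n_total: int, case_fraction: float = 0.5, maf: float = 0.001,
                   causal_fraction: float = 0.8, odds_ratio: float = 5.0,
                   alpha: float = 0.05, replicates: int = 100,
                   region_variants: int = 25, seed: int = 0) -> PowerResult:
    """Monte-Carlo burden-test power for one design point.

    ``region_variants`` (default 25) stands in for the rare-variant count
    of a ~5 kb target region. Deterministic for a given seed.
    """
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must lie strictly between 0 and 1")
    if n_total <= 0 or replicates <= 0 or region_variants <= 0:
        raise ValueError("n_total, replicates and region_variants must be positive")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(replicates):
        p = _one_replicate(rng, n_total, case_fraction, maf, causal_fraction,
                           odds_ratio, region_variants)
        if p < alpha:
            rejections += 1
    return PowerResult(n_total=n_total, case_fraction=case_fraction, maf=maf,
                       causal_fraction=causal_fraction, odds_ratio=odds_ratio,
                       alpha=alpha, replicates=replicates,
                       power=rejections / replicates, seed=seed)


def find_min_n(n_grid: Sequence[int], target_power: float = 0.8,
               seed: int = 0, **power_kwargs) -> tuple[int | None, list[PowerResult]]:
    """Smallest grid point whose simulated power reaches the target.

    Every grid point uses an independent child seed spawned from ``seed``
    so the curve shares one reproducible seed stream. Returns
    (min_n or None, the full curve).
    """
    if len(n_grid) == 0:
        raise ValueError("empty sample-size grid")
    if list(n_grid) != sorted(n_grid):
        raise ValueError("n_grid must be increasing")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(n_grid)) % (2 ** 31)
    curve = [simulate_power(n_total=int(n), seed=int(s), **power_kwargs)
             for n, s in zip(n_grid, child_seeds)]
    for res in curve:
        if res.power >= target_power:
            return res.n_total, curve
    return None, curve


def downsample_discovery(samples: list[SampleRecord], carriers: pd.DataFrame,
                         ancestry: str, cancer: str,
                         sizes: Sequence[int], iterations: int = 10,
                         seed: int = 0, method: str = "tft",
                         fdr_threshold: float = 0.05,
                         min_cases: int = 20) -> DownsampleCurve:
    """Discovery curve over random case subsets of increasing size.

    For each subset size, cases of the target (ancestry, cancer) cohort
    are subsampled uniformly without replacement (controls are kept in
    full), the association analysis is rerun, and genes significant at
    the FDR threshold in the target cohort are counted. Reported per size:
    mean, min and max over the iterations.
    """
    rng = np.random.default_rng(seed)
    case_ids = [s.sample_id for s in samples
                if s.analysis_group == ancestry and s.cancer_type == cancer]
    other = [s for s in samples
             if not (s.analysis_group == ancestry and s.cancer_type == cancer)]
    by_id = {s.sample_id: s for s in samples}
    n_cases = len(case_ids)
    mean_genes, min_genes, max_genes = [], [], []
    for size in sizes:
        if size > n_cases:
            raise ValueError(f"subset size {size} exceeds cohort size {n_cases}")
        counts = []
        for _ in range(iterations):
            if size == 0:
                counts.append(0)
                continue
            picked = sorted(rng.choice(case_ids, size, replace=False).tolist())
            subset = other + [by_id[sid] for sid in picked]
            sub_carriers = carriers.loc[[s.sample_id for s in subset]]
            results = run_associations(subset, sub_carriers, method=method,
                                       min_cases=min_cases)
            n_sig = sum(1 for r in results
                        if r.ancestry == ancestry and r.cancer == cancer
                        and math.isfinite(r.fdr) and r.fdr < fdr_threshold)
            counts.append(n_sig)
        mean_genes.append(float(np.mean(counts)))
        min_genes.append(int(np.min(counts)))
        max_genes.append(int(np.max(counts)))
    return DownsampleCurve(sizes=list(sizes), mean_genes=mean_genes,
                           min_genes=min_genes, max_genes=max_genes,
                           iterations=iterations, seed=seed)
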