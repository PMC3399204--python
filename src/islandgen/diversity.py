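"""Per-population diversity statistics.

Observed/expected heterozygosity, rarefied allelic richness, the exact paired
signed-rank comparison of per-locus richness, and the assembled per-population
summary record (the standard columns of a microsatellite diversity table:
n, a, r, H_O, H_E, F_IS, HWE p, rare alleles per locus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeMatrix,
    allele_frequencies,
    mean_alleles_per_locus,
    rare_alleles,
)
from .fstats import wc_f_statistics
from .hwe import hwe_exact_test


@dataclass
class PerLocusStat:
    per_locus: dict[str, float]
    mean: float


def _pop_locus_genotypes(gm: GenotypeMatrix, population: str, j: int) -> np.ndarray:
    idx = [i for i, p in enumerate(gm.populations) if p == population]
    if not idx:
        raise KeyError(f"unknown population {population!r}")
    calls = gm.calls[idx, j, :]
    return calls[(calls != MISSING).all(axis=1)]


def observed_heterozygosity(gm: GenotypeMatrix, population: str) -> PerLocusStat:
    """Fraction of non-missing genotypes heterozygous, per locus and mean."""
    per_locus: dict[str, float] = {}
    for j, locus in enumerate(gm.loci):
        g = _pop_locus_genotypes(gm, population, j)
        if len(g) == 0:
            continue
        per_locus[locus] = float((g[:, 0] != g[:, 1]).mean())
    if not per_locus:
        raise ValueError(f"no genotyped loci for population {population!r}")
    return PerLocusStat(per_locus, float(np.mean(list(per_locus.values()))))


def expected_heterozygosity(gm: GenotypeMatrix, population: str) -> PerLocusStat:
    """Nei's unbiased gene diversity, per locus and mean over loci.

    H_E = 2n/(2n-1) * (1 - sum_k p_k^2) with n the number of non-missing
    genotypes at the locus.  Loci with fewer than two genotypes are excluded.
    """
    per_locus: dict[str, float] = {}
    for j, locus in enumerate(gm.loci):
        g = _pop_locus_genotypes(gm, population, j)
        n = len(g)
        if n < 2:
            continue
        genes = g.ravel()
        _, counts = np.unique(genes, return_counts=True)
        p = counts / (2 * n)
        per_locus[locus] = float((2 * n) / (2 * n - 1) * (1.0 - (p**2).sum()))
    if not per_locus:
        raise ValueError(f"no locus with >=2 genotypes for {population!r}")
    return PerLocusStat(per_locus, float(np.mean(list(per_locus.values()))))


def _rarefied_richness(allele_gene_counts: np.ndarray, g: int) -> float:
    """Expected allele count in a subsample of g genes (hypergeometric)."""
    total = int(allele_gene_counts.sum())
    if g > total:
        raise ValueError(f"rarefaction size {g} exceeds gene count {total}")
    r = 0.0
    for nk in allele_gene_counts:
        # 1 - C(total - nk, g) / C(total, g), exact integer arithmetic
        r += 1.0 - math.comb(total - int(nk), g) / math.comb(total, g)
    return r


def min_gene_count(aft: AlleleFrequencyTable, populations: list[str] | None = None) -> int:
    """Smallest non-empty gene count across compared populations x loci."""
    pops = populations if populations is not None else aft.populations
    counts = [
        aft[(p, locus)].gene_count
        for p in pops
        for locus in aft.loci
        if not aft[(p, locus)].empty
    ]
    if not counts:
        raise ValueError("no population x locus cell with data")
    return min(counts)


def allelic_richness(
    gm: GenotypeMatrix,
    population: str,
    g: int | None = None,
    compare_with: list[str] | None = None,
) -> PerLocusStat:
    """Rarefied allelic richness per locus and its mean.

    r_g at a locus is the expected number of distinct alleles among g genes
    drawn without replacement from the 2N sampled genes.  When ``g`` is
    omitted it defaults to the smallest gene count over all loci of the
    populations under comparison (``compare_with`` + the focal population),
    the convention that makes richness comparable across unequal samples.
    """
    aft = allele_frequencies(gm)
    if g is None:
        pops = [population] + [
            p for p in (compare_with or aft.populations) if p != population
        ]
        g = min_gene_count(aft, pops)
    if g < 2:
        raise ValueError("rarefaction size must be >= 2")
    per_locus: dict[str, float] = {}
    for locus in aft.loci:
        rec = aft[(population, locus)]
        if rec.empty:
            continue
        if g > rec.gene_count:
            raise ValueError(
                f"rarefaction size {g} exceeds gene count {rec.gene_count} "
                f"at locus {locus!r}"
            )
        gene_counts = np.round(
            np.array(list(rec.frequencies.values())) * rec.gene_count
        ).astype(int)
        per_locus[locus] = _rarefied_richness(gene_counts, g)
    if not per_locus:
        raise ValueError(f"no data for population {population!r}")
    return PerLocusStat(per_locus, float(np.mean(list(per_locus.values()))))


def wilcoxon_richness_test(x: np.ndarray, y: np.ndarray) -> float | None:
    """Exact two-sided paired Wilcoxon signed-rank p-value.

    Pairs with zero difference are dropped.  For m <= 25 informative pairs the
    exact null distribution of the signed-rank sum is enumerated by dynamic
    programming over midranks (ties allowed); beyond that a normal
    approximation with tie correction is used.  Returns None when no
    informative pair remains.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    m = d.size
    if m == 0:
        return None
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if m <= 25:
        # integer DP over doubled midranks
        r2 = np.round(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        counts /= 2.0**m
        w2 = int(round(2 * w_plus))
        lower = counts[: w2 + 1].sum()
        upper = counts[w2:].sum()
        return float(min(1.0, 2 * min(lower, upper)))
    mean = m * (m + 1) / 4
    # tie correction on the variance of the rank sum
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = m * (m + 1) * (2 * m + 1) / 24 - (tie_counts**3 - tie_counts).sum() / 48
    z = (w_plus - mean) / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


@dataclass
class PopulationSummary:
    """One row of a diversity summary table."""

    population: str
    n: int
    a: float
    r: float
    H_O: float
    H_E: float
    F_IS: float | None
    hwe_p: float | None
    rare_mean: float
    rare_sd: float
    monomorphic: list[str]


def population_summary(
    gm: GenotypeMatrix,
    population: str,
    g: int | None = None,
    seed: int | None = None,
    rare_threshold: float = 0.05,
    hwe_steps: int = 100_000,
) -> PopulationSummary:
    """Assemble the per-population diversity record.

    The multi-locus HWE p-value combines locus-wise exact tests over
    polymorphic loci with Fisher's method; F_IS is the multilocus
    Weir-Cockerham within-population estimate (None when every locus is
    monomorphic in the population, e.g. a population of clones).
    """
    aft = allele_frequencies(gm)
    if population not in aft.populations:
        raise KeyError(f"unknown population {population!r}")
    n = sum(1 for p in gm.populations if p == population)
    a, _ = mean_alleles_per_locus(aft, population)
    r = allelic_richness(gm, population, g=g).mean
    ho = observed_heterozygosity(gm, population).mean
    he = expected_heterozygosity(gm, population).mean
    ra = rare_alleles(aft, population, rare_threshold)
    mono = [
        locus for locus in aft.loci if aft[(population, locus)].allele_count <= 1
    ]
    try:
        fis = wc_f_statistics(gm, [population]).F_IS
    except ValueError:
        fis = None

    rng = np.random.default_rng(seed)
    pvals = []
    for locus in gm.loci:
        if aft[(population, locus)].allele_count < 2:
            continue
        p = hwe_exact_test(
            gm, population, locus, n_steps=hwe_steps,
            seed=int(rng.integers(2**31 - 1)),
        )
        if p is not None:
            pvals.append(p)
    if pvals:
        _, hwe_p = stats.combine_pvalues(pvals, method="fisher")
        hwe_p = float(hwe_p)
    else:
        hwe_p = None
    return PopulationSummary(
        population=population, n=n, a=a, r=r, H_O=ho, H_E=he, F_IS=fis,
        hwe_p=hwe_p, rare_mean=ra.mean, rare_sd=ra.sd, monomorphic=mono,
    )
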