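"""Exact test of Hardy-Weinberg proportions, conditional on allele counts.

The conditional probability of a genotype-count array {n_kl} given allele
counts {m_k} under random union of gametes is

    P = n! * 2^h * prod_k m_k! / ( (2n)! * prod_{k<=l} n_kl! )

with n genotypes and h heterozygotes.  The two-sided exact p-value is the
total mass of arrays no more probable than the observed one.  Arrays are
enumerated exhaustively when their number is manageable; otherwise the exact
conditional distribution is sampled by random re-pairing of the 2n genes
(each shuffle is an i.i.d. draw from the null).
"""

from __future__ import annotations

import math
from itertools import combinations_with_replacement

import numpy as np

from .core import MISSING, GenotypeMatrix

_REL_TOL = 1e-9


def _log_prob(n: int, log_const: float, het: int, pair_counts: dict) -> float:
    """log P of a genotype array; log_const collects the array-free factors."""
    s = log_const + het * math.log(2.0)
    for c in pair_counts.values():
        s -= math.lgamma(c + 1)
    return s


def _enumerate_tables(m: list[int], max_tables: int):
    """Yield (het_count, sum_log_factorial_cells) over all genotype arrays.

    ``m`` is the per-allele gene count vector.  Raises ``OverflowError`` once
    more than ``max_tables`` arrays have been produced.
    """
    K = len(m)
    produced = 0

    def rec(counts: tuple[int, ...], het: int, logfac: float):
        nonlocal produced
        i = next((k for k in range(K) if counts[k] > 0), None)
        if i is None:
            produced += 1
            if produced > max_tables:
                raise OverflowError("enumeration too large")
            yield het, logfac
            return
        mi = counts[i]
        # n_ii homozygotes, remainder paired with later alleles
        for n_ii in range(mi // 2, -1, -1):
            rem = mi - 2 * n_ii
            base = list(counts)
            base[i] = 0
            yield from _compose(
                base, i + 1, rem, het, logfac - (0 if n_ii == 0 else math.lgamma(n_ii + 1)),
            )

    def _compose(counts: list[int], j: int, rem: int, het: int, logfac: float):
        # distribute `rem` genes of allele i among heterozygote classes (i, j>=j)
        if rem == 0:
            yield from rec(tuple(counts), het, logfac)
            return
        if j >= K:
            return
        avail = counts[j]
        for n_ij in range(min(rem, avail), -1, -1):
            counts[j] -= n_ij
            yield from _compose(
                counts, j + 1, rem - n_ij, het + n_ij,
                logfac - (0 if n_ij == 0 else math.lgamma(n_ij + 1)),
            )
            counts[j] += n_ij

    yield from rec(tuple(m), 0, 0.0)


def _observed_table(genotypes: np.ndarray, alleles: np.ndarray):
    index = {int(a): i for i, a in enumerate(alleles)}
    pairs: dict[tuple[int, int], int] = {}
    het = 0
    for a, b in genotypes:
        i, j = sorted((index[int(a)], index[int(b)]))
        pairs[(i, j)] = pairs.get((i, j), 0) + 1
        het += i != j
    return pairs, het


def hwe_exact_test(
    gm: GenotypeMatrix,
    population: str,
    locus: str,
    n_steps: int = 100_000,
    seed: int | None = None,
    max_tables: int = 1_000_000,
) -> float | None:
    """Exact conditional HWE p-value for one locus in one population.

    Returns None (not applicable) when the locus is monomorphic in the
    population.  Uses complete enumeration when at most ``max_tables``
    genotype arrays are compatible with the allele counts; otherwise a
    Monte-Carlo estimate from ``n_steps`` random gene re-pairings (add-one
    estimator, so p is never exactly 0).
    """
    if locus not in gm.loci:
        raise KeyError(f"unknown locus {locus!r}")
    j = gm.loci.index(locus)
    idx = [i for i, p in enumerate(gm.populations) if p == population]
    if not idx:
        raise KeyError(f"unknown population {population!r}")
    g = gm.calls[idx, j, :]
    g = g[(g != MISSING).all(axis=1)]
    genes = g.ravel()
    alleles, m = np.unique(genes, return_counts=True)
    if alleles.size < 2:
        return None
    n = len(g)
    log_const = (
        math.lgamma(n + 1)
        + sum(math.lgamma(int(mk) + 1) for mk in m)
        - math.lgamma(2 * n + 1)
    )
    pairs, het_obs = _observed_table(g, alleles)
    logfac_obs = -sum(math.lgamma(c + 1) for c in pairs.values())
    logp_obs = log_const + het_obs * math.log(2.0) + logfac_obs
    cut = logp_obs + _REL_TOL * abs(logp_obs)

    try:
        total = 0.0
        tail = 0.0
        for het, logfac in _enumerate_tables([int(x) for x in m], max_tables):
            logp = log_const + het * math.log(2.0) + logfac
            p = math.exp(logp)
            total += p
            if logp <= cut:
                tail += p
        return float(min(1.0, tail / total))
    except OverflowError:
        pass

    from scipy.special import gammaln

    rng = np.random.default_rng(seed)
    K = alleles.size
    coded = np.searchsorted(alleles, genes)
    offdiag = np.array(
        [i != j for i in range(K) for j in range(K)], dtype=bool
    )
    hits = 0
    for _ in range(n_steps):
        pool = rng.permutation(coded).reshape(-1, 2)
        pool.sort(axis=1)
        key = pool[:, 0] * K + pool[:, 1]
        cells = np.bincount(key, minlength=K * K)
        het_s = int(cells[offdiag].sum())
        logp_s = (
            log_const + het_s * math.log(2.0) - gammaln(cells + 1).sum()
        )
        if logp_s <= cut:
            hits += 1
    return float((hits + 1) / (n_steps + 1))


def enumerate_hwe_pvalue(allele_counts: list[int], observed_pairs: dict, max_tables: int = 1_000_000) -> float:
    """Exact p directly from gene counts and a genotype-count dict.

    ``observed_pairs`` maps (i, j) allele-index pairs (i <= j) to genotype
    counts.  Convenience entry point for toy tables and tests.
    """
    m = [int(x) for x in allele_counts]
    n = sum(observed_pairs.values())
    if 2 * n != sum(m):
        raise ValueError("genotype counts inconsistent with gene counts")
    log_const = (
        math.lgamma(n + 1)
        + sum(math.lgamma(mk + 1) for mk in m)
        - math.lgamma(2 * n + 1)
    )
    het_obs = sum(c for (i, j), c in observed_pairs.items() if i != j)
    logfac_obs = -sum(math.lgamma(c + 1) for c in observed_pairs.values())
    logp_obs = log_const + het_obs * math.log(2.0) + logfac_obs
    cut = logp_obs + _REL_TOL * abs(logp_obs)
    total = tail = 0.0
    for het, logfac in _enumerate_tables(m, max_tables):
        logp = log_const + het * math.log(2.0) + logfac
        p = math.exp(logp)
        total += p
        if logp <= cut:
            tail += p
    return float(min(1.0, tail / total))
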