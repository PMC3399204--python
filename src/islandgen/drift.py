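"""Wright-Fisher genetic drift: Monte-Carlo forecasting of diversity loss.

Each locus evolves independently by multinomial resampling of 2*Ne genes per
nonoverlapping generation (random mating, constant effective size, no
mutation/migration/selection).  Recorded per generation: gene diversity
1 - sum p^2 (exact in-model, no small-sample correction) and the surviving
allele count, averaged over loci, with empirical 2.5/97.5% envelopes across
replicates.  The closed-form companion H_t = H_0 (1 - 1/(2Ne))^t gives the
expected geometric decay the simulator must track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def project_heterozygosity(H0: float, Ne: float, t: int) -> float:
    """Closed-form expected heterozygosity after t generations of drift.

    H_t = H_0 * (1 - 1/(2 Ne))^t.
    """
    if not 0 <= H0 <= 1:
        raise ValueError("H0 must be in [0, 1]")
    if Ne <= 0.5:
        raise ValueError("Ne must exceed 0.5 (decay factor must be positive)")
    if t < 0:
        raise ValueError("t must be >= 0")
    return float(H0 * (1 - 1 / (2 * Ne)) ** t)


@dataclass
class DriftConfig:
    """Scenario for the forward drift simulation."""

    Ne: int
    generations: int
    replicates: int = 1000
    seed: int | None = None
    initial_frequencies: dict[str, np.ndarray] = field(default_factory=dict)
    keep_replicates: bool = False

    def __post_init__(self) -> None:
        if self.Ne < 1:
            raise ValueError("Ne must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not self.initial_frequencies:
            self.initial_frequencies = default_initial_frequencies()
        for locus, p in self.initial_frequencies.items():
            p = np.asarray(p, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1) > 1e-9:
                raise ValueError(f"frequencies at {locus!r} must sum to 1")
            self.initial_frequencies[locus] = p


@dataclass
class DriftTrajectory:
    """Per-generation summaries of the drift Monte Carlo."""

    generations: np.ndarray  # 0..t_max
    het_mean: np.ndarray  # mean over loci and replicates
    het_lo: np.ndarray
    het_hi: np.ndarray
    alleles_mean: np.ndarray
    alleles_lo: np.ndarray
    alleles_hi: np.ndarray
    het_replicates: np.ndarray | None = None  # (R, t_max+1) locus means
    alleles_replicates: np.ndarray | None = None
    #: per-locus (R, K) final-generation allele frequencies
    final_frequencies: dict[str, np.ndarray] | None = None


def simulate_drift(config: DriftConfig) -> DriftTrajectory:
    """Run the multinomial Wright-Fisher Monte Carlo.

    Loci are simulated independently for every replicate; summaries are the
    replicate x locus means per generation and the 2.5/97.5 percentile
    envelope of the per-replicate locus means.
    """
    rng = np.random.default_rng(config.seed)
    R, G = config.replicates, config.generations
    loci = list(config.initial_frequencies)
    L = len(loci)
    het = np.zeros((R, L, G + 1))
    cnt = np.zeros((R, L, G + 1))
    final: dict[str, np.ndarray] = {}
    two_ne = 2 * config.Ne
    for l, locus in enumerate(loci):
        p0 = config.initial_frequencies[locus]
        p = np.tile(p0, (R, 1))
        het[:, l, 0] = 1 - (p**2).sum(axis=1)
        cnt[:, l, 0] = (p > 0).sum(axis=1)
        for g in range(1, G + 1):
            draws = rng.multinomial(two_ne, p)
            p = draws / two_ne
            het[:, l, g] = 1 - (p**2).sum(axis=1)
            cnt[:, l, g] = (p > 0).sum(axis=1)
        final[locus] = p
    het_rep = het.mean(axis=1)  # (R, G+1) locus means
    cnt_rep = cnt.mean(axis=1)
    lo_h, hi_h = np.percentile(het_rep, [2.5, 97.5], axis=0)
    lo_c, hi_c = np.percentile(cnt_rep, [2.5, 97.5], axis=0)
    return DriftTrajectory(
        generations=np.arange(G + 1),
        het_mean=het_rep.mean(axis=0),
        het_lo=lo_h,
        het_hi=hi_h,
        alleles_mean=cnt_rep.mean(axis=0),
        alleles_lo=lo_c,
        alleles_hi=hi_c,
        het_replicates=het_rep if config.keep_replicates else None,
        alleles_replicates=cnt_rep if config.keep_replicates else None,
        final_frequencies=final if config.keep_replicates else None,
    )


def generations_to_threshold(
    config: DriftConfig, target_H: float, trajectory: DriftTrajectory | None = None
) -> int | None:
    """First generation at which mean simulated diversity falls to target_H.

    Returns 0 when the target is already met initially and None when the
    target is not reached within the configured horizon.
    """
    if trajectory is None:
        trajectory = simulate_drift(config)
    if target_H >= trajectory.het_mean[0]:
        return 0
    below = np.nonzero(trajectory.het_mean <= target_H)[0]
    return int(below[0]) if below.size else None


def default_initial_frequencies(
    mean_het: float = 0.597, allele_counts: tuple[int, ...] = (10, 6, 6, 4, 18, 12, 3, 1, 9, 14, 8, 10, 16)
) -> dict[str, np.ndarray]:
    """Deterministic 13-locus frequency table for a mainland-like source.

    Per-locus allele counts average 9.0 (one locus monomorphic) and the mean
    gene diversity equals ``mean_het`` exactly.  Each polymorphic locus gets
    one common allele at frequency q and K-1 equally frequent minor alleles,
    with q solved so the locus hits its share c*(1 - 1/K) of the target
    (c a common scaling constant).  This emulates a large, diverse source
    population whose true frequency table is unknown but whose summary
    diversity is specified.
    """
    K = np.array(allele_counts, dtype=int)
    poly = K > 1
    weight = (1 - 1 / K[poly]).sum()
    c = mean_het * len(K) / weight
    if c >= 1:  # per-locus targets would exceed the 1 - 1/K ceiling
        raise ValueError("target mean heterozygosity not attainable")
    out: dict[str, np.ndarray] = {}
    for i, k in enumerate(K):
        name = f"L{i + 1:02d}"
        if k == 1:
            out[name] = np.array([1.0])
            continue
        H = c * (1 - 1 / k)
        # solve q^2 + (1-q)^2/(k-1) = 1 - H for the major-allele frequency
        A = 1 + 1 / (k - 1)
        B = -2 / (k - 1)
        C = 1 / (k - 1) - (1 - H)
        q = (-B + np.sqrt(B**2 - 4 * A * C)) / (2 * A)
        rest = (1 - q) / (k - 1)
        out[name] = np.array([q] + [rest] * (k - 1))
    return out
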