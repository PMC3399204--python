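"""Weir-Cockerham F-statistics (variance-components estimators).

The 1984 moment estimators of F_IS, F_ST and F_IT from codominant genotypes,
with multilocus values formed as ratios of summed variance components
("ratio of averages"), plus pairwise theta with a bootstrap-over-loci CI and
a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix


@dataclass
class LocusComponents:
    """Summed-over-alleles variance components at one locus.

    a: among-population; b: among-individual-within-population;
    c: within-individual.
    """

    a: float
    b: float
    c: float


@dataclass
class FStatistics:
    F_IS: float
    F_ST: float | None
    F_IT: float | None
    per_locus: dict[str, LocusComponents]
    loci_used: list[str]


def _locus_components(
    calls: list[np.ndarray],
) -> LocusComponents | None:
    """Components at one locus from per-population genotype arrays (n_i, 2)."""
    calls = [g for g in calls if len(g) > 0]
    r = len(calls)
    if r == 0:
        return None
    alleles = np.unique(np.concatenate([g.ravel() for g in calls]))
    if alleles.size < 2:
        return None
    n = np.array([len(g) for g in calls], dtype=float)
    nbar = n.mean()
    nsum = n.sum()
    if nbar <= 1:
        return None
    nc = (nsum - (n**2).sum() / nsum) / (r - 1) if r > 1 else np.nan

    a = b = c = 0.0
    for al in alleles:
        p = np.array([(g == al).mean() for g in calls])  # allele frequency
        h = np.array([((g == al).sum(axis=1) == 1).mean() for g in calls])
        pbar = (n * p).sum() / nsum
        hbar = (n * h).sum() / nsum
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar) if r > 1 else 0.0
        frac = (r - 1) / r if r > 1 else 0.0
        b_al = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - frac * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c_al = hbar / 2
        if r > 1:
            a_al = (nbar / nc) * (
                s2
                - (1 / (nbar - 1))
                * (pbar * (1 - pbar) - frac * s2 - hbar / 4)
            )
        else:
            a_al = 0.0
        a, b, c = a + a_al, b + b_al, c + c_al
    return LocusComponents(a, b, c)


def _per_pop_calls(
    gm: GenotypeMatrix, populations: list[str], j: int
) -> list[np.ndarray]:
    out = []
    for p in populations:
        idx = [i for i, q in enumerate(gm.populations) if q == p]
        g = gm.calls[idx, j, :]
        out.append(g[(g != MISSING).all(axis=1)])
    return out


def wc_f_statistics(
    gm: GenotypeMatrix, populations: list[str] | None = None
) -> FStatistics:
    """Multilocus Weir-Cockerham F-statistics over the given populations.

    Loci monomorphic across all included populations are excluded.  With a
    single population only F_IS is defined (F_ST/F_IT are None).  Raises
    ``ValueError`` when every locus is uninformative.
    """
    pops = populations if populations is not None else gm.population_set
    for p in pops:
        if p not in gm.populations:
            raise KeyError(f"unknown population {p!r}")
    per_locus: dict[str, LocusComponents] = {}
    for j, locus in enumerate(gm.loci):
        comp = _locus_components(_per_pop_calls(gm, pops, j))
        if comp is not None:
            per_locus[locus] = comp
    if not per_locus:
        raise ValueError("all loci monomorphic: F-statistics undefined")
    A = sum(cp.a for cp in per_locus.values())
    B = sum(cp.b for cp in per_locus.values())
    C = sum(cp.c for cp in per_locus.values())
    f_is = 1 - C / (B + C) if (B + C) != 0 else float("nan")
    if len(pops) > 1:
        f_st = A / (A + B + C) if (A + B + C) != 0 else float("nan")
        f_it = 1 - C / (A + B + C) if (A + B + C) != 0 else float("nan")
    else:
        f_st = f_it = None
    return FStatistics(f_is, f_st, f_it, per_locus, list(per_locus))


@dataclass
class FstResult:
    pair: tuple[str, str] | str
    theta: float
    ci_low: float
    ci_high: float
    perm_p: float | None
    n_perm: int
    n_boot: int
    degenerate_ci: bool = False


def _theta_from_components(comps: list[LocusComponents]) -> float:
    A = sum(c.a for c in comps)
    tot = sum(c.a + c.b + c.c for c in comps)
    return A / tot if tot != 0 else float("nan")


def global_fst(gm: GenotypeMatrix, populations: list[str] | None = None,
               n_boot: int = 1000, seed: int | None = None) -> FstResult:
    """Global theta over all populations with a bootstrap-over-loci 95% CI."""
    fs = wc_f_statistics(gm, populations)
    comps = list(fs.per_locus.values())
    rng = np.random.default_rng(seed)
    boots = _bootstrap_theta(comps, n_boot, rng)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return FstResult("global", fs.F_ST, float(lo), float(hi), None, 0, n_boot,
                     degenerate_ci=len(comps) < 2)


def _bootstrap_theta(
    comps: list[LocusComponents], n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    L = len(comps)
    out = np.empty(n_boot)
    for t in range(n_boot):
        idx = rng.integers(0, L, size=L)
        out[t] = _theta_from_components([comps[i] for i in idx])
    return out


def pairwise_fst(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    n_boot: int = 1000,
    n_perm: int = 1500,
    seed: int | None = None,
) -> FstResult:
    """Pairwise theta with 95% bootstrap-over-loci CI and permutation p.

    The permutation null reassigns individuals at random between the two
    populations (sample sizes preserved); p uses the add-one estimator
    ``(#{theta* >= theta} + 1) / (n_perm + 1)``.
    """
    for p in (pop_a, pop_b):
        if sum(1 for q in gm.populations if q == p) < 2:
            raise ValueError(f"population {p!r} needs >= 2 individuals")
    rng = np.random.default_rng(seed)
    fs = wc_f_statistics(gm, [pop_a, pop_b])
    comps = list(fs.per_locus.values())
    degenerate = len(comps) < 2
    boots = _bootstrap_theta(comps, n_boot, rng)
    lo, hi = np.percentile(boots, [2.5, 97.5])

    idx = [i for i, q in enumerate(gm.populations) if q in (pop_a, pop_b)]
    sub_calls = gm.calls[idx]
    labels = np.array([gm.populations[i] == pop_a for i in idx])
    n_a = int(labels.sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(idx))
        lab = np.zeros(len(idx), dtype=bool)
        lab[perm[:n_a]] = True
        theta_star = _theta_permuted(sub_calls, lab)
        if theta_star is not None and theta_star >= fs.F_ST - 1e-15:
            count += 1
    perm_p = (count + 1) / (n_perm + 1)
    return FstResult(
        (pop_a, pop_b), fs.F_ST, float(lo), float(hi), perm_p, n_perm, n_boot,
        degenerate_ci=degenerate,
    )


def _theta_permuted(calls: np.ndarray, in_a: np.ndarray) -> float | None:
    comps = []
    for j in range(calls.shape[1]):
        ga = calls[in_a, j, :]
        gb = calls[~in_a, j, :]
        comp = _locus_components(
            [ga[(ga != MISSING).all(axis=1)], gb[(gb != MISSING).all(axis=1)]]
        )
        if comp is not None:
            comps.append(comp)
    if not comps:
        return None
    return _theta_from_components(comps)
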