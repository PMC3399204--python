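"""Genotype data model and allele-frequency bookkeeping.

Diploid codominant genotypes (microsatellites) for individuals grouped into
populations.  Alleles are categorical positive integers; 0 encodes a missing
call.  Missing data are excluded locus-wise: an individual with a missing call
at one locus still contributes to every other locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel allele label for a missing genotype call.
MISSING = 0


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotype calls with population labels.

    Attributes
    ----------
    individuals : list of str
        Ordered individual identifiers.
    loci : list of str
        Ordered locus names.
    populations : list of str
        Per-individual population label, parallel to ``individuals``.
    calls : ndarray of shape (n_individuals, n_loci, 2)
        Positive-integer allele labels; both entries 0 mean MISSING.
        Allele order within a genotype is not meaningful.
    """

    individuals: list[str]
    loci: list[str]
    populations: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {m}, 2)"
            )
        if len(self.populations) != n:
            raise ValueError("populations must be parallel to individuals")
        if (self.calls < 0).any():
            raise ValueError("allele labels must be non-negative integers")
        # a half-missing call is malformed: a genotype is either typed or not
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("genotype with exactly one missing allele")

    @property
    def population_set(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (individuals x loci) mask of missing genotype calls."""
        return (self.calls == MISSING).all(axis=2)

    def subset_population(self, population: str) -> "GenotypeMatrix":
        if population not in self.populations:
            raise KeyError(f"unknown population {population!r}")
        idx = [i for i, p in enumerate(self.populations) if p == population]
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in idx],
            loci=list(self.loci),
            populations=[population] * len(idx),
            calls=self.calls[idx],
        )

    def drop_individuals(self, names: set[str]) -> "GenotypeMatrix":
        idx = [i for i, ind in enumerate(self.individuals) if ind not in names]
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in idx],
            loci=list(self.loci),
            populations=[self.populations[i] for i in idx],
            calls=self.calls[idx],
        )


@dataclass
class LocusFrequencies:
    """Allele frequencies of one population at one locus."""

    frequencies: dict[int, float]
    gene_count: int  # 2 x number of non-missing genotypes

    @property
    def allele_count(self) -> int:
        return len(self.frequencies)

    @property
    def empty(self) -> bool:
        return self.gene_count == 0


@dataclass
class AlleleFrequencyTable:
    """Per (population, locus) allele relative frequencies and gene counts."""

    populations: list[str]
    loci: list[str]
    table: dict[tuple[str, str], LocusFrequencies] = field(repr=False)

    def __getitem__(self, key: tuple[str, str]) -> LocusFrequencies:
        pop, locus = key
        if pop not in self.populations:
            raise KeyError(f"unknown population {pop!r}")
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")
        return self.table[(pop, locus)]

    def to_frame(self):
        """Tidy DataFrame: one row per (population, locus, allele)."""
        import pandas as pd

        rows = []
        for (pop, locus), rec in self.table.items():
            for allele, freq in sorted(rec.frequencies.items()):
                rows.append(
                    dict(population=pop, locus=locus, allele=allele,
                         frequency=freq, gene_count=rec.gene_count)
                )
        return pd.DataFrame(
            rows,
            columns=["population", "locus", "allele", "frequency", "gene_count"],
        )

    def alleles(self, locus: str, populations: list[str] | None = None) -> list[int]:
        """Sorted union of alleles observed at ``locus``."""
        pops = populations if populations is not None else self.populations
        out: set[int] = set()
        for p in pops:
            out.update(self.table[(p, locus)].frequencies)
        return sorted(out)


def allele_frequencies(gm: GenotypeMatrix) -> AlleleFrequencyTable:
    """Tabulate per-(population, locus) allele frequencies.

    Each non-missing genotype contributes two genes; individuals missing at a
    locus are excluded from that locus only.  A population x locus cell with
    no data is flagged empty (``gene_count == 0``) and skipped downstream.
    """
    if not gm.individuals:
        raise ValueError("empty genotype matrix")
    pops = gm.population_set
    table: dict[tuple[str, str], LocusFrequencies] = {}
    pop_idx = {p: [i for i, q in enumerate(gm.populations) if q == p] for p in pops}
    for j, locus in enumerate(gm.loci):
        for p in pops:
            genes = gm.calls[pop_idx[p], j, :].ravel()
            genes = genes[genes != MISSING]
            if genes.size == 0:
                table[(p, locus)] = LocusFrequencies({}, 0)
                continue
            labels, counts = np.unique(genes, return_counts=True)
            total = int(genes.size)
            freqs = {int(a): c / total for a, c in zip(labels, counts)}
            table[(p, locus)] = LocusFrequencies(freqs, total)
    return AlleleFrequencyTable(populations=pops, loci=list(gm.loci), table=table)


def private_alleles(
    aft: AlleleFrequencyTable, focal: str, reference: list[str] | set[str]
) -> dict[str, set[int]]:
    """Alleles present in ``focal`` and absent from every reference population.

    Returns a per-locus set (possibly empty) of private allele labels.
    """
    reference = list(reference)
    for p in [focal, *reference]:
        if p not in aft.populations:
            raise KeyError(f"unknown population {p!r}")
    out: dict[str, set[int]] = {}
    for locus in aft.loci:
        focal_alleles = {
            a for a, f in aft[(focal, locus)].frequencies.items() if f > 0
        }
        for ref in reference:
            focal_alleles -= set(aft[(ref, locus)].frequencies)
        out[locus] = focal_alleles
    return out


@dataclass
class RareAlleleSummary:
    per_locus: dict[str, int]
    mean: float
    sd: float


def rare_alleles(
    aft: AlleleFrequencyTable, population: str, threshold: float = 0.05
) -> RareAlleleSummary:
    """Count alleles at frequency in (0, threshold] per locus.

    The boundary is inclusive (an allele at exactly the threshold frequency
    counts as rare).  Returns per-locus counts with their mean and standard
    deviation over loci (ddof=1, matching a mean +/- sd table entry).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    per_locus: dict[str, int] = {}
    for locus in aft.loci:
        rec = aft[(population, locus)]
        per_locus[locus] = sum(
            1 for f in rec.frequencies.values() if 0 < f <= threshold + 1e-12
        )
    counts = np.array(list(per_locus.values()), dtype=float)
    sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    return RareAlleleSummary(per_locus, float(counts.mean()), sd)


def mean_alleles_per_locus(
    aft: AlleleFrequencyTable, population: str
) -> tuple[float, dict[str, int]]:
    """Arithmetic mean over loci of the number of distinct observed alleles."""
    if population not in aft.populations:
        raise KeyError(f"unknown population {population!r}")
    per_locus = {
        locus: aft[(population, locus)].allele_count for locus in aft.loci
    }
    counted = [c for c in per_locus.values()]
    return float(np.mean(counted)), per_locus


def monomorphic_loci(aft: AlleleFrequencyTable, population: str) -> list[str]:
    """Loci at which the population shows exactly one allele."""
    return [
        locus
        for locus in aft.loci
        if aft[(population, locus)].allele_count == 1
    ]
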