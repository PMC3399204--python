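"""Closed-form effective-population-size and effective-inbreeding estimators.

Three desk calculations used to interpret island diversity loss:

* Ne from heterozygosity decline over t generations (exact inversion of the
  drift decay H_t = H_0 (1 - 1/(2Ne))^t);
* Ne from a census size via a fixed Ne/N ratio (0.1 by default, the rule of
  thumb for wild vertebrate populations);
* the effective inbreeding coefficient Fe = 1 - H_island / H_mainland, the
  cumulative inbreeding implied by an island's diversity deficit relative to
  its source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


@dataclass
class NeEstimate:
    method: str  # "het_loss" | "census_ratio"
    Ne: float
    inputs: dict


@dataclass
class InbreedingEstimate:
    Fe: float
    H_island: float
    H_mainland: float


def ne_from_het_loss(H0: float, Ht: float, t: int) -> NeEstimate:
    """Average Ne implied by a decline from H0 to Ht over t generations.

    Ne = 1 / (2 * (1 - (Ht/H0)^(1/t))).
    """
    if not 0 < H0 <= 1:
        raise ValueError("H0 must be in (0, 1]")
    if Ht <= 0:
        raise ValueError("Ht must be positive")
    if Ht >= H0:
        raise ValueError("no diversity loss (Ht >= H0): Ne unbounded")
    if t < 1:
        raise ValueError("t must be >= 1")
    ne = 1.0 / (2.0 * (1.0 - (Ht / H0) ** (1.0 / t)))
    return NeEstimate("het_loss", float(ne), {"H0": H0, "Ht": Ht, "t": t})


def ne_from_census(N: float, ratio: float = 0.1) -> NeEstimate:
    """Ne from a census estimate via the Ne/N ratio (default 0.1)."""
    if N < 0:
        raise ValueError("census size must be non-negative")
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    return NeEstimate("census_ratio", float(ratio * N), {"N": N, "ratio": ratio})


def effective_inbreeding(H_island: float, H_mainland: float) -> InbreedingEstimate:
    """Effective inbreeding coefficient Fe = 1 - H_island / H_mainland."""
    if H_mainland <= 0:
        raise ValueError("mainland heterozygosity must be positive")
    for name, h in (("H_island", H_island), ("H_mainland", H_mainland)):
        if not 0 <= h <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    fe = 1.0 - H_island / H_mainland
    if fe < 0:
        warnings.warn(
            "island heterozygosity exceeds mainland: Fe is negative",
            stacklevel=2,
        )
    return InbreedingEstimate(float(fe), H_island, H_mainland)
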