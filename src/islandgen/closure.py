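"""Tests of the population-closure assumption for capture-recapture data.

Two tests are provided, both with closure as the null hypothesis, so small
p-values suggest the population was open during sampling:

* ``closure_test_stanley_burnham`` ("Test 1"): a chi-square test combining
  per-interior-occasion 2x2 contingency components sensitive to recruitment
  (is an animal caught at occasion i new, and is it seen again afterwards?)
  and to mortality/emigration (is occasion i an animal's last, and had it
  been seen before?).  Under closure each table is independent, so the
  component chi-squares sum with one df each.
* ``closure_test_otis`` ("Test 2", the program-CAPTURE statistic): for each
  animal caught k >= 2 times, the span between first and last capture is
  compared with its expectation under random placement of k captures among
  the T occasions; the standardized sum is asymptotically normal, and
  too-short spans (animals present for only part of the study) give the
  one-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cmr import CaptureHistory


@dataclass
class ClosureResult:
    test: str
    statistic: float | None
    df: int | None
    p_value: float | None
    verdict: str


def closure_test_otis(ch: CaptureHistory) -> ClosureResult:
    """Span-based closure test from times of first and last capture.

    For an animal with k captures among T occasions, the span q = last -
    first of a uniformly random k-subset of {1..T} has
    E(q) = (k-1)(T+1)/(k+1) and
    Var(q) = 2(k-1)(T-k)(T+1)/((k+1)^2 (k+2)).
    z = (sum q - sum E)/sqrt(sum Var); p = P(Z <= z) (one-sided: short spans
    indicate lack of closure).
    """
    T = ch.n_occasions
    if T < 3:
        raise ValueError("closure test needs >= 3 occasions")
    det = ch.detections
    k = det.sum(axis=1)
    multi = k >= 2
    if not multi.any():
        return ClosureResult(
            "Otis span test", None, None, None,
            "no multiply-captured individuals: test not applicable",
        )
    occ = np.arange(T)
    first = np.array([occ[row.astype(bool)][0] for row in det[multi]])
    last = np.array([occ[row.astype(bool)][-1] for row in det[multi]])
    q = (last - first).astype(float)
    kk = k[multi].astype(float)
    e = (kk - 1) * (T + 1) / (kk + 1)
    v = 2 * (kk - 1) * (T - kk) * (T + 1) / ((kk + 1) ** 2 * (kk + 2))
    var_sum = float(v.sum())
    if var_sum <= 0:
        return ClosureResult(
            "Otis span test", None, None, None,
            "degenerate spans (all animals caught on all occasions)",
        )
    z = float((q.sum() - e.sum()) / np.sqrt(var_sum))
    p = float(stats.norm.cdf(z))
    verdict = "closure rejected at alpha=0.05" if p < 0.05 else "consistent with closure"
    return ClosureResult("Otis span test", z, None, p, verdict)


def _component_chi2(table: np.ndarray) -> float | None:
    """Pearson chi-square of a 2x2 table; None when a margin is empty."""
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return None
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def closure_test_stanley_burnham(ch: CaptureHistory) -> ClosureResult:
    """Chi-square closure test combining recruitment and mortality components.

    For each interior occasion i (2..T-1):

    * recruitment-sensitive component: animals first captured at or before i,
      classified (first capture at i vs before i) x (recaptured after i vs
      not);
    * mortality/emigration-sensitive component: animals last captured at or
      after i, classified (last capture at i vs after i) x (captured before i
      vs not).

    In each table the row classification depends only on captures on one
    side of occasion i and the column classification only on the other side,
    so under closure (captures independent across occasions given presence)
    the table shows independence and contributes one chi-square df.
    Degenerate tables (an empty margin) are dropped and the df adjusted.
    """
    T = ch.n_occasions
    if T < 4:
        raise ValueError("closure test needs >= 4 occasions")
    det = ch.detections.astype(bool)
    occ = np.arange(T)
    first = np.array([occ[row][0] for row in det])
    last = np.array([occ[row][-1] for row in det])
    seen_before = np.zeros_like(det)
    seen_before[:, 1:] = np.cumsum(det[:, :-1], axis=1) > 0
    seen_after = np.zeros_like(det)
    for j in range(T - 1):
        seen_after[:, j] = det[:, j + 1:].any(axis=1)

    stat = 0.0
    df = 0
    dropped = 0
    for i in range(1, T - 1):
        new = first == i
        old = first < i
        again = seen_after[:, i]
        t_rec = np.array(
            [
                [(new & again).sum(), (new & ~again).sum()],
                [(old & again).sum(), (old & ~again).sum()],
            ],
            dtype=float,
        )
        ends = last == i
        cont = last > i
        before = seen_before[:, i]
        t_mort = np.array(
            [
                [(ends & before).sum(), (ends & ~before).sum()],
                [(cont & before).sum(), (cont & ~before).sum()],
            ],
            dtype=float,
        )
        for tbl in (t_rec, t_mort):
            c = _component_chi2(tbl)
            if c is None:
                dropped += 1
            else:
                stat += c
                df += 1
    if df == 0:
        return ClosureResult(
            "Stanley-Burnham component test", None, None, None,
            "no informative component tables: test not applicable",
        )
    p = float(stats.chi2.sf(stat, df))
    verdict = "closure rejected at alpha=0.05" if p < 0.05 else "consistent with closure"
    if dropped:
        verdict += f" ({dropped} degenerate component tables dropped)"
    return ClosureResult("Stanley-Burnham component test", stat, df, p, verdict)
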