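# islandgen

Conservation-genetics toolkit for small, isolated populations, built around
a case study of the two island platypus (*Ornithorhynchus anatinus*)
populations off southern Australia: a recently founded island population
(≤16 founders, ~7 generations of isolation) and a long-isolated endemic one.
The package implements the full quantitative chain such a study needs:

* **Microsatellite diversity** — GenePop-dialect I/O; allele frequencies
  with locus-wise missing-data handling; observed and Nei-unbiased expected
  heterozygosity; rarefied allelic richness
  `r_g = Σ_k [1 − C(2N−N_k, g)/C(2N, g)]`; private and rare
  (frequency ≤ 0.05) alleles; exact paired signed-rank comparison of
  per-locus richness.
* **F-statistics** — Weir–Cockerham variance-components estimators of
  F_IS/F_ST/F_IT (multilocus values as ratios of summed components),
  pairwise θ with bootstrap-over-loci 95% CIs and permutation p-values;
  exact conditional Hardy–Weinberg tests (complete enumeration of genotype
  arrays where feasible, Monte-Carlo gene re-pairing otherwise), combined
  across loci by Fisher's method.
* **Closed-population mark–recapture** — Huggins conditional likelihood for
  the eight models M(0)…M(tbh) (time, permanent trap response, linear or
  quadratic individual-covariate heterogeneity on the logit scale),
  Horvitz–Thompson abundance `N̂ = Σ 1/π̂_i` with Huggins-style standard
  errors, AIC model selection, and two population-closure tests
  (a Stanley–Burnham-style chi-square component test and the
  capture-span test of program CAPTURE).
* **Drift forecasting and effective size** — Wright–Fisher multinomial
  Monte Carlo of per-locus diversity loss at constant Ne; the closed forms
  `H_t = H_0 (1 − 1/(2Ne))^t`, its inversion
  `Ne = 1/(2[1 − (H_t/H_0)^{1/t}])`, census-ratio `Ne = 0.1 N`, and the
  effective inbreeding coefficient `F_e = 1 − H_island/H_mainland`.
* **Synthetic data with known truth** — HWE/inbred genotype sampling,
  Balding–Nichols differentiated populations, founder-bottleneck histories,
  and capture-history generators for every model in the family.

## Worked example

The study's desk calculations run from printed summary statistics alone
(packaged in `islandgen.published`):

```python
from islandgen import ne_from_het_loss, ne_from_census, effective_inbreeding

ne_from_het_loss(0.597, 0.419, 7).Ne    # 10.14  — Ne from diversity decline
ne_from_census(110).Ne                  # 11.0   — Ne from census at ratio 0.1
effective_inbreeding(0.419, 0.597).Fe   # 0.30   — founded island
effective_inbreeding(0.032, 0.597).Fe   # 0.95   — long-isolated island
```

The island population lost diversity from a mainland-like H_E of 0.597 to
0.419 over about seven generations, implying an average effective size of
~10 — matching the census-based estimate of 11 (≈110 animals × 0.1) — and
an effective inbreeding coefficient of 0.30; the long-isolated island
(H_E = 0.032) is at F_e = 0.95.

The forecast continues from there (`islandgen forecast`, or
`analysis/04_forecast.py`), running 1000 Wright–Fisher replicates over 13
loci at Ne = 11 from a frequency table calibrated to the mainland summary
(mean H_E 0.597, 9.0 alleles/locus):

```text
Ne from heterozygosity decline: 10.14
Ne from census x 0.1: 11.0
effective inbreeding, founded island: 0.30
effective inbreeding, long-isolated island: 0.95
mean diversity after 50 generations: 0.059 (alleles 1.17)
```

i.e. within 50 generations the founded island's mean expected
heterozygosity is forecast to collapse to ~0.06 with most loci fixed —
approaching the state of the long-isolated population.

## Analysis chain

Numbered drivers under `analysis/` replay the study end to end on a
synthetic corpus with known truth (the real genotypes and capture histories
were never deposited), writing tables under `results/`:

1. `01_simulate_data.py` — mainland/regional genotypes, a founder-bottleneck
   island, and two sex-specific capture surveys at the study's scale.
2. `02_diversity.py` — diversity summary table, private/monomorphic alleles,
   pairwise θ with CIs, richness signed-rank test.
3. `03_abundance.py` — closure tests, the 9-model AIC table per sex,
   study-area and island-wide abundance.
4. `04_forecast.py` — Ne/F_e report and the drift forecast.

A `click` CLI (`islandgen diversity|cmr|forecast|simulate-fixtures|
replicate-study`) exposes the same steps on user files.

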