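# Methods

This note records the models implemented, the conventions and numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the problem sizes used by the test suite.

## Genotype model and diversity statistics

Genotypes are unordered pairs of categorical integer alleles at each of L
microsatellite loci (13 in the island case study); `0` encodes a missing
call, and a genotype is either fully typed or fully missing. Missing data
are excluded **locus-wise**: an individual missing at one locus still
contributes everywhere else. Repeat-motif lengths are not used — no
stepwise-mutation analysis is performed — so allele labels are purely
categorical and every statistic is invariant to relabeling.

* **Observed heterozygosity** H_O: share of non-missing genotypes that are
  heterozygous, averaged over loci.
* **Expected heterozygosity** uses Nei's unbiased estimator
  H_E = [2n/(2n−1)](1 − Σ p_k²) with n the locus-wise genotype count. The
  correction matters at the study's sample sizes (n = 12–21 on the
  islands).
* **Allelic richness** is rarefaction to a standard number of genes g:
  r_g = Σ_k [1 − C(2N−N_k, g)/C(2N, g)], evaluated in exact integer
  arithmetic. When g is not given it defaults to the smallest locus-wise
  gene count among the populations being compared (the convention that
  makes richness comparable across unequal samples). Richness is
  non-decreasing in g and equals the observed allele count at g = 2N.
* **Rare alleles** are counted at frequency in (0, 0.05], boundary
  inclusive; the summary reports the per-locus mean ± sd (ddof = 1).
* **Private alleles** of a focal population are alleles with positive
  frequency there and zero frequency in every reference population,
  reported per locus.

### F-statistics

The Weir–Cockerham (1984) moment estimators are computed from
per-allele variance components a (among populations), b (among individuals
within populations) and c (within individuals), with locus-wise sample
sizes. Multilocus estimates are ratios of components **summed** over
alleles and loci (ratio of averages), not averages of per-locus ratios.
Loci monomorphic across all included populations are excluded; if no locus
is informative the estimate is undefined and an error is raised (a
population of clones has no defined F_IS). With a single population only
F_IS is defined (the a component needs ≥ 2 populations).

Pairwise θ carries a 95% CI from 1000 bootstrap resamples of loci
(percentile method over the recomputed component ratios) and a permutation
p-value from 1500 random reassignments of individuals between the two
populations, using the add-one estimator (#{θ* ≥ θ}+1)/(n_perm+1) so p is
never zero. Whether the original study's CIs were bootstrap-over-loci is
not documented; bootstrap-over-loci is this package's choice and is stated
in the output header.

### Hardy–Weinberg exact tests

The test conditions on allele counts: the probability of a genotype-count
array {n_kl} is n! 2^h Π m_k!/((2n)! Π n_kl!). When at most 10⁶ arrays are
compatible with the allele counts they are enumerated completely and the
p-value is the exact tail mass of arrays no more probable than the observed
one (two-sided by probability ordering). Beyond that, the conditional
distribution is sampled by randomly re-pairing the 2n genes — each shuffle
is an independent draw from the exact null, avoiding the mixing diagnostics
a Markov-chain sampler would need — with the add-one estimator and a fixed
seed. The per-population HWE p combines locus-wise tests over polymorphic
loci with Fisher's method; the combination rule behind the study's single
per-population p-value is undocumented, so Fisher is this package's
documented choice. Exact-test p-values are discrete, which makes the
Fisher combination mildly conservative.

### Signed-rank comparison of richness

Per-locus richness vectors of two populations are compared with a paired
two-sided Wilcoxon signed-rank test. Zero differences are dropped; for up
to 25 informative pairs the exact null distribution of the rank sum is
built by dynamic programming over doubled midranks (ties allowed), with
p = 2·min(lower tail, upper tail) capped at 1; beyond 25 pairs a normal
approximation with tie correction is used. scipy's exact path refuses tied
ranks, hence the in-house enumeration; the two agree exactly on tie-free
input.

## Closed-population mark–recapture

Capture histories are binary detection matrices over ordered occasions;
only animals detected at least once are observed, and per-individual
covariates (e.g. body weight) are taken at first capture and treated as
constant. Occasions can be pooled (logical OR) to avoid sparseness, and
covariates are z-scored with denominator n; the transform parameters are
stored for reproducibility.

Capture probabilities are inverse-logit linear predictors with, depending
on the model cell: T−1 time dummies against occasion 1; a permanent
trap-response indicator (any prior capture) that enters **only** recapture
probabilities, since an uncaptured animal cannot have responded; and one or
two covariate terms (linear/quadratic heterogeneity). The 2×2×2 grid gives
M(0), M(t), M(b), M(h), M(tb), M(th), M(bh), M(tbh), plus the quadratic
M(h) variant.

The conditional (Huggins) likelihood is
Π_i Π_j p_ij^{y_ij}(1−p_ij)^{1−y_ij} / π_i with
π_i = 1 − Π_j(1 − p̃_ij) built from first-capture probabilities p̃.
Abundance is Horvitz–Thompson, N̂ = Σ 1/π̂_i ≥ D, with variance
Σ(1−π̂_i)/π̂_i² plus a delta-method term over the observed-information
covariance of the coefficients. Optimisation is BFGS with an analytic
gradient from the intercept at the logit of the naive capture fraction
(other coefficients 0) plus two seeded jittered restarts; gradient
tolerance 10⁻⁸; the Hessian for the covariance is a central difference of
the analytic gradient. Fits with any first-capture probability above 0.999
are flagged as boundary cases (e.g. every animal caught on every occasion,
where N̂ = D exactly). Model selection is minimum AIC among converged fits,
ties broken by fewer parameters and then by the canonical model order.

### Closure tests

Two tests with closure as the null:

* **Component chi-square test** (Stanley–Burnham style). For each interior
  occasion i, two 2×2 tables: among animals first captured at or before i,
  (first capture at i vs before) × (recaptured after i vs not); and among
  animals last captured at or after i, (last capture at i vs after) ×
  (captured before i vs not). In each table the rows depend on captures on
  one side of i only and the columns on the other side, so closure implies
  independence; Pearson chi-squares are summed, one df per non-degenerate
  table (empty-margin tables are dropped and the df adjusted). Exact
  agreement with the original program cannot be verified without the
  study's data; the test is validated by simulation (type-I error 0.072 at
  α = 0.05 over 500 closed M(0) datasets; power 0.5–0.8 under strong
  permanent emigration).
* **Capture-span test** (the program-CAPTURE statistic). For each animal
  with k ≥ 2 captures, the span between first and last capture is compared
  to its expectation under a uniformly random k-subset of the T occasions
  (E = (k−1)(T+1)/(k+1), Var = 2(k−1)(T−k)(T+1)/((k+1)²(k+2)), both
  verifiable by enumeration at small T); the standardized sum is treated as
  normal and the one-sided lower tail (short spans = transient animals)
  gives p.

The open-population (Jolly–Seber family) likelihood is out of scope: when
the two tests disagree, the pipeline reports both and proceeds with closed
models under an explicit caveat in the verdict text.

## Drift simulation and closed-form estimators

Each locus evolves independently by multinomial resampling of 2Ne genes per
nonoverlapping generation — no mutation, migration, selection, or varying
Ne. Within the simulator, diversity is gene diversity 1 − Σp² without the
small-sample correction, because the in-model frequencies are exact and the
recursion E[H_{t+1}] = (1 − 1/(2Ne)) E[H_t] then holds exactly; this is
what makes the closed form H_t = H_0(1 − 1/(2Ne))^t a strict oracle for the
engine. Summaries per generation are means over loci and replicates with
empirical 2.5/97.5-percentile envelopes across replicates of the
locus-mean. Allele counts are non-increasing per replicate, and allele
frequencies are martingales (fixation probability equals the initial
frequency) — both tested.

The default initial table is a deterministic 13-locus construction
calibrated to the mainland summary (mean gene diversity exactly 0.597,
per-locus allele counts averaging 9.0 with one monomorphic locus): each
polymorphic locus has one major allele and K−1 equally frequent minor
alleles, with the major frequency solved per locus so that the locus
diversities share a common scaling of their 1 − 1/K ceilings. The real
frequency table behind the study was never published; only this
summary-level calibration is possible, and conclusions that depend on the
shape of the frequency spectrum (e.g. exact allele-count trajectories)
inherit that uncertainty.

The closed-form estimators: Ne = 1/(2[1 − (H_t/H_0)^{1/t}]) exactly inverts
the decay (round-trip identity to 10⁻⁹ relative tolerance across
Ne ∈ [1, 10⁴], t ∈ [1, 100]); census-ratio Ne = ratio × N with ratio 0.1 by
default; effective inbreeding F_e = 1 − H_island/H_mainland, negative (with
a warning) if the island exceeds the mainland. The generation count is a
user input; the case study's t = 7 (~70 years at a ~10-year generation
time) is a documented default, and using today's mainland H_E as the
founder-stock H_0 is an assumption the data cannot validate.

## Synthetic-data generators

* Genotypes: two genes per locus per individual from the population
  frequencies; with inbreeding F_IS the second gene copies the first with
  probability F_IS, giving exactly the target heterozygote deficit in
  expectation.
* Differentiated populations: per-locus Dirichlet draws around ancestral
  frequencies with concentration (1−F)/F (Balding–Nichols), then HWE
  sampling. At F = 0.25, 2×200 individuals and ~20 loci, the
  Weir–Cockerham estimate recovers the target within [0.15, 0.35] in ≥95%
  of seeds.
* Founder bottleneck: 2·n_founders genes sampled per locus from the source
  (founders as a simple random sample of genes — no family structure, as
  only founder counts are documented for the case study), Wright–Fisher
  drift at Ne for t generations, then a final HWE sample. The default
  scenario (16 founders, Ne 11, t 7) has expected final diversity
  0.597·(1 − 1/32)·(1 − 1/22)⁷ ≈ 0.418, reproduced by simulation.
* Capture histories: all N animals simulated under the chosen model cell
  (standard-normal covariates, matching the z-score convention), then
  conditioned to detected animals, with truth metadata returned separately
  so data files stay format-pure.

What the generators do **not** emulate: mutation, migration and selection;
linkage between loci; null alleles and genotyping error; age structure,
temporary emigration and covariate drift in the capture surveys. Passing
recovery tests therefore demonstrates correctness of the estimators under
their own assumptions, not robustness to these real-data complications.

## Problem sizes and runtime choices

The default test run keeps simulations at sizes that make the statistical
assertions sharp but cheap: drift calibration at 1000 replicates × 13 loci
× 50 generations (closed-form agreement within 3 Monte-Carlo SEs at
t ∈ {1, 7, 25, 50}); abundance recovery at 200 replicates per generating
model with N = 200, T = 10 (|relative bias| < 10%, Wald-interval coverage
in [0.90, 0.98]); closure-test calibration at 500 closed and 150 open
datasets; differentiation recovery over 100 seeds; and exact-test
cross-checks on enumerable tables (Monte-Carlo vs enumeration within 3
binomial SEs at 10⁵ draws). All stochastic procedures take explicit seeds
and are bit-reproducible.

## Known limitations

* The component closure test is a reconstruction from the published test
  structure, not a port of the original program; only its operating
  characteristics are guaranteed (by simulation), not statistic-for-
  statistic parity.
* Heterogeneity is covariate-driven only; latent-class or random-effect
  heterogeneity (mixture M(h)) is not implemented, mirroring the study's
  covariate-based models.
* The HWE Monte-Carlo p-value has sampling error ~(p(1−p)/n_steps)^½;
  headers record the step count so users can tighten it.
* Bootstrap-over-loci CIs are unreliable with very few polymorphic loci;
  such results are flagged degenerate rather than suppressed.
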