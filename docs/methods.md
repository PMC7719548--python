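# Methods

## The cline model

Allele frequency along the transect is modelled by the symmetric
two-parameter sigmoid `p(x) = ½(1 + tanh(2(x − c)/w))`. The width
convention is `w = 1/max slope` (the slope at the center is exactly `1/w`),
which is the standard hybrid-zone parameterization; the model is
algebraically identical to the logistic `1/(1 + e^{−4(x−c)/w})`. We fit
center and width only — no introgression tails, no asymmetry — because at
the ~25-site sampling density of a typical transect a stepped cline is not
identifiable, and the downstream width test consumes only `w`.

**Likelihoods.** For allele data the site log-likelihood is
`k log p(x) + (n − k) log(1 − p(x))` with `p` clipped to `[1e−12, 1−1e−12]`
to keep fixed sites finite. For continuous indices (plumage hybrid index,
genomic EV1 min–max rescaled to [0, 1], occidentalis side at 0) the model
is `y_site ~ N(p(x), τ²)` with `τ²` profiled out, so the MLE is the
least-squares fit and the reported log-likelihood uses `τ̂² = RSS/m`.

**Optimization.** The likelihood surface is multimodal under sparse
sampling (a very narrow cline between two adjacent sites can tie with a
broad one), so we run bounded L-BFGS-B from eight deterministic starts:
centers at the 25/50/75% position quantiles crossed with widths at
{0.1, 0.5, 1} × the sampled span (two redundant combinations dropped).
Bounds are center within half a span beyond the data and width in
`[max(1e−3, 1e−4·span), 20·span]`. Bootstrap refits warm-start from the
full-data MLE plus two spread starts; with fewer starts per refit the
bootstrap stays affordable without losing the mode in practice
(replicate-level failures are dropped, counted, and >20% aborts).

**Bootstrap and the width test.** Uncertainty comes from site-level
resampling (sites, not individuals, are the exchangeable unit along a
transect; epochs are resampled independently). For the cline parameters we
report basic (bias-reflecting) bootstrap intervals rather than plain
percentile ones: with only a handful of sites inside the transition,
resamples that omit them collapse toward degenerate narrow widths, shifting
the bootstrap distribution below the estimate, and in replicated
simulations at the default sampling scale the percentile width interval
covered the generating width in only ~72% of datasets versus ~93% for the
basic interval (the width MLE itself is essentially unbiased). The
width-change statistic `w₂² − w₁²` keeps the plain percentile interval,
whose one-sided error rates calibrate correctly in the same simulations.
The neutral expectation for the change in squared width over Δt generations
is `2πσ²Δt`, from the neutral-diffusion cline growth law `w(t) = √(2πσ²t)`.
σ (dispersal, km·gen^−1/2) and Δt are user inputs — they come from
demographic knowledge of the system, not from the genetic data. The
"less than neutral" verdict fires iff the upper 95% bound of `w₂² − w₁²`
falls below `2πσ²Δt`; with a two-sided percentile interval this is a
one-sided test at nominal level 2.5%.

Degenerate inputs: fewer than 3 sites or an all-constant frequency profile
is an error; a frequency span ≤ 0.2 warns (width weakly identified) but
proceeds.

## Weir–Cockerham F_ST

Per biallelic SNP we compute the 1984 two-level variance components for
two populations of unequal size from genotype counts: `a` (among
populations), `b` (among individuals within populations) and `c` (within
individuals, = h̄/2), using the observed heterozygote frequency, and
θ = a/(a+b+c). Loci with fewer than two called diploids in either
population are skipped and counted. Negative per-locus θ is retained —
truncation would bias the genome-wide average, which is the ratio of sums
Σa/Σ(a+b+c). Windows tile each contig from position 1 in half-open
`[start, start+10000)` intervals of 1-based coordinates (so position 10000
belongs to the first window); the window statistic defaults to the same
ratio of sums, with a per-locus mean available as an option because the
two conventions coexist in the literature.

## PCA and kinship

Genomic PCA mean-imputes missing dosages, centers each locus at `2p̂` and
by default standardizes by `√(2p̂(1−p̂))`, then takes the SVD of the
individual × locus matrix; scores are `U·S`, and percent variance is taken
over the full computed spectrum. Axis 1 is oriented so
occidentalis-labelled individuals score low (EV1 is then a genomic hybrid
index); other axes get a deterministic sign. The frequency-weighted
kinship option is exactly the Gram matrix of the same standardized data,
so the PCA axes and the structure-correction axes used by the GWAS are one
computation — a deliberate single source of truth, verified by a test.
The unweighted kinship is plain mean IBS allele sharing
`1 − |g_i − g_j|/2` over loci called in both individuals.

## Association scan

Trait and per-locus dosage are residualized on an intercept plus the top
`n_axes` PCA eigenvectors (default 3 — enough to absorb the dominant
ancestry gradient of a two-taxon zone; exposed as a flag) and tested with
`χ² = (n − n_axes − 1)·r²` where `r` is the residual–residual correlation.
With `n_axes = 0` this reduces to the classic trend score test
`(n − 1)·r²`. Missing dosages are mean-imputed per locus so `n` is stable
across loci; loci with minor-allele count < 2 are excluded from the scan
and from λ estimation (a monomorphic locus gets χ² = 0 with a flag, not an
error). Genomic-control λ defaults to the regression estimator (slope
through the origin of sorted observed χ² on expected 1-df quantiles), with
the median/0.455 estimator as a robustness check; correction divides by
`max(λ, 1)` by default so deflation never manufactures significance, and λ
itself is always reported unclipped. Per-locus variance explained is the
plain squared Pearson correlation of dosage and trait on complete cases;
a structure-corrected r² is what the residualized statistic already
encodes, so the plain scale is reported to match how effect sizes are
usually quoted.

## Dominance

`h = (Z̄_TT − Z̄_OT)/(Z̄_TT − Z̄_OO)` on complete cases, unclamped (sampling
noise can push it outside [0, 1]; clamping would bias the bootstrap
distribution). The bootstrap resamples individuals from the pooled sample,
matching the usual practice; stratified-by-class resampling is available
as a sensitivity flag. Bootstrap iterations that empty a class or equalize
the homozygote means are redrawn, capped at 10× the requested iterations,
with >50% degeneracy aborting — the point estimate is then too fragile to
interval.

## The synthetic zone generator

The generator emulates the statistical structure of a two-species songbird
hybrid zone, not its biology:

* **Transect and sampling.** 25 sites every 20 km over 1000–1480 km, 12
  diploids per site per epoch (600 total), two epochs with freshly drawn
  individuals — the width test only consumes per-epoch frequencies, so no
  pedigree links the epochs.
* **Background loci** (default 2000, on one synthetic contig at 1-kb
  spacing): ancestral frequency Uniform(0.05, 0.95), end-population
  frequencies `p ± f√(p(1−p))` with the spread `f` calibrated by a short
  pilot Monte-Carlo (3 iterations of simulate–measure–rescale against the
  Weir–Cockerham weighted average) to hit the background F_ST target of
  0.03 between the transect ends. Each background locus follows a wide
  cline (width 112 km) between its end frequencies, so the genomic hybrid
  index also clines. Because the parental-labelled pools span several
  near-end sites rather than the exact ends, their realized F_ST sits
  slightly below the end-to-end target (~0.025) — accepted as faithful to
  how real parental samples are pooled.
* **Island loci** (default 1, on a second contig): frequency exactly on
  the sigmoid cline, center 1216 km and width 42 km in epoch 1 — the scale
  of a narrow selected cline. Epoch 2 keeps that width by default (the
  selection scenario); with `neutral_widening` the epoch-2 width obeys
  `w₂² = w₁² + 2πσ²Δt` exactly. Defaults σ = 20 km·gen^−1/2 and Δt = 3
  give a neutral expectation of ≈7540 km², the magnitude relevant to a
  decades-apart resampling of a passerine zone; both are free parameters
  since dispersal is external knowledge.
* **Traits.** Four continuous traits (crown, cheek, breast, flank) driven
  by the causal island locus with dominance h = 0.810, 0.908, 0.557, 0.345
  and variance-explained targets 0.60, 0.57, 0.49, 0.59 — the "opposing
  dominance" configuration of one locus pulling different traits toward
  different parents. Class means are (0, 1−h, 1); Gaussian noise variance
  is solved so the squared Pearson correlation between dosage and trait
  equals the r² target in a Hardy–Weinberg p = ½ reference population
  (dominance caps the attainable linear r², and an impossible target is
  rejected). Traits are conditionally independent given the causal
  genotype. In the zone sample itself genotypes are bimodal, so realized
  zone-sample r² runs higher than the balanced-reference target — expected
  and documented rather than corrected.
* **Missingness** is uniform at rate 0.05 (GBS-like), applied after trait
  generation so phenotypes reflect the true genotype.
* **Determinism.** One integer seed; five named substreams
  (frequencies, genotypes, traits, missingness, pilot calibration) via
  `SeedSequence.spawn`, so runs are bit-identical.

What the generator does **not** emulate: linkage disequilibrium and its
decay (loci are conditionally independent given location), low-coverage
genotype uncertainty, trait covariance beyond the shared locus, spatially
structured missingness, and drift between epochs. Passing tests therefore
validate the estimators under clean sampling noise, not robustness to
those real-data complications.

## Problem sizes and numerical choices

Default analyses run at 300 individuals × 2001 loci; bootstrap defaults
are 1000 replicates for cline CIs (the replicate count is not critical;
tests use 200) and 10,000 for dominance. Replicated calibration
experiments in the test suite use 50 dataset replicates, the smallest
count at which the targeted 80–95% rates are stable. Optimizer and
likelihood tolerances are the scipy defaults; ties in allele orientation
break toward no flip with a warning.

## Known limitations

* The two-epoch width test assumes the same transect geometry in both
  epochs and treats σ²Δt as known; uncertainty in dispersal is not
  propagated.
* The gaussian cline likelihood weights all sites equally rather than by
  site sample size.
* The association scan handles continuous traits only, with a
  fixed-effect axis correction rather than a mixed model.
* F_ST operates on called genotypes; there is no genotype-likelihood mode
  for low-depth data.
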