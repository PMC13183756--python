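# Methods

`vocalib` models how a voice-type classifier distorts per-speaker
vocalization counts in long-form child audio recordings, and uses that model
either to *calibrate* downstream analyses (treating the true counts as
latent and inferring them jointly with the scientific parameters) or to
*simulate* the distortion for sensitivity analysis and null-hypothesis
testing.  This note documents the models, the priors and defaults, the
sampler, the synthetic-data generator, and the numerical choices, in enough
detail to reproduce or modify any of them.

## 1. The count law

The number of detections a classifier attributes to class *j* because of
one true vocalization of class *i* is not 0/1: detections can be missed,
misattributed, or split into several segments.  We therefore use Efron's
double (generalized) Poisson distribution, `DPO(m, tau)`, with mean `m` and
variance `m/tau`, which covers both over-dispersion (`tau < 1`) and
under-dispersion (`tau > 1`) and reduces exactly to Poisson at `tau = 1`.

Implementation: Efron's density with the `0^0 := 1` convention at `y = 0`,
renormalized by truncated summation.  The truncation window is
`mean ± 16·sd + 30`, which keeps the neglected tail mass below `1e-12`
(verified against full summation in the test suite).  Renormalization
shifts the distribution's mean away from the raw density parameter — by
about 1% at `(m=5, tau=0.5)` and by more than 20% for small means under
over-dispersion — which would silently distort small confusion rates and
every closed-form mean prediction.  We therefore *mean-calibrate* the
distribution: the raw parameter is solved (vectorized Newton iteration
using the identity `d mean / d raw = tau·var/raw`, with a monotone
bisection fallback for extreme under-dispersion where the mean is nearly a
step function of the raw parameter) so that the realized mean equals the
nominal `m` exactly.  At `tau = 1` the calibration is the identity.  The
realized variance remains `m/tau` only approximately (within ~5% at
moderate means; exact values are whatever the renormalized density gives).

## 2. Model of the classifier's behavior

True counts `v_i` (i ∈ {CHI, OCH, FEM, MAL}) generate per-cell detection
counts `n_ij ~ DPO(lambda_ij · v_i, tau)`, independently across cells; only
the column totals `n_j = Σ_i n_ij` are observed.  `lambda` is the
confusion-rate matrix: diagonal entries are recall-like true-positive
rates, off-diagonal entries misattribution rates.  Rates vary across
recordings: `lambda_kij ~ Gamma(mean mu_ij, shape alpha_ij)`, independent
across cells (the model specifies marginals only; within-recording
correlation of cells is not modeled).

Two likelihoods are used:

* **Annotated 15-s windows** (true `v` known): the exact marginal of the
  observed total sums over all decompositions `{n_ij ≥ 0 : Σ_i n_ij = n_j}`.
  Because sources are independent and the sum factorizes over target
  classes, this equals the convolution of the four per-source DPO pmfs
  evaluated at the total — `O(C·n²)` instead of explicit enumeration.
  Windows are capped at 40 counts per class (15-s windows stay far below
  this); beyond the cap the likelihood refuses rather than approximates.
* **Whole recordings** (`v` latent): the total is modeled directly as
  `n_j ~ DPO(Σ_i lambda_ij·v_i, tau)` with `v` continuous.  This matches
  the exact form in mean and variance and coincides with it in the
  single-source limit (verified to 2% in tests).

Priors: `mu_ij ~ half-normal(1)`; `alpha_ij ~ Pareto(1, 1.5)` truncated to
`alpha ≥ 1`; a single dispersion `tau ~ half-normal(1)` shared across
cells.  The Gamma shapes' Pareto prior and the ≥1 truncation bound the
rate variability; the `mu` and `tau` priors are weakly-informative choices
of this package (rates near 0–1.5 are plausible for diarization systems).

## 3. Model of speech behavior

Expected counts per recording follow a log-link GLM with a
population/corpus/child hierarchy:

```
log rate_ks = mu_pop_s + corpus_dev_{c(k),s} + child_dev_{ch(k),s}
            + 1{s=OCH}  · beta_sib_och · sib_ch
            + 1{s∈ADU}  · beta_sib_adu · sib_ch
            + 1{s=CHI}  · (alpha_ch + beta_dev · ail_ch) · min(age_k, 24)/24
alpha_ch ~ Normal(alpha_dev, sigma_dev)
```

with `corpus_dev ~ N(0, sigma_corpus²)`, `child_dev ~ N(0, sigma_child²)`
(sampled non-centered).  Children are equivalent at birth and diverge
log-linearly with age up to a fixed plateau at 24 months.  `sib` is a
binary any-siblings indicator by default (a count-coded variant is a
configuration switch).  Counts around the GLM mean are gamma-Poisson
(negative binomial) with dispersion `phi` (variance `r + r²/phi`); the
count law is isolated in one function so it can be swapped.

**Adult-input covariate.** The long-term input effect `beta_dev` multiplies
a child-level covariate `ail_ch`: the deviation of the child's expected
adult (FEM+MAL) log-rate from the population expectation, divided by
`sqrt(sigma_corpus² + sigma_child²)`.  We deliberately standardize against
the model's own conditional expectation rather than z-scoring across the
sampled children: batch z-scoring couples every child's likelihood through
the sample mean/SD (breaking the conditional independence the sampler
exploits) and makes the generative model depend on who else was sampled.
The covariate is therefore only *approximately* unit-scale (its realized
SD is ~0.7–0.8), which is acceptable for an effect on a N(0,1) prior.

Priors: effects `~ N(0,1)`; hierarchy SDs `~ half-normal(1)`; population
log-rates `~ N(4, 3)`; `log phi ~ N(2.3, 1)`.

Defaults of the generator (`BehaviorParams`): population rates
(55, 25, 90, 35) for (CHI, OCH, FEM, MAL) per recording — a reference
observation window of roughly one hour of daytime home audio;
`sigma_corpus = 0.2`, `sigma_child = 0.3`; `beta_sib_och = 1.1` (children
with siblings hear much more other-child speech), `beta_sib_adu = −0.22`
(~20% less adult input); `alpha_dev = 0.7` (output roughly doubles by the
24-month plateau), `sigma_dev = 0.25`; `beta_dev = 0.15`; `phi = 10`.
Corpora default to six (the study design this mirrors pooled six corpora);
children are assigned round-robin; ages are longitudinal (random start in
3–30 months, recordings 3 months apart); sibling counts follow
(0.45, 0.35, 0.20) over {0, 1, 2}.

## 4. Joint inference

Three fits share one blocked adaptive Metropolis-within-Gibbs engine:

* `fit_confusion` — confusion profile from annotated windows only.
* `naive_fit` — behavior model with classifier counts plugged in as truth
  (the uncalibrated comparator).
* `fit_joint` — the calibrated fit: for every recording the true counts
  `v_k` are latent (log-parameterized, hence strictly positive), informed
  from above by the behavior model (the moment-matched continuous Gamma
  relaxation of the negative binomial, shape `r·phi/(phi+r)`) and from
  below by the classifier's output through the recording-level count
  likelihood; the confusion hyperparameters are learned simultaneously
  from calibration windows, or held fixed at a known profile
  (`fix_confusion=`) for coverage studies conditioned on the classifier.

**Sampler.** No gradient-based probabilistic-programming backend is used;
inference runs on random-walk Metropolis with the following structure,
which in our experiments is what makes these posteriors tractable:

* *Elementwise-parallel blocks*: conditionally independent units
  (recordings, children, confusion cells) are proposed and accepted in one
  vectorized pass.
* *Non-centered confusion rates*: `lambda_kij = mu_ij · g_kij` with
  `g ~ Gamma(alpha, alpha)`, so the population means feel the likelihood
  directly.
* *Adaptive covariance* (Haario-style) proposals for the four
  per-target-class `mu` column blocks and for the 12 correlated global
  behavior parameters.
* *Interweaving (ASIS) moves* along known posterior ridges, all
  likelihood-invariant or nearly so: `mu_ij ↔ g_·ij` scale moves;
  per-recording `v_ki ↔ g_ki·` scale moves; global per-source
  `v_·i ↔ mu_i· ↔ mu_pop_i` row-scale moves; hierarchical location shifts
  (`mu_pop ↔` deviation means, `alpha_dev ↔` slope means) and scale shifts
  (each hierarchy SD against its deviations); and a dispersion move that
  rescales the latent counts' deviations when `phi` moves.
* *Prior-refresh independence proposals* for single `mu` cells (the
  half-normal prior is the proposal, so weakly identified cells can jump
  their heavy tails).
* Latent counts update per (recording, class) with individually adapted
  steps plus a joint 4-vector proposal per recording; chains start from
  overdispersed moment estimates so pooled chains expose, rather than
  hide, incomplete exploration.

Proposal scales adapt only during warmup (Robbins–Monro); after warmup the
chain is a fixed-kernel Markov chain.  Defaults are 4 chains of 1000
warmup + 1000 sampling sweeps; every fit reports split-R̂ and bulk ESS
(via arviz) for all stored parameters and flags the result if R̂ exceeds
1.05 on the headline parameters.  All fits are exactly reproducible given
(seed, chains, iterations).

**Numerical fast paths.** The samplers evaluate the DPO normalization
constant and mean calibration through a per-dispersion interpolation table
(log-spaced grid, linear interpolation in log-mean; error < 5e-4 nats,
tested), rebuilt via warm-started Newton whenever `tau` moves.  The window
convolution and recording-level likelihood have numba kernels that are
numerically identical to the numpy reference paths (tested to 1e-10); the
public likelihood functions always use the exact Newton path.

## 5. Synthetic data and what it does (not) show

The generator produces: (a) calibration windows — true 15-s counts Poisson
around per-class means (1.2, 0.5, 1.8, 0.8), classifier counts via a
per-recording rate draw and the DPO cell model; (b) full corpora — the
behavior model end to end, with a truth sidecar for scoring.  Two bundled
profiles mimic the qualitative behavior of common classifiers: a
*recall-biased* profile (high diagonals, non-negligible confusion between
acoustically close classes, consistent rates) and a *precision-biased* one
(fewer false positives, lower recall, more variable rates).  Their numeric
values are synthetic.

Because generator and model share the same structure, passing tests show
that the inference machinery is correct and well calibrated *under the
assumed model*, at the simulated scale.  They do not show that real
classifiers satisfy the model (e.g., linear additivity under overlapping
speech, covariate-independent confusion rates, a reliable human ground
truth), nor do they validate the specific numeric profiles.

## 6. Validation experiments (sizes used)

The acceptance tests run scaled-down versions of the validation loop; the
sizes are deliberate choices balancing statistical resolution against a
single-CPU test run:

* **Count-law exactness**: Poisson reduction to 1e-8; renormalization to
  1e-10; moments of 1e5 draws at `(m=5, tau=0.5)` within 4 MC SEs.
* **Marginal likelihood**: equality with exhaustive decomposition
  enumeration to 1e-10 on five fixed cases; agreement with frequencies
  from 1e6 simulated replicates within 3 MC SEs.
* **Confusion recovery**: 20 replicate fits on 300 windows (10 recordings
  × 30), 2 chains × (400+400); pooled 95% CI coverage of the 16 mean
  rates tested against nominal by a one-sided binomial test.
* **Latent-count coverage**: 20 simulated datasets (10 children × 2
  recordings, parameters drawn from a documented plausible prior, known
  recall-biased profile), joint fit conditioned on the profile at
  2 chains × (900+900); empirical coverage at levels {0.5, 0.8, 0.9,
  0.95} within 3 binomial SDs.  Coverage is sensitive to chain length
  here: halving the chains reproducibly under-covers by ~2 points, which
  is why these settings are larger than elsewhere.
* **Bias and repair**: 20 replicate corpora (50 children × 3 recordings)
  through an adversarial profile (CHI↔FEM confusion 0.25, OCH→adult
  leakage 0.2/0.1), calibration windows 15 recordings × 24; naive at
  2 × (400+400), joint at 2 × (450+450).
* **Distortion mechanisms**: the spurious CHI~FEM correlation (400 units,
  299-replicate Monte-Carlo null) and the fixed-adult-total proportion
  experiment (2000 samples, fresh rate draw per sample).

## 7. Known limitations

* The continuous relaxations (Gamma for the latent counts, single-DPO for
  the recording totals) are approximations; their error is visible as a
  ~1-point coverage deficit at short chain lengths and small counts.
* `alpha` (rate-consistency shapes) and `tau` mix more slowly than the
  rates themselves; their posteriors need longer chains than the headline
  effects, and fits flag this honestly via R̂.
* One classifier per fit; multi-classifier joint integration, covariate-
  dependent confusion rates, annotation-aggregation models, temporal/turn
  structure, and correcting individual segment labels are out of scope.
* The 24-month plateau is a fixed constant, not estimated.
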