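# vocalib

Bayesian calibration of classifier-derived vocalization counts from
long-form child audio recordings.

## The problem

Daylong recordings from child-worn devices are annotated by automatic
voice-type classifiers that attribute each detected vocalization to one of
four speaker classes — the key child wearing the device (CHI), other
children (OCH), female adults (FEM) and male adults (MAL).  These
classifiers miss vocalizations, split them, and confuse speakers.  Such
errors do not average out: speech from one class leaking into another
distorts measured speech quantities (e.g., the share of female adult
input), manufactures correlations between speakers that do not exist, and
biases effect sizes (e.g., how siblings change adult input, or how output
grows with age).  `vocalib` is for researchers who analyze per-speaker
vocalization counts and want to know — and correct — what classification
errors do to their conclusions.

## The model

The classifier's behavior: each true vocalization of class *i* yields a
double-Poisson number of detections attributed to class *j*,

    n_ij ~ DPO(λ_ij · v_i, τ),        n_j = Σ_i n_ij observed,

where λ is the recording-specific confusion matrix, itself drawn per
recording from Gamma(mean μ_ij, shape α_ij).  On human-annotated 15-s
windows (where the true counts v are known) the likelihood of the observed
totals marginalizes the unobserved decomposition exactly; at the recording
level the true counts are treated as continuous latent variables with
n_j ~ DPO(Σ_i λ_ij v_i, τ).

Speech behavior: a hierarchical log-link GLM for expected counts per
recording, with population/corpus/child levels, sibling effects on
other-child and adult speech, a child-specific age slope that plateaus at
24 months, and a long-term effect of adult input on the child's output.

Calibration couples the two: the posterior over behavior parameters θ,
confusion (nuisance) parameters ν, and latent true counts is explored
jointly, so classifier counts inform the latent truth rather than being
mistaken for it.  The alternative to calibration is simulation: fix a true
effect θ̂ (e.g., a null), simulate behavior and classifier, run your
pipeline, and compare θ_meas with θ̂.

Inference runs on a package-provided blocked adaptive Metropolis sampler
(vectorized elementwise updates, non-centered parameterizations,
interweaving moves along posterior ridges) with split-R̂/ESS diagnostics;
see `docs/methods.md` for the full specification.

## Worked example

Simulate a 50-children corpus with a known sibling effect on adult input
(β_sib_adu = −0.22), push it through a confusion-heavy synthetic
classifier, and compare the naive fit against calibration:

```python
import numpy as np
from vocalib import (BehaviorParams, CalibrationDataset, MCMCConfig,
                     simulate_true_counts)
from vocalib.calibration import fit_joint, naive_fit, simulate_classifier_counts
from vocalib.synthetic import FixtureSpec, make_calibration_clips
from vocalib.confusion import ConfusionProfile

mu = np.array([[0.65, 0.08, 0.25, 0.02],
               [0.10, 0.50, 0.20, 0.10],
               [0.25, 0.05, 0.65, 0.08],
               [0.02, 0.03, 0.10, 0.55]])
profile = ConfusionProfile(mu=mu, alpha=np.full((4, 4), 6.0), tau=0.7)

params = BehaviorParams()                      # truth: beta_sib_adu = -0.22
rng = np.random.default_rng(0)
corpus = simulate_true_counts(params, 50, 3, rng)
frame = simulate_classifier_counts(corpus, profile, rng)
clips = make_calibration_clips(FixtureSpec(
    n_clip_recordings=15, windows_per_recording=24,
    profiles={"classifier": profile}, rng_seed=1000))
ds = CalibrationDataset(clips=clips, recordings=frame, classifier="classifier")

cfg = MCMCConfig(chains=2, warmup=500, samples=500, seed=0)
naive = naive_fit(ds, mcmc_config=cfg)
cal = fit_joint(ds, mcmc_config=cfg)
for name, post in [("naive", naive), ("calibrated", cal)]:
    lo, hi = post.ci("beta_sib_adu", 0.8)
    print(f"{name:10s} beta_sib_adu = {post.mean('beta_sib_adu'):+.3f} "
          f"80% CI [{lo:+.2f}, {hi:+.2f}]")
```

Output (seed 0):

```
naive      beta_sib_adu = +0.032 80% CI [-0.04, +0.11]
calibrated beta_sib_adu = -0.225 80% CI [-0.33, -0.11]
```

The naive fit concludes siblings *increase* adult input — other-child
speech leaking into the adult classes opens a spurious path from siblings
to measured adult counts.  The calibrated posterior recovers the true
negative effect, with a wider (honest) interval.

The same machinery powers quick sensitivity simulations, e.g. the
fixed-adult-total experiment (CHI = 1500; OCH 0 or 1000 with probability
1/2; FEM = 3000·p, MAL = 3000·(1−p), p ~ uniform):

```python
from vocalib import female_proportion_experiment
res = female_proportion_experiment(profile, n_samples=2000, rng_seed=0)
print(res.bias_curve(n_bins=5)[["theta_hat_mid", "theta_meas_median"]])
```

```
   theta_hat_mid  theta_meas_median
0       0.097080           0.384049
1       0.294088           0.501881
2       0.500453           0.619580
3       0.705972           0.731521
4       0.905649           0.840611
```

Measured proportions are pulled toward the middle: overestimated when few
female adults speak, underestimated when they dominate.

A thin command-line interface wraps the same functions (`vocalib synth`,
`fit-confusion`, `calibrate`, `naive-fit`, `coverage`, `sensitivity`,
`null-test`); every run writes a manifest with its seed and configuration.

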