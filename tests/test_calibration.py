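"""Inference smoke and identity checks (full recovery lives in acceptance)."""

import numpy as np
import pytest
from scipy.stats import halfnorm

from vocalib.behavior import BehaviorParams, simulate_true_counts
from vocalib.calibration import (
    CalibrationDataset,
    coverage_calibration,
    dataset_from_frames,
    fit_confusion,
    fit_joint,
    naive_fit,
    simulate_classifier_counts,
)
from vocalib.mcmc import MCMCConfig
from vocalib.segments_io import ClipCounts
from vocalib.speakers import SPEAKER_LABELS
from vocalib.synthetic import FixtureSpec, make_calibration_clips

QUICK = MCMCConfig(chains=2, warmup=250, samples=250, seed=0)


def perfect_clips(n_rec=4, n_win=10, seed=0):
    rng = np.random.default_rng(seed)
    clips = []
    for r in range(n_rec):
        for w in range(n_win):
            v = rng.poisson([1.2, 0.5, 1.8, 0.8])
            clips.append(
                ClipCounts(f"r{r}:{w}", f"r{r}", w, v, {"clf": v.copy()})
            )
    return clips


def truth_dataset(n_children=25, seed=0, params=None):
    corpus = simulate_true_counts(params or BehaviorParams(), n_children, 2, seed)
    frame = corpus.recordings.copy()
    for s in SPEAKER_LABELS:
        frame[f"n_{s}"] = frame[f"v_{s}"]
    return corpus, CalibrationDataset(clips=[], recordings=frame, classifier="truth")


def test_single_recording_rejected():
    clips = [c for c in perfect_clips(n_rec=1)]
    with pytest.raises(ValueError, match="2 recordings"):
        fit_confusion(clips, QUICK, classifier="clf")


def test_no_data_posterior_equals_prior():
    """With zero clips the confusion posterior must reproduce its priors."""
    post = fit_confusion([], MCMCConfig(chains=2, warmup=500, samples=1500, seed=1))
    pooled = post.stacked("mu").reshape(-1)
    for q in (0.25, 0.5, 0.75):
        assert np.quantile(pooled, q) == pytest.approx(halfnorm.ppf(q, scale=1.0), abs=0.08)
    tau = post.stacked("tau")
    assert np.median(tau) == pytest.approx(halfnorm.ppf(0.5, scale=1.0), abs=0.1)


def test_identity_classifier_recovery():
    """Clips where the classifier reproduces truth: mu concentrates near I."""
    clips = perfect_clips(n_rec=6, n_win=20)
    post = fit_confusion(clips, MCMCConfig(chains=2, warmup=400, samples=400, seed=2), classifier="clf")
    mu = post.mean("mu")
    assert np.all(np.diag(mu) > 0.8)
    off = mu[~np.eye(4, dtype=bool)]
    assert np.all(off < 0.12)


def test_more_windows_shrink_posterior(vtc_like_profile):
    sds = []
    for n_win in (8, 32):
        spec = FixtureSpec(
            n_clip_recordings=6,
            windows_per_recording=n_win,
            profiles={"clf": vtc_like_profile},
            rng_seed=4,
        )
        post = fit_confusion(
            make_calibration_clips(spec),
            MCMCConfig(chains=2, warmup=300, samples=300, seed=4),
            classifier="clf",
        )
        sds.append(post.sd("mu")[2, 2])
    assert sds[1] < sds[0]


def test_naive_recovers_truth_on_perfect_counts():
    params = BehaviorParams()
    corpus, ds = truth_dataset(n_children=30, seed=4)
    post = naive_fit(ds, mcmc_config=MCMCConfig(chains=2, warmup=400, samples=400, seed=4))
    lo, hi = post.ci("beta_sib_och", 0.98)
    assert lo < params.beta_sib_och < hi
    realized_slope = corpus.children["alpha_c_dev"].mean()
    lo, hi = post.ci("alpha_dev", 0.98)
    assert lo < realized_slope < hi


def test_joint_agrees_with_naive_under_identity_confusion(identity_profile):
    _, ds = truth_dataset(n_children=20, seed=6)
    naive = naive_fit(ds, mcmc_config=QUICK)
    cal = fit_joint(ds, mcmc_config=QUICK, fix_confusion=identity_profile)
    for name in ("beta_sib_och", "beta_sib_adu"):
        assert cal.mean(name) == pytest.approx(naive.mean(name), abs=0.12)
    # and the latent counts sit on the observed ones
    v = cal.mean("v")
    n_obs = ds.recordings[[f"n_{s}" for s in SPEAKER_LABELS]].to_numpy()
    assert np.abs(v / np.maximum(n_obs, 1) - 1.0)[n_obs > 5].max() < 0.2


def test_same_inputs_feed_both_fits(adversarial_profile):
    """Interface contract: one dataset object drives naive and calibrated."""
    rng = np.random.default_rng(0)
    corpus = simulate_true_counts(BehaviorParams(), 15, 2, rng)
    frame = simulate_classifier_counts(corpus, adversarial_profile, rng)
    clips = make_calibration_clips(
        FixtureSpec(n_clip_recordings=4, windows_per_recording=8,
                    profiles={"classifier": adversarial_profile}, rng_seed=1)
    )
    ds = CalibrationDataset(clips=clips, recordings=frame, classifier="classifier")
    naive = naive_fit(ds, mcmc_config=MCMCConfig(chains=2, warmup=150, samples=150, seed=0))
    cal = fit_joint(ds, mcmc_config=MCMCConfig(chains=2, warmup=150, samples=150, seed=0))
    assert set(naive.draws) <= set(cal.draws)
    assert cal.draws["v"].shape[-2] == len(frame)


def test_missing_covariates_rejected():
    _, ds = truth_dataset(n_children=5, seed=1)
    ds.recordings.loc[2, "age_months"] = np.nan
    with pytest.raises(ValueError, match="missing covariates"):
        naive_fit(ds, mcmc_config=QUICK)


def test_joint_requires_clips_or_fixed_profile():
    _, ds = truth_dataset(n_children=5, seed=2)
    with pytest.raises(ValueError, match="clips"):
        fit_joint(ds, mcmc_config=QUICK)


def test_coverage_requires_enough_sims():
    with pytest.raises(ValueError, match="20"):
        coverage_calibration(5)


def test_dataset_from_frames_joins_on_classifier():
    import pandas as pd

    meta = pd.DataFrame(
        {
            "recording_id": ["r1", "r2"],
            "child_id": ["c1", "c1"],
            "corpus_id": ["x", "x"],
            "age_months": [10.0, 13.0],
            "n_siblings": [1, 1],
        }
    )
    counts = pd.DataFrame(
        {
            "recording_id": ["r1", "r2", "r1"],
            "annotator_id": ["vtc", "vtc", "lena"],
            "CHI": [5, 6, 4],
            "OCH": [0, 1, 0],
            "FEM": [9, 8, 7],
            "MAL": [2, 2, 2],
        }
    )
    ds = dataset_from_frames(meta, counts, "vtc")
    assert len(ds.recordings) == 2
    assert ds.recordings["n_CHI"].tolist() == [5, 6]
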