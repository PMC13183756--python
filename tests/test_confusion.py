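"""Confusion model: rate sampling, count simulation, exact marginals."""

import itertools

import numpy as np
import pytest

from vocalib.confusion import (
    ConfusionDraw,
    ConfusionProfile,
    clip_log_likelihood,
    conv_sum_logpmf,
    precision_biased_profile,
    recall_biased_profile,
    recording_log_likelihood,
    sample_confusion,
    simulate_counts,
)
from vocalib.dpo import dpo_pmf


def brute_force_clip_likelihood(n, v, lam, tau):
    """Independent oracle: enumerate every decomposition of each total."""
    total = 0.0
    for j in range(4):
        pj = 0.0
        for parts in itertools.product(range(int(n[j]) + 1), repeat=4):
            if sum(parts) != n[j]:
                continue
            p = 1.0
            for i in range(4):
                p *= dpo_pmf(parts[i], lam[i, j] * v[i], tau)
            pj += p
        total += np.log(pj)
    return total


# ------------------------------------------------------------------- profiles


def test_profile_roundtrip(tmp_path, vtc_like_profile):
    path = tmp_path / "profile.tsv"
    vtc_like_profile.to_text(path)
    back = ConfusionProfile.from_text(path)
    assert np.array_equal(back.mu, vtc_like_profile.mu)
    assert np.array_equal(back.alpha, vtc_like_profile.alpha)
    assert back.tau == vtc_like_profile.tau


def test_profile_validation():
    with pytest.raises(ValueError):
        ConfusionProfile(mu=-np.ones((4, 4)), alpha=np.ones((4, 4)), tau=1.0)
    with pytest.raises(ValueError):
        ConfusionProfile(mu=np.ones((4, 4)), alpha=0.5 * np.ones((4, 4)), tau=1.0)
    with pytest.raises(ValueError):
        ConfusionProfile(mu=np.ones((4, 4)), alpha=np.ones((4, 4)), tau=0.0)


def test_bundled_profiles_qualitative():
    lena, vtc = precision_biased_profile(), recall_biased_profile()
    # recall-oriented: higher true-positive rates; precision-oriented: fewer
    # false positives but more variable behavior
    assert np.all(np.diag(vtc.mu) > np.diag(lena.mu))
    off = ~np.eye(4, dtype=bool)
    assert vtc.mu[off].sum() > lena.mu[off].sum()
    assert vtc.alpha[0, 0] > lena.alpha[0, 0]


# ------------------------------------------------------------------- sampling


def test_sample_confusion_moments(vtc_like_profile, rng):
    draws = np.stack([sample_confusion(vtc_like_profile, rng).lam for _ in range(20_000)])
    mean = draws.mean(axis=0)
    sd_mc = draws.std(axis=0) / np.sqrt(draws.shape[0])
    assert np.all(np.abs(mean - vtc_like_profile.mu) < 5 * sd_mc + 1e-12)
    assert np.all(draws >= 0)


def test_sample_confusion_concentrates_at_large_shape(rng):
    profile = ConfusionProfile(mu=np.full((4, 4), 0.5), alpha=np.full((4, 4), 1e6), tau=1.0)
    draws = np.stack([sample_confusion(profile, rng).lam for _ in range(200)])
    assert draws.std(axis=0).max() < 1e-2 * 0.5


def test_sample_confusion_reproducible(vtc_like_profile):
    a = sample_confusion(vtc_like_profile, 7).lam
    b = sample_confusion(vtc_like_profile, 7).lam
    assert np.array_equal(a, b)


# ----------------------------------------------------------------- simulation


def test_simulate_counts_zero_truth(identity_profile, rng):
    draw = sample_confusion(identity_profile, rng)
    assert all(
        np.array_equal(simulate_counts(np.zeros(4, dtype=int), draw, 1.0, rng), np.zeros(4))
        for _ in range(20)
    )


def test_simulate_counts_mean_linearity(vtc_like_profile, rng):
    draw = sample_confusion(vtc_like_profile, rng)
    v = np.array([3, 1, 5, 2])
    reps = simulate_counts(v, draw, vtc_like_profile.tau, rng, size=40_000)
    expected = v @ draw.lam
    se = reps.std(axis=0) / np.sqrt(reps.shape[0])
    assert np.all(np.abs(reps.mean(axis=0) - expected) < 5 * se)


def test_simulate_counts_near_degenerate_noise(rng):
    draw = ConfusionDraw(np.eye(4))
    v = np.array([5, 0, 2, 1])
    reps = simulate_counts(v, draw, 1e3, rng, size=500)
    assert (reps == v).all(axis=1).mean() > 0.9


# ---------------------------------------------------------------- clip marginal


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_clip_likelihood_matches_enumeration(seed, vtc_like_profile):
    rng = np.random.default_rng(seed)
    draw = sample_confusion(vtc_like_profile, rng)
    v = rng.integers(0, 4, size=4)
    n = rng.integers(0, 4, size=4)
    ours = clip_log_likelihood(n, v, draw, vtc_like_profile.tau)
    oracle = brute_force_clip_likelihood(n, v, draw.lam, vtc_like_profile.tau)
    assert ours == pytest.approx(oracle, abs=1e-10)


def test_clip_likelihood_degenerate_point_mass():
    draw = ConfusionDraw(np.zeros((4, 4)))
    assert clip_log_likelihood(np.zeros(4, int), np.array([2, 0, 1, 0]), draw, 1.0) == 0.0


def test_clip_likelihood_normalizes(vtc_like_profile, rng):
    draw = sample_confusion(vtc_like_profile, rng)
    v = np.array([1, 0, 2, 1])
    for j in range(4):
        means = np.tile(v * draw.lam[:, j], (31, 1))
        lp = conv_sum_logpmf(means, np.arange(31), vtc_like_profile.tau)
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-6)


def test_clip_likelihood_matches_simulation_frequency(rng):
    lam = np.diag([0.7, 0.6, 0.8, 0.5])
    lam[2, 0] = 0.2
    draw = ConfusionDraw(lam)
    v = np.array([1, 0, 1, 0])
    n = np.array([1, 0, 0, 0])
    p = np.exp(clip_log_likelihood(n, v, draw, 1.0))
    reps = simulate_counts(v, draw, 1.0, rng, size=200_000)
    freq = (reps == n).all(axis=1).mean()
    assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / reps.shape[0])


def test_enumeration_cap_enforced(vtc_like_profile, rng):
    draw = sample_confusion(vtc_like_profile, rng)
    with pytest.raises(ValueError, match="windows"):
        clip_log_likelihood(np.array([50, 0, 0, 0]), np.array([1, 0, 0, 0]), draw, 1.0)


# ------------------------------------------------------------ recording level


def test_recording_likelihood_zero_case():
    draw = ConfusionDraw(np.eye(4))
    assert recording_log_likelihood(np.zeros(4, int), np.zeros(4), draw, 1.0) == 0.0


def test_recording_likelihood_one_source_limit():
    """With a single source the continuous and exact forms coincide."""
    draw = ConfusionDraw(np.diag([0.7, 0.6, 0.8, 0.5]))
    v = np.array([30, 0, 0, 0])
    for n0 in [15, 21, 27]:
        n = np.array([n0, 0, 0, 0])
        exact = clip_log_likelihood(n, v, draw, 0.8)
        cont = recording_log_likelihood(n, v.astype(float), draw, 0.8)
        assert cont == pytest.approx(exact, rel=0.02)


def test_recording_likelihood_unimodal_in_observed_count():
    draw = ConfusionDraw(np.diag([0.7, 0.6, 0.8, 0.5]))
    v = np.array([50.0, 0, 0, 0])
    center = 35
    lls = []
    for n0 in range(10, 70):
        n = np.array([n0, 0, 0, 0])
        lls.append(recording_log_likelihood(n, v, draw, 0.8))
    lls = np.array(lls)
    peak = np.argmax(lls)
    assert abs((10 + peak) - center) <= 2
    assert np.all(np.diff(lls[: peak + 1]) > 0)
    assert np.all(np.diff(lls[peak:]) < 0)
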