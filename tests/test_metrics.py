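"""Agreement metrics: speaker-pair correlations, ICC, derived measures."""

import numpy as np
import pandas as pd
import pytest

from vocalib.confusion import ConfusionProfile, sample_confusion, simulate_counts
from vocalib.metrics import female_adult_proportion, icc, pearson_by_speaker_pair
from vocalib.speakers import SPEAKER_LABELS


def counts_frame(array, **ids):
    frame = pd.DataFrame(array, columns=list(SPEAKER_LABELS))
    for key, values in ids.items():
        frame[key] = values
    return frame


def test_duplicated_column_gives_unit_correlation(rng):
    x = rng.poisson(10, size=100)
    frame = counts_frame(
        np.column_stack([x, x, rng.poisson(10, 100), rng.poisson(10, 100)]),
        recording_id=[f"r{i}" for i in range(100)],
    )
    _, R = pearson_by_speaker_pair(frame, level="recording")
    assert R.loc["CHI", "OCH"] == pytest.approx(1.0)
    assert np.allclose(np.diag(R), 1.0)
    assert np.allclose(R.values, R.values.T, equal_nan=True)


def test_independent_counts_uncorrelated(rng):
    frame = counts_frame(
        rng.poisson(20, size=(4000, 4)), recording_id=[f"r{i}" for i in range(4000)]
    )
    tidy, R = pearson_by_speaker_pair(frame, level="recording")
    off = R.values[~np.eye(4, dtype=bool)]
    assert np.abs(off).max() < 4 / np.sqrt(4000)
    assert set(tidy.columns) == {"speaker_i", "speaker_j", "level", "R", "p", "N"}


def test_shared_confusion_source_inflates_correlation(rng):
    """The distortion mechanism: FEM speech leaking into the CHI count."""
    mu = np.eye(4) * 0.7
    mu[2, 0] = 0.3  # female adult -> key child
    profile = ConfusionProfile(mu=mu, alpha=np.full((4, 4), 8.0), tau=0.7)
    lam_means = rng.gamma(3.0, np.array([30, 10, 50, 20]) / 3.0, size=(800, 4))
    v = rng.poisson(lam_means)
    n = np.zeros_like(v)
    for k in range(v.shape[0]):
        draw = sample_confusion(profile, rng)
        n[k] = simulate_counts(v[k], draw, profile.tau, rng)
    ids = [f"r{i}" for i in range(v.shape[0])]
    _, R_true = pearson_by_speaker_pair(counts_frame(v, recording_id=ids), "recording")
    _, R_meas = pearson_by_speaker_pair(counts_frame(n, recording_id=ids), "recording")
    assert abs(R_true.loc["CHI", "FEM"]) < 0.1
    assert R_meas.loc["CHI", "FEM"] > R_true.loc["CHI", "FEM"] + 0.1


def test_constant_column_flagged_not_zero(rng):
    frame = counts_frame(
        np.column_stack([np.full(10, 3), rng.poisson(5, 10), rng.poisson(5, 10), rng.poisson(5, 10)]),
        recording_id=[f"r{i}" for i in range(10)],
    )
    with pytest.warns(RuntimeWarning, match="constant"):
        _, R = pearson_by_speaker_pair(frame, "recording")
    assert np.isnan(R.loc["CHI", "FEM"])


def test_aggregation_levels():
    frame = counts_frame(
        np.array([[1, 0, 0, 0], [2, 0, 0, 0], [3, 0, 0, 0], [5, 0, 0, 0]]),
        recording_id=["r1", "r1", "r2", "r3"],
        child_id=["c1", "c1", "c1", "c2"],
        clip_id=["k1", "k2", "k3", "k4"],
    )
    from vocalib.metrics import _aggregate

    rec = _aggregate(frame, "recording")
    assert rec.loc["r1", "CHI"] == 3  # clips summed within recording
    child = _aggregate(frame, "child")
    assert child.loc["c1", "CHI"] == 3  # mean of recording-level counts
    with pytest.raises(ValueError):
        _aggregate(frame, "galaxy")


def test_minimum_units_enforced():
    frame = counts_frame(np.ones((2, 4)), recording_id=["a", "b"])
    with pytest.raises(ValueError, match="at least 3"):
        pearson_by_speaker_pair(frame, "recording")


# ------------------------------------------------------------------------ ICC


def test_icc_perfect_agreement(rng):
    x = rng.poisson(10, 50).astype(float)
    assert icc(x, x) == pytest.approx(1.0, abs=1e-6)


def test_icc_independent_raters(rng):
    x, y = rng.normal(0, 1, 400), rng.normal(0, 1, 400)
    assert abs(icc(x, y)) < 0.15


def test_icc_generative_oracle(rng):
    """Equal unit and error variance gives a true ICC of 0.5."""
    unit = rng.normal(0, 1, 600)
    x = unit + rng.normal(0, 1, 600)
    y = unit + rng.normal(0, 1, 600)
    assert icc(x, y) == pytest.approx(0.5, abs=0.1)


def test_icc_symmetric_in_raters(rng):
    unit = rng.normal(0, 1, 100)
    x = unit + rng.normal(0, 0.5, 100)
    y = unit + rng.normal(0, 0.5, 100)
    assert icc(x, y) == pytest.approx(icc(y, x), abs=1e-9)


def test_icc_degenerate_variance_flagged():
    with pytest.warns(RuntimeWarning, match="degenerate"):
        out = icc(np.full(5, 2.0), np.full(5, 2.0))
    assert np.isnan(out)


def test_icc_variant_knob(rng):
    unit = rng.normal(0, 1, 200)
    x = unit + rng.normal(0, 0.7, 200)
    y = unit + 0.5 + rng.normal(0, 0.7, 200)  # systematic offset
    # consistency (ICC3) forgives the offset; absolute agreement (ICC2) does not
    assert icc(x, y, variant="ICC3") > icc(x, y, variant="ICC2")


# ----------------------------------------------------------------- proportion


def test_female_adult_proportion_values():
    assert female_adult_proportion([0, 0, 3000, 0]) == 1.0
    assert female_adult_proportion([10, 5, 70, 70]) == 0.5
    assert female_adult_proportion([0, 0, 900, 2100]) == pytest.approx(0.3)


def test_female_adult_proportion_undefined():
    with pytest.warns(RuntimeWarning, match="undefined"):
        out = female_adult_proportion([5, 2, 0, 0])
    assert np.isnan(out)
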