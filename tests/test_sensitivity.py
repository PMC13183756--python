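"""Simulation engine: sensitivity loops, bias curves, Monte-Carlo p-values."""

import numpy as np
import pandas as pd
import pytest

from vocalib.sensitivity import (
    PIPELINES,
    SensitivityConfig,
    SensitivityResult,
    female_proportion_experiment,
    null_test,
    run_sensitivity,
)
from vocalib.speakers import SPEAKER_LABELS


def poisson_generator(means):
    def gen(theta, rng):
        v = rng.poisson(means, size=(40, 4))
        return pd.DataFrame(v, columns=[f"v_{s}" for s in SPEAKER_LABELS])

    return gen


def test_unknown_pipeline_rejected(identity_profile):
    config = SensitivityConfig(
        theta_spec=0.0,
        generator=poisson_generator([10, 5, 20, 10]),
        profile=identity_profile,
        pipeline="not_a_pipeline",
        n_replicates=2,
    )
    with pytest.raises(KeyError, match="not_a_pipeline"):
        run_sensitivity(config)
    with pytest.raises(ValueError):
        SensitivityConfig(0.0, poisson_generator([1, 1, 1, 1]), identity_profile, "female_proportion", n_replicates=0)


def test_error_free_limit_recovers_theta(identity_profile):
    """With a perfect classifier the measured proportion equals the truth."""
    res = female_proportion_experiment(identity_profile, n_samples=300, rng_seed=0)
    dev = np.abs(res.table["theta_meas"] - res.table["theta_hat"])
    assert dev.mean() < 0.01


def test_replicates_bit_identical_across_reruns(vtc_like_profile):
    a = female_proportion_experiment(vtc_like_profile, n_samples=50, rng_seed=9)
    b = female_proportion_experiment(vtc_like_profile, n_samples=50, rng_seed=9)
    assert a.table.equals(b.table)


def test_run_size_matches_request(vtc_like_profile):
    res = female_proportion_experiment(vtc_like_profile, n_samples=120, rng_seed=2)
    assert len(res.table) == 120


def test_bias_curve_invariant_to_replicate_order(vtc_like_profile):
    res = female_proportion_experiment(vtc_like_profile, n_samples=200, rng_seed=4)
    shuffled = SensitivityResult(table=res.table.sample(frac=1.0, random_state=0))
    a = res.bias_curve(n_bins=8).reset_index(drop=True)
    b = shuffled.bias_curve(n_bins=8).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_null_test_add_one_rule(identity_profile):
    config = SensitivityConfig(
        theta_spec=0.0,
        generator=poisson_generator([10, 5, 20, 10]),
        profile=identity_profile,
        pipeline="chi_fem_correlation",
        n_replicates=49,
        rng_seed=3,
    )
    # statistic above every achievable correlation
    assert null_test(2.0, config) == pytest.approx(1 / 50)
    # statistic below every achievable correlation
    assert null_test(-2.0, config) == pytest.approx(1.0)


def test_null_pvalues_roughly_uniform(identity_profile):
    """Observed statistics drawn from the null give calibrated p-values."""
    gen = poisson_generator([15, 6, 25, 12])
    rng = np.random.default_rng(0)
    pvals = []
    for rep in range(30):
        config = SensitivityConfig(
            theta_spec=0.0,
            generator=gen,
            profile=identity_profile,
            pipeline="chi_fem_correlation",
            n_replicates=39,
            rng_seed=1000 + rep,
        )
        observed = run_sensitivity(
            SensitivityConfig(
                theta_spec=0.0,
                generator=gen,
                profile=identity_profile,
                pipeline="chi_fem_correlation",
                n_replicates=1,
                rng_seed=rep,
            )
        ).table["theta_meas"].iloc[0]
        pvals.append(null_test(observed, config))
    pvals = np.asarray(pvals)
    assert 0.3 < pvals.mean() < 0.7
    assert pvals.min() < 0.35 and pvals.max() > 0.65


def test_registered_pipelines_present():
    assert {"female_proportion", "chi_fem_correlation"} <= set(PIPELINES)
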