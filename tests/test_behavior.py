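"""Speech-behavior model: link function, hierarchy, forward simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vocalib.behavior import (
    BehaviorParams,
    ChildState,
    age_basis,
    draw_counts,
    expected_rates,
    simulate_true_counts,
)
from vocalib.speakers import SpeakerClass


def make_child(params, n_siblings=0, alpha_c_dev=0.0, ail=0.0):
    return ChildState(
        child_id="c0",
        corpus_id="corpus0",
        n_siblings=n_siblings,
        alpha_c_dev=alpha_c_dev,
        mu_child=params.mu_pop.copy(),
        adult_input_level=ail,
    )


def test_age_basis_values():
    assert age_basis(0.0) == 0.0
    assert age_basis(12.0) == 0.5
    assert age_basis(24.0) == 1.0
    assert age_basis(36.0) == 1.0  # plateau after 24 months
    with pytest.raises(ValueError):
        age_basis(-1.0)


def test_sibling_effects_zeroed_out():
    params = BehaviorParams(beta_sib_och=0.0, beta_sib_adu=0.0)
    r0 = expected_rates(params, make_child(params, n_siblings=0), 12.0)
    r2 = expected_rates(params, make_child(params, n_siblings=2), 12.0)
    assert np.allclose(r0, r2)


def test_children_equivalent_at_birth():
    params = BehaviorParams()
    fast = expected_rates(params, make_child(params, alpha_c_dev=2.0), 0.0)
    slow = expected_rates(params, make_child(params, alpha_c_dev=-2.0), 0.0)
    assert fast[SpeakerClass.CHI] == pytest.approx(slow[SpeakerClass.CHI])
    assert fast[SpeakerClass.CHI] == pytest.approx(np.exp(params.mu_pop[SpeakerClass.CHI]))


def test_slope_doubles_output_at_plateau():
    params = BehaviorParams(beta_dev=0.0)
    child = make_child(params, alpha_c_dev=np.log(2.0))
    r0 = expected_rates(params, child, 0.0)
    r24 = expected_rates(params, child, 24.0)
    assert r24[SpeakerClass.CHI] == pytest.approx(2.0 * r0[SpeakerClass.CHI])
    # non-CHI classes do not carry the developmental slope
    assert np.allclose(r24[1:], r0[1:])


def test_sibling_effect_direction():
    params = BehaviorParams()
    r0 = expected_rates(params, make_child(params, 0), 12.0)
    r1 = expected_rates(params, make_child(params, 1), 12.0)
    assert r1[SpeakerClass.OCH] > r0[SpeakerClass.OCH]
    assert r1[SpeakerClass.FEM] < r0[SpeakerClass.FEM]
    assert r1[SpeakerClass.MAL] < r0[SpeakerClass.MAL]
    assert r1[SpeakerClass.CHI] == pytest.approx(r0[SpeakerClass.CHI])


@settings(deadline=None, max_examples=30)
@given(
    a1=st.floats(min_value=-1.0, max_value=1.0),
    delta=st.floats(min_value=0.01, max_value=1.0),
    age=st.floats(min_value=0.5, max_value=48.0),
)
def test_chi_rate_monotone_in_slope(a1, delta, age):
    params = BehaviorParams()
    lo = expected_rates(params, make_child(params, alpha_c_dev=a1), age)
    hi = expected_rates(params, make_child(params, alpha_c_dev=a1 + delta), age)
    assert hi[SpeakerClass.CHI] > lo[SpeakerClass.CHI]


def test_rates_strictly_positive():
    params = BehaviorParams(beta_sib_adu=-5.0)
    rates = expected_rates(params, make_child(params, 3, alpha_c_dev=-4.0), 24.0)
    assert np.all(rates > 0)


def test_simulation_sizes():
    corpus = simulate_true_counts(BehaviorParams(), 200, 5, rng_seed=0)
    assert len(corpus.recordings) == 1000  # 200 children x 5 recordings
    assert corpus.recordings["recording_id"].is_unique


def test_simulation_reproducible():
    a = simulate_true_counts(BehaviorParams(), 20, 2, rng_seed=11)
    b = simulate_true_counts(BehaviorParams(), 20, 2, rng_seed=11)
    assert a.recordings.equals(b.recordings)


def test_marginal_mean_matches_lognormal_closed_form():
    """MC moment check against the analytic lognormal marginal for FEM."""
    params = BehaviorParams()
    corpus = simulate_true_counts(params, 1500, 2, rng_seed=3, sibling_probs=(1.0,))
    # no siblings anywhere: E[v_FEM] = exp(mu + (sig_c^2 + sig_ch^2)/2)
    expected = np.exp(
        params.mu_pop[SpeakerClass.FEM] + (params.sigma_corpus**2 + params.sigma_child**2) / 2
    )
    v = corpus.recordings["v_FEM"].to_numpy()
    se = v.std() / np.sqrt(v.size)
    assert abs(v.mean() - expected) < 4 * se


def test_degenerate_hierarchy_collapses_variation():
    params = BehaviorParams(sigma_corpus=0.0, sigma_child=0.0, sigma_dev=0.0, phi=1e7)
    corpus = simulate_true_counts(
        params, 40, 1, rng_seed=5, sibling_probs=(1.0,), age_start_range=(30.0, 30.0)
    )
    counts = corpus.true_counts()
    # identical covariates, no hierarchy, near-Poisson noise: tight spread
    assert np.all(counts.std(axis=0) < 2.0 * np.sqrt(counts.mean(axis=0)))


def test_count_law_moments(rng):
    x = draw_counts(np.full(50_000, 40.0), 5.0, rng)
    assert x.mean() == pytest.approx(40.0, rel=0.02)
    assert x.var() == pytest.approx(40.0 + 40.0**2 / 5.0, rel=0.1)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        BehaviorParams(sigma_child=-0.1)
    with pytest.raises(ValueError):
        BehaviorParams(phi=0.0)
    with pytest.raises(ValueError):
        BehaviorParams(sib_coding="nonsense")
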