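"""Hierarchical model of children's speech behavior.

Expected vocalization counts per recording follow a log-link GLM with a
population / corpus / child hierarchy:

* each speaker class (CHI, OCH, FEM, MAL) has a population log-rate, with
  Gaussian corpus- and child-level deviations;
* having siblings raises the other-child (OCH) log-rate and shifts the
  adult (FEM, MAL) log-rates; it does not enter the key child's (CHI) rate
  directly;
* the key child's output grows log-linearly with age up to a plateau at 24
  months, with a child-specific random slope, so that children are
  equivalent at birth and diverge as they age;
* the child-level expected amount of adult input has a long-term effect on
  the child's output that interacts with age (more input, faster growth).

Counts around the GLM mean are gamma-Poisson (negative binomial) with
dispersion ``phi``; the count law is isolated in :func:`draw_counts` so it
can be swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .speakers import N_CLASSES, SPEAKER_LABELS, SpeakerClass

__all__ = [
    "BehaviorParams",
    "ChildState",
    "SyntheticCorpus",
    "PLATEAU_MONTHS",
    "age_basis",
    "adult_input_scale",
    "expected_rates",
    "draw_counts",
    "simulate_true_counts",
]

#: age (months) at which the log-linear developmental trend plateaus
PLATEAU_MONTHS = 24.0


@dataclass(frozen=True)
class BehaviorParams:
    """All parameters of the speech-behavior model.

    Defaults describe a reference daytime observation window of roughly one
    hour of home audio: a two-year-old producing ~110 vocalizations, mostly
    female-adult input, a strong positive sibling effect on other-child
    speech and a moderate negative one on adult speech.
    """

    mu_pop: np.ndarray = field(
        default_factory=lambda: np.log(np.array([55.0, 25.0, 90.0, 35.0]))
    )
    sigma_corpus: float = 0.2
    sigma_child: float = 0.3
    beta_sib_och: float = 1.1
    beta_sib_adu: float = -0.22
    alpha_dev: float = 0.7
    sigma_dev: float = 0.25
    beta_dev: float = 0.15
    phi: float = 10.0
    sib_coding: str = "binary"  # "binary" (any siblings) or "count"

    def __post_init__(self):
        mu_pop = np.asarray(self.mu_pop, dtype=float)
        if mu_pop.shape != (N_CLASSES,):
            raise ValueError("mu_pop must have length 4")
        for name in ("sigma_corpus", "sigma_child", "sigma_dev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.phi > 0:
            raise ValueError("phi must be > 0")
        if self.sib_coding not in ("binary", "count"):
            raise ValueError("sib_coding must be 'binary' or 'count'")
        object.__setattr__(self, "mu_pop", mu_pop)

    def sib_covariate(self, n_siblings) -> np.ndarray:
        n = np.asarray(n_siblings, dtype=float)
        return (n > 0).astype(float) if self.sib_coding == "binary" else n


@dataclass(frozen=True)
class ChildState:
    """Latent state of one child (log-rates, slope, input level)."""

    child_id: str
    corpus_id: str
    n_siblings: int
    alpha_c_dev: float
    mu_child: np.ndarray
    adult_input_level: float

    def __post_init__(self):
        mu_child = np.asarray(self.mu_child, dtype=float)
        if mu_child.shape != (N_CLASSES,):
            raise ValueError("mu_child must have length 4")
        object.__setattr__(self, "mu_child", mu_child)


def age_basis(age_months) -> np.ndarray:
    """Developmental basis: linear ramp from 0 at birth to 1 at the plateau.

    ``min(age, 24) / 24`` — log-linear growth up to 24 months, flat after.
    """
    age = np.asarray(age_months, dtype=float)
    if np.any(age < 0):
        raise ValueError("age_months must be >= 0")
    out = np.minimum(age, PLATEAU_MONTHS) / PLATEAU_MONTHS
    return float(out) if out.ndim == 0 else out


def adult_input_scale(params: BehaviorParams) -> float:
    """Standardization scale for the child-level adult-input covariate."""
    return float(np.hypot(params.sigma_corpus, params.sigma_child) + 1e-3)


def adult_input_level(params: BehaviorParams, mu_child: np.ndarray) -> np.ndarray:
    """Child-level adult-input covariate on an approximately N(0,1) scale.

    The deviation of the child's expected adult (FEM+MAL) log-rate from the
    population expectation, in units of the total hierarchy SD.  Computed
    from the model's own parameters rather than batch statistics so that the
    covariate of one child never depends on the other children sampled.
    """
    mu_child = np.atleast_2d(mu_child)
    child = np.logaddexp(mu_child[:, SpeakerClass.FEM], mu_child[:, SpeakerClass.MAL])
    ref = np.logaddexp(params.mu_pop[SpeakerClass.FEM], params.mu_pop[SpeakerClass.MAL])
    return (child - ref) / adult_input_scale(params)


def expected_rates(params: BehaviorParams, child: ChildState, age_months: float) -> np.ndarray:
    """Expected per-recording counts for each speaker class (log-link GLM)."""
    sib = float(params.sib_covariate(child.n_siblings))
    log_rate = child.mu_child.copy()
    log_rate[SpeakerClass.OCH] += params.beta_sib_och * sib
    log_rate[SpeakerClass.FEM] += params.beta_sib_adu * sib
    log_rate[SpeakerClass.MAL] += params.beta_sib_adu * sib
    slope = child.alpha_c_dev + params.beta_dev * child.adult_input_level
    log_rate[SpeakerClass.CHI] += slope * age_basis(age_months)
    return np.exp(log_rate)


def draw_counts(mean, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts around the GLM mean.

    Variance is ``mean + mean**2 / phi``; isolated here so the count law can
    be swapped without touching the rest of the generator.
    """
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(phi, mean / phi)
    return rng.poisson(lam)


@dataclass
class SyntheticCorpus:
    """A simulated corpus: per-recording truth plus per-child latent state."""

    recordings: pd.DataFrame  # recording_id, child_id, corpus_id, age_months, n_siblings, v_*
    children: pd.DataFrame  # child_id, corpus_id, n_siblings, alpha_c_dev, adult_input_level
    params: BehaviorParams

    def true_counts(self) -> np.ndarray:
        return self.recordings[[f"v_{s}" for s in SPEAKER_LABELS]].to_numpy()


def _draw_children(
    params: BehaviorParams,
    n_children: int,
    rng: np.random.Generator,
    n_corpora: int,
    sibling_probs: Sequence[float],
) -> list[ChildState]:
    corpus_dev = rng.normal(0.0, params.sigma_corpus, size=(n_corpora, N_CLASSES))
    children = []
    for c in range(n_children):
        corpus = c % n_corpora
        mu_child = params.mu_pop + corpus_dev[corpus] + rng.normal(
            0.0, params.sigma_child, size=N_CLASSES
        )
        children.append(
            ChildState(
                child_id=f"child{c:04d}",
                corpus_id=f"corpus{corpus}",
                n_siblings=int(rng.choice(len(sibling_probs), p=sibling_probs)),
                alpha_c_dev=float(rng.normal(params.alpha_dev, params.sigma_dev)),
                mu_child=mu_child,
                adult_input_level=float(adult_input_level(params, mu_child)[0]),
            )
        )
    return children


def simulate_true_counts(
    params: BehaviorParams,
    children: int | Sequence[ChildState],
    recordings_per_child: int,
    rng_seed,
    n_corpora: int = 6,
    sibling_probs: Sequence[float] = (0.45, 0.35, 0.20),
    age_start_range: tuple[float, float] = (3.0, 30.0),
    months_between_recordings: float = 3.0,
) -> SyntheticCorpus:
    """Simulate a longitudinal corpus of true vocalization counts.

    ``children`` may be an integer (covariates and latent states are drawn
    from the hierarchy) or a list of :class:`ChildState`.  Each child is
    recorded ``recordings_per_child`` times at fixed intervals from a random
    starting age.  Fully reproducible given the seed.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if isinstance(children, (int, np.integer)):
        states = _draw_children(params, int(children), rng, n_corpora, sibling_probs)
    else:
        states = list(children)
    rows = []
    for child in states:
        age0 = rng.uniform(*age_start_range)
        for r in range(recordings_per_child):
            age = age0 + r * months_between_recordings
            rates = expected_rates(params, child, age)
            v = draw_counts(rates, params.phi, rng)
            row = {
                "recording_id": f"{child.child_id}_rec{r}",
                "child_id": child.child_id,
                "corpus_id": child.corpus_id,
                "age_months": age,
                "n_siblings": child.n_siblings,
            }
            row.update({f"v_{s}": int(v[k]) for k, s in enumerate(SPEAKER_LABELS)})
            rows.append(row)
    children_frame = pd.DataFrame(
        {
            "child_id": [c.child_id for c in states],
            "corpus_id": [c.corpus_id for c in states],
            "n_siblings": [c.n_siblings for c in states],
            "alpha_c_dev": [c.alpha_c_dev for c in states],
            "adult_input_level": [c.adult_input_level for c in states],
        }
    )
    return SyntheticCorpus(recordings=pd.DataFrame(rows), children=children_frame, params=params)
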