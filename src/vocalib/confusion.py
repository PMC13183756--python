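"""Model of a voice-type classifier's behavior.

Each true vocalization by speaker class ``i`` causes the classifier to
attribute a random number of detections to every class ``j``.  The count
``n_ij`` of detections attributed to ``j`` because of true speech from ``i``
follows a double Poisson, ``n_ij ~ DPO(lambda_ij * v_i, tau)``, where ``v_i``
is the true vocalization count; only the totals ``n_j = sum_i n_ij`` are
observable.  The matrix ``lambda`` is the classifier's confusion-rate matrix
(diagonal = recall-like true-positive rates, off-diagonal = misattribution
rates) and varies from recording to recording: ``lambda_kij`` is drawn from
a Gamma distribution with mean ``mu_ij`` and shape ``alpha_ij``.

The exact likelihood of an observed total marginalizes the unobserved
decomposition ``{n_ij}``; because the sources are independent, that sum is
the convolution of the four per-source double-Poisson pmfs, computed here
per target class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dpo import dpo_logpmf, dpo_pmf_grid, dpo_rvs
from .speakers import N_CLASSES, SPEAKER_LABELS

__all__ = [
    "ConfusionProfile",
    "ConfusionDraw",
    "ENUMERATION_CAP",
    "sample_confusion",
    "simulate_counts",
    "clip_log_likelihood",
    "recording_log_likelihood",
    "conv_sum_logpmf",
    "precision_biased_profile",
    "recall_biased_profile",
]

#: largest per-window count accepted by the exact clip likelihood;
#: 15-s windows keep counts far below this in practice
ENUMERATION_CAP = 40


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class ConfusionProfile:
    """Population-level confusion behavior of one classifier.

    Attributes
    ----------
    mu : (4, 4) array
        Mean confusion rates; ``mu[i, j]`` is the expected number of
        detections attributed to class j per true vocalization of class i.
    alpha : (4, 4) array
        Gamma shapes controlling how much the rates vary across recordings
        (larger = more consistent classifier). Must be >= 1.
    tau : float
        Double-Poisson dispersion shared across all class pairs; the count
        variance is mean / tau.
    """

    mu: np.ndarray
    alpha: np.ndarray
    tau: float

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        alpha = np.asarray(self.alpha, dtype=float)
        if mu.shape != (N_CLASSES, N_CLASSES) or alpha.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("mu and alpha must be 4x4 matrices")
        if np.any(mu < 0):
            raise ValueError("mu must be >= 0 elementwise")
        if np.any(alpha < 1):
            raise ValueError("alpha must be >= 1 elementwise")
        if not float(self.tau) > 0:
            raise ValueError("tau must be > 0")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "tau", float(self.tau))

    def to_text(self, path) -> None:
        """Serialize as a plain-text table (round-trip safe)."""
        lines = []
        for name, mat in (("mu", self.mu), ("alpha", self.alpha)):
            for i in range(N_CLASSES):
                for j in range(N_CLASSES):
                    lines.append(
                        f"{name}\t{SPEAKER_LABELS[i]}\t{SPEAKER_LABELS[j]}\t{mat[i, j]:.17g}"
                    )
        lines.append(f"tau\t-\t-\t{self.tau:.17g}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path) -> "ConfusionProfile":
        mu = np.zeros((N_CLASSES, N_CLASSES))
        alpha = np.ones((N_CLASSES, N_CLASSES))
        tau = None
        index = {lab: k for k, lab in enumerate(SPEAKER_LABELS)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: malformed profile line {lineno}: {line!r}")
            name, i, j, value = fields
            if name == "tau":
                tau = float(value)
            elif name in ("mu", "alpha"):
                target = mu if name == "mu" else alpha
                target[index[i], index[j]] = float(value)
            else:
                raise ValueError(f"{path}: unknown field {name!r} on line {lineno}")
        if tau is None:
            raise ValueError(f"{path}: missing tau line")
        return cls(mu=mu, alpha=alpha, tau=tau)


@dataclass(frozen=True)
class ConfusionDraw:
    """Recording-specific confusion rates lambda (one 4x4 matrix)."""

    lam: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.lam, dtype=float)
        if lam.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("lambda must be a 4x4 matrix")
        if np.any(lam < 0):
            raise ValueError("lambda must be >= 0 elementwise")
        object.__setattr__(self, "lam", lam)


def sample_confusion(profile: ConfusionProfile, rng) -> ConfusionDraw:
    """Draw one recording's confusion-rate matrix from the profile.

    Rates are independent across (i, j) pairs, Gamma with mean ``mu_ij`` and
    shape ``alpha_ij`` (rate = alpha / mu); entries with mu = 0 are 0.
    """
    rng = _as_rng(rng)
    lam = np.zeros((N_CLASSES, N_CLASSES))
    pos = profile.mu > 0
    shape = profile.alpha[pos]
    scale = profile.mu[pos] / shape
    lam[pos] = rng.gamma(shape, scale)
    return ConfusionDraw(lam=lam)


def simulate_counts(v, draw: ConfusionDraw, tau: float, rng, size: int | None = None) -> np.ndarray:
    """Simulate the classifier's per-class counts for true counts ``v``.

    ``n_ij ~ DPO(lambda_ij * v_i, tau)`` independently; returns the
    observable totals ``n_j = sum_i n_ij`` as a length-4 integer vector,
    or a ``(size, 4)`` array of independent replicates when ``size`` is
    given (the replicate path draws all sixteen cells at once, which makes
    Monte-Carlo checks with millions of replicates cheap).
    """
    rng = _as_rng(rng)
    v = np.asarray(v)
    if v.shape != (N_CLASSES,) or np.any(v < 0) or np.any(v != np.floor(v)):
        raise ValueError("v must be a length-4 vector of non-negative integers")
    means = v[:, None].astype(float) * draw.lam
    if size is None:
        return dpo_rvs(means, tau, rng).sum(axis=0)
    out = np.zeros((int(size), N_CLASSES), dtype=np.int64)
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            m = means[i, j]
            if m > 0:
                out[:, j] += dpo_rvs(m, tau, rng, size=int(size))
    return out


def conv_sum_logpmf(
    means: np.ndarray, n_obs: np.ndarray, tau: float, table=None
) -> np.ndarray:
    """log P(sum_i Y_i = n) for independent Y_i ~ DPO(means[., i], tau).

    ``means`` has shape (N, C): one row of per-source means per observation;
    ``n_obs`` the N observed totals.  The marginal over all decompositions of
    the total equals the C-fold convolution of the per-source pmfs, evaluated
    at the total.  Fully vectorized over rows.  ``table`` (a LognormTable for
    this tau) switches the pmf grids to their interpolated fast path.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    n_obs = np.atleast_1d(np.asarray(n_obs)).astype(np.int64)
    n_rows, n_src = means.shape
    ymax = int(n_obs.max(initial=0))
    # one batched pmf-grid call for all sources, then iterated convolution
    grids = dpo_pmf_grid(means.T.ravel(), tau, ymax, table=table).reshape(
        n_src, n_rows, ymax + 1
    )
    acc = grids[0]
    for i in range(1, n_src):
        nxt = grids[i]
        conv = np.zeros_like(acc)
        for a in range(ymax + 1):
            conv[:, a:] += acc[:, a][:, None] * nxt[:, : ymax + 1 - a]
        acc = conv
    p = acc[np.arange(n_rows), n_obs]
    with np.errstate(divide="ignore"):
        return np.log(p)


def clip_log_likelihood(n, v, draw: ConfusionDraw, tau: float) -> float:
    """Exact log P(n | v, lambda, tau) for one annotated window.

    Marginalizes the latent decomposition counts exactly, per target class
    (the joint sum factorizes across target classes because sources
    contribute independently to each).
    """
    n = np.asarray(n)
    v = np.asarray(v)
    for name, arr in (("n", n), ("v", v)):
        if arr.shape != (N_CLASSES,) or np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise ValueError(f"{name} must be a length-4 vector of non-negative integers")
        if np.any(arr > ENUMERATION_CAP):
            raise ValueError(
                f"per-window counts above {ENUMERATION_CAP} are intractable for the "
                "exact marginal; split the clip into smaller windows"
            )
    # row j: means of the four sources feeding target class j
    means = (v[:, None].astype(float) * draw.lam).T
    return float(conv_sum_logpmf(means, n.astype(np.int64), tau).sum())


def recording_log_likelihood(n, v_latent, draw: ConfusionDraw, tau: float) -> float:
    """Continuous-count log likelihood for a whole recording.

    Treats the latent true counts as continuous and models the observed
    totals directly as ``n_j ~ DPO(sum_i lambda_ij v_i, tau)``; smooth in
    ``v_latent``, suitable for recording-scale counts where the exact
    decomposition sum is intractable.
    """
    n = np.asarray(n)
    v_latent = np.asarray(v_latent, dtype=float)
    if v_latent.shape != (N_CLASSES,) or np.any(v_latent < 0):
        raise ValueError("v_latent must be a length-4 vector of non-negative reals")
    m = draw.lam.T @ v_latent
    return float(np.sum(dpo_logpmf(n, m, tau)))


def recall_biased_profile() -> ConfusionProfile:
    """Synthetic profile of a recall-oriented classifier (VTC-like).

    Balanced precision/recall: high diagonal rates, non-negligible
    misattribution between acoustically close classes (the two child classes,
    the two adult classes, and female adults vs. children), and peaked
    (consistent) rate distributions.  Values are synthetic, for tests and
    simulation studies; they follow the qualitative pattern only.
    """
    mu = np.array(
        [
            [0.68, 0.10, 0.08, 0.01],
            [0.12, 0.55, 0.06, 0.02],
            [0.09, 0.05, 0.72, 0.08],
            [0.02, 0.02, 0.10, 0.60],
        ]
    )
    alpha = np.full((4, 4), 8.0)
    return ConfusionProfile(mu=mu, alpha=alpha, tau=0.7)


def precision_biased_profile() -> ConfusionProfile:
    """Synthetic profile of a precision-oriented classifier (LENA-like).

    Fewer false positives (small off-diagonals) but lower recall (smaller
    diagonals) and more variable behavior across recordings (smaller Gamma
    shapes).  Values are synthetic.
    """
    mu = np.array(
        [
            [0.50, 0.05, 0.04, 0.005],
            [0.07, 0.35, 0.03, 0.01],
            [0.05, 0.02, 0.55, 0.05],
            [0.01, 0.01, 0.06, 0.42],
        ]
    )
    alpha = np.full((4, 4), 2.5)
    return ConfusionProfile(mu=mu, alpha=alpha, tau=0.6)
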