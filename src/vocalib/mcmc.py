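"""Posterior containers and the adaptive Metropolis machinery.

Inference in this package runs on a blocked random-walk Metropolis-within-
Gibbs sampler.  Conditionally independent units (recordings, children,
confusion-matrix cells) are updated *elementwise in parallel*: proposals for
every unit are evaluated in one vectorized pass and accepted or rejected per
unit, which is valid because each unit's conditional posterior does not
depend on the other units in the block.  Proposal scales adapt per block
during warmup (Robbins-Monro on the acceptance rate) and are frozen
afterwards, so the post-warmup chain is a valid Markov chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MCMCConfig", "PosteriorSamples", "AdaptiveScales"]

RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings: chains, warmup and post-warmup sweeps, seed."""

    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 0
    target_accept: float = 0.30

    def __post_init__(self):
        if self.chains < 1 or self.warmup < 1 or self.samples < 1:
            raise ValueError("chains, warmup and samples must all be >= 1")


class AdaptiveScales:
    """Per-block random-walk proposal scales with warmup-only adaptation."""

    def __init__(self, shape, init: float = 0.3):
        self.log_scale = np.full(shape, np.log(init))
        self._t = 0

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def adapt(self, accepted, target: float) -> None:
        """Robbins-Monro step toward the target acceptance rate."""
        self._t += 1
        rate = min(0.25, 3.0 / np.sqrt(self._t + 10.0))
        self.log_scale += rate * (np.asarray(accepted, dtype=float) - target)
        np.clip(self.log_scale, np.log(1e-5), np.log(50.0), out=self.log_scale)

    def scale_col_adapt(self, col: int, accepted, target: float) -> None:
        """Adapt a single column of a 2-d scale array."""
        self._t += 0.25
        rate = min(0.25, 3.0 / np.sqrt(self._t + 10.0))
        self.log_scale[:, col] += rate * (np.asarray(accepted, dtype=float) - target)
        np.clip(self.log_scale, np.log(1e-5), np.log(50.0), out=self.log_scale)


class AdaptiveCovProposal:
    """Haario-style adaptive multivariate proposal for one parameter block.

    Tracks running mean/covariance of the visited states during warmup and
    proposes with the scaled empirical covariance (2.38^2/d) times an
    adapted global multiplier; frozen after warmup.
    """

    def __init__(self, dim: int, init: float = 0.1, jitter: float = 1e-8):
        self.dim = dim
        self.log_mult = 0.0
        self.jitter = jitter
        self._n = 0
        self._mean = np.zeros(dim)
        self._m2 = np.eye(dim) * init**2
        self._chol = np.eye(dim) * init
        self._since_chol = 0

    def step(self, rng: np.random.Generator) -> np.ndarray:
        return np.exp(self.log_mult) * (self._chol @ rng.standard_normal(self.dim))

    def update(self, x: np.ndarray, accepted: float, target: float) -> None:
        self._n += 1
        delta = x - self._mean
        self._mean += delta / self._n
        self._m2 += np.outer(delta, x - self._mean)
        rate = min(0.25, 3.0 / np.sqrt(self._n + 10.0))
        self.log_mult += rate * (accepted - target)
        self._since_chol += 1
        if self._n >= 2 * self.dim and self._since_chol >= 20:
            cov = self._m2 / (self._n - 1)
            cov = (2.38**2 / self.dim) * cov + self.jitter * np.eye(self.dim)
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass
            self._since_chol = 0


@dataclass
class PosteriorSamples:
    """Labeled MCMC draws with summaries and convergence diagnostics.

    ``draws[name]`` has shape ``(chains, samples, *param_shape)``.
    """

    draws: dict[str, np.ndarray]
    warnings_: list[str] = field(default_factory=list)
    flagged: bool = False
    accept_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        sizes = {v.shape[:2] for v in self.draws.values()}
        if len(sizes) > 1:
            raise ValueError("all parameters must have identical (chains, draws) shape")

    # ------------------------------------------------------------------ access
    def stacked(self, name: str) -> np.ndarray:
        """All chains pooled: shape (chains*samples, *param_shape)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def mean(self, name: str) -> np.ndarray | float:
        out = self.stacked(name).mean(axis=0)
        return float(out) if out.ndim == 0 else out

    def sd(self, name: str) -> np.ndarray | float:
        out = self.stacked(name).std(axis=0, ddof=1)
        return float(out) if out.ndim == 0 else out

    def ci(self, name: str, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Central credible interval at the given level."""
        if not 0 < level <= 1:
            raise ValueError("level must be in (0, 1]")
        pooled = self.stacked(name)
        lo = (1.0 - level) / 2.0
        return (
            np.quantile(pooled, lo, axis=0),
            np.quantile(pooled, 1.0 - lo, axis=0),
        )

    # ------------------------------------------------------------- diagnostics
    def _labels(self, name: str) -> list[str]:
        size = int(np.prod(self.draws[name].shape[2:], dtype=int))
        return [name] if size == 1 else [f"{name}[{i}]" for i in range(size)]

    def _flat_diag(self, dataset) -> dict[str, float]:
        out = {}
        for name in self.draws:
            values = np.ravel(np.asarray(dataset[name]))
            out.update(dict(zip(self._labels(name), values.astype(float))))
        return out

    def rhat(self) -> dict[str, float]:
        """Split-R̂ (rank-normalized, via arviz) per scalar parameter."""
        import arviz as az

        return self._flat_diag(az.rhat(az.from_dict(posterior=self.draws)))

    def ess(self) -> dict[str, float]:
        """Bulk effective sample size (via arviz) per scalar parameter."""
        import arviz as az

        return self._flat_diag(az.ess(az.from_dict(posterior=self.draws)))

    def check_convergence(self, names=None, threshold: float = RHAT_THRESHOLD) -> None:
        """Flag the result if split-R̂ exceeds the threshold on any parameter."""
        for label, r in self.rhat().items():
            if names is not None and not any(label.startswith(n) for n in names):
                continue
            if np.isfinite(r) and r > threshold:
                self.flagged = True
                msg = f"possible non-convergence: split-Rhat({label}) = {r:.3f}"
                self.warnings_.append(msg)
                warnings.warn(msg, RuntimeWarning, stacklevel=2)

    def summary(self, levels=(0.8, 0.95)) -> pd.DataFrame:
        """Per-scalar summary: mean, sd, central CIs, split-R̂, ESS."""
        rhat, ess = self.rhat(), self.ess()
        rows = []
        for name, arr in self.draws.items():
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            labels = self._labels(name)
            ci_bounds = {level: self.ci(name, level) for level in levels}
            for idx, label in enumerate(labels):
                x = flat[:, :, idx]
                row = {
                    "parameter": label,
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "rhat": rhat[label],
                    "ess": ess[label],
                }
                for level in levels:
                    lo, hi = ci_bounds[level]
                    row[f"ci{int(level * 100)}_lo"] = np.ravel(lo)[idx]
                    row[f"ci{int(level * 100)}_hi"] = np.ravel(hi)[idx]
                rows.append(row)
        return pd.DataFrame(rows)

    # -------------------------------------------------------------------- I/O
    def to_netcdf(self, path) -> None:
        """Persist draws via arviz (also usable for its own diagnostics)."""
        import arviz as az

        az.from_dict(posterior=self.draws).to_netcdf(str(path))

    @staticmethod
    def combine(per_chain: list[dict[str, np.ndarray]]) -> "PosteriorSamples":
        """Stack per-chain draw dicts (each name -> (samples, *shape))."""
        names = per_chain[0].keys()
        draws = {n: np.stack([c[n] for c in per_chain], axis=0) for n in names}
        return PosteriorSamples(draws=draws)
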