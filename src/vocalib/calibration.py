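"""Joint Bayesian inference: confusion model, behavior model, latent counts.

Three fits are provided:

* :func:`fit_confusion` — learn a classifier's confusion profile (mean rates
  ``mu``, consistency shapes ``alpha``, count dispersion ``tau`` and the
  per-recording rates ``lambda``) from human-annotated 15-s windows, using
  the exact marginal likelihood of the observed totals.
* :func:`naive_fit` — fit the speech-behavior model treating classifier
  counts as if they were true counts (the uncalibrated comparator).
* :func:`fit_joint` — the calibrated fit: true recording-level counts are
  latent, informed from above by the behavior model and from below by the
  classifier output through the confusion model, with the confusion
  parameters learned simultaneously from calibration windows.

All fits run the blocked adaptive Metropolis sampler from :mod:`.mcmc`;
conditionally independent units (recordings, children, matrix cells) are
updated in parallel.  Results are :class:`~vocalib.mcmc.PosteriorSamples`
with split-R̂/ESS diagnostics attached.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .confusion import (
    ENUMERATION_CAP,
    ConfusionProfile,
    conv_sum_logpmf,
    sample_confusion,
    simulate_counts,
)
from .behavior import BehaviorParams, SyntheticCorpus, age_basis, simulate_true_counts
from .dpo import LognormTable
from .mcmc import AdaptiveCovProposal, AdaptiveScales, MCMCConfig, PosteriorSamples
from .segments_io import ClipCounts
from .speakers import N_CLASSES, SPEAKER_LABELS

__all__ = [
    "ConfusionPriors",
    "BehaviorConfig",
    "CalibrationDataset",
    "fit_confusion",
    "fit_joint",
    "naive_fit",
    "coverage_calibration",
    "dataset_from_frames",
]

THETA_NAMES = (
    "mu_pop",
    "sigma_corpus",
    "sigma_child",
    "beta_sib_och",
    "beta_sib_adu",
    "alpha_dev",
    "sigma_dev",
    "beta_dev",
    "phi",
)


@dataclass(frozen=True)
class ConfusionPriors:
    """Priors on the confusion hyperparameters.

    Mean rates: half-normal(mu_sd); shapes: Pareto(1, alpha_shape) truncated
    to >= 1; dispersion: half-normal(tau_sd).
    """

    mu_sd: float = 1.0
    alpha_shape: float = 1.5
    tau_sd: float = 1.0


@dataclass(frozen=True)
class BehaviorConfig:
    """Priors and coding choices for the speech-behavior model."""

    sib_coding: str = "binary"
    mu_pop_loc: float = 4.0
    mu_pop_sd: float = 3.0
    effect_sd: float = 1.0  # N(0, effect_sd) on unconstrained effects
    sigma_sd: float = 1.0  # half-normal on hierarchy SDs
    phi_log_loc: float = 2.3  # lognormal prior on the count dispersion
    phi_log_sd: float = 1.0


@dataclass
class CalibrationDataset:
    """Calibration clips plus recording-level counts for one classifier."""

    clips: list[ClipCounts]
    recordings: pd.DataFrame
    classifier: str


def dataset_from_frames(
    metadata: pd.DataFrame,
    counts: pd.DataFrame,
    classifier: str,
    clips: Sequence[ClipCounts] = (),
) -> CalibrationDataset:
    """Assemble a dataset from a metadata table and a tidy counts table.

    ``counts`` columns: recording_id, annotator_id, CHI, OCH, FEM, MAL.
    """
    sub = counts[counts["annotator_id"] == classifier]
    merged = metadata.merge(
        sub[["recording_id", *SPEAKER_LABELS]].rename(
            columns={s: f"n_{s}" for s in SPEAKER_LABELS}
        ),
        on="recording_id",
        how="inner",
    )
    return CalibrationDataset(clips=list(clips), recordings=merged, classifier=classifier)


# ===================================================================== helpers


def _mh(delta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    delta = np.asarray(delta, dtype=float)
    return np.log(rng.random(delta.shape)) < delta


def _halfnormal_lp(x, sd):
    return -0.5 * (np.asarray(x) / sd) ** 2


def _gamma_lp(x, shape, rate):
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


# ------------------------------------------------------------- clip-side data


@dataclass
class _ClipData:
    V: np.ndarray  # (W, 4) human counts
    N: np.ndarray  # (W, 4) classifier counts
    rec_idx: np.ndarray  # (W,)
    n_rec: int
    rec_ids: list[str]

    @classmethod
    def from_clips(cls, clips: Sequence[ClipCounts], classifier: str | None) -> "_ClipData":
        clips = list(clips)
        if not clips:
            return cls(
                V=np.zeros((0, N_CLASSES), dtype=np.int64),
                N=np.zeros((0, N_CLASSES), dtype=np.int64),
                rec_idx=np.zeros(0, dtype=np.int64),
                n_rec=0,
                rec_ids=[],
            )
        if classifier is None:
            names = sorted({k for c in clips for k in c.n})
            if len(names) != 1:
                raise ValueError(
                    f"clips carry counts for {names}; pass classifier= to pick one"
                )
            classifier = names[0]
        rec_ids = sorted({c.recording_id for c in clips})
        index = {r: k for k, r in enumerate(rec_ids)}
        V = np.stack([c.v for c in clips])
        N = np.stack([c.n[classifier] for c in clips])
        if np.any(V > ENUMERATION_CAP) or np.any(N > ENUMERATION_CAP):
            raise ValueError(
                f"per-window counts above {ENUMERATION_CAP} cannot be marginalized "
                "exactly; use smaller windows"
            )
        rec = np.array([index[c.recording_id] for c in clips], dtype=np.int64)
        return cls(V=V, N=N, rec_idx=rec, n_rec=len(rec_ids), rec_ids=rec_ids)

    def col_loglik(self, lam_col: np.ndarray, tau: float, j: int, table=None) -> np.ndarray:
        """Per-recording log P(n_j | v, lambda, tau) summed over windows.

        ``lam_col`` has shape (n_rec, 4): the rates feeding target class j.
        With a table, dispatches to the numba kernel when available (same
        interpolated normalization; the numpy path is the exact reference).
        """
        from . import _fast
        from .dpo import _y_tables

        if table is not None and _fast.HAVE_NUMBA:
            lgam, ylogy = _y_tables(64)
            return _fast.col_loglik_kernel(
                np.ascontiguousarray(lam_col),
                table.tau,
                self.V.astype(np.float64),
                self.N[:, j].astype(np.int64),
                self.rec_idx,
                self.n_rec,
                table._log_grid,
                table._log_raw,
                table._values,
                lgam,
                ylogy,
                table.m_lo,
                table.m_hi,
            )
        means = self.V * lam_col[self.rec_idx]
        ll = conv_sum_logpmf(means, self.N[:, j], tau, table=table)
        return np.bincount(self.rec_idx, weights=ll, minlength=self.n_rec)


def _g_col_prior(lg_col: np.ndarray, alpha_col: np.ndarray) -> np.ndarray:
    """Per-recording log prior of a column of relative rates g (log-param).

    Non-centered parameterization: lambda_kij = mu_ij * g_kij with
    g ~ Gamma(alpha_ij, alpha_ij) (mean 1), so the population means enter
    the likelihood directly and mix without dragging the per-recording
    rates through their prior.
    """
    g = np.exp(lg_col)
    return (_gamma_lp(g, alpha_col[None, :], alpha_col[None, :]) + lg_col).sum(axis=1)


def _hyper_lp(lmu, zal, priors: ConfusionPriors):
    """Elementwise log prior (4,4) of (mu, alpha) in sampling coordinates."""
    mu = np.exp(lmu)
    lp_mu = _halfnormal_lp(mu, priors.mu_sd) + lmu
    # alpha = 1 + exp(z): Pareto(1, shape) density ~ alpha^-(shape+1), Jacobian exp(z)
    lp_al = -(priors.alpha_shape + 1.0) * np.log1p(np.exp(zal)) + zal
    return lp_mu + lp_al


def _mu_col_lp(lmu_col, priors: ConfusionPriors):
    return (_halfnormal_lp(np.exp(lmu_col), priors.mu_sd) + lmu_col).sum()


def _prior_refresh_mu(lmu, col_ll, eval_col, priors, rng):
    """Independence move: redraw one random mu cell per column from its prior.

    The half-normal prior doubles as the proposal, so the acceptance ratio
    reduces to the likelihood ratio; gives weakly identified cells (whose
    conditional is close to the prior) a chance to jump their heavy tails.
    """
    for j in range(4):
        i = int(rng.integers(4))
        mu_star = abs(rng.normal(0.0, priors.mu_sd)) + 1e-12
        lmu_p = lmu.copy()
        lmu_p[i, j] = np.log(mu_star)
        prop_ll = eval_col(j, lmu_p)
        if bool(_mh(np.array(prop_ll.sum() - col_ll[:, j].sum()), rng)):
            lmu = lmu_p
            col_ll[:, j] = prop_ll
    return lmu


def _asis_scale_move(lmu, zal, g_sets, s_asis, priors, rng, warm, target):
    """Interweaving move: mu_ij *= e^d, g_kij *= e^-d (lambda invariant).

    The likelihood is untouched, so this slides the population rates along
    the mu-g ridge at prior-only cost; accepted cellwise.  ``g_sets`` is a
    list of (K, 4, 4) log-relative-rate arrays sharing the same profile.
    """
    alpha = 1.0 + np.exp(zal)
    delta = s_asis.scale * rng.standard_normal((4, 4))
    lmu_p = lmu + delta
    d = (
        _halfnormal_lp(np.exp(lmu_p), priors.mu_sd)
        + lmu_p
        - _halfnormal_lp(np.exp(lmu), priors.mu_sd)
        - lmu
    )
    for lg in g_sets:
        if lg.shape[0] == 0:
            continue
        lg_p = lg - delta[None]
        d += (
            (alpha[None] - 1.0) * lg_p - alpha[None] * np.exp(lg_p) + lg_p
            - (alpha[None] - 1.0) * lg + alpha[None] * np.exp(lg) - lg
        ).sum(axis=0)
    acc = _mh(d.ravel(), rng).reshape(4, 4)
    lmu = np.where(acc, lmu_p, lmu)
    for lg in g_sets:
        if lg.shape[0]:
            lg -= np.where(acc, delta, 0.0)[None]
    if warm:
        s_asis.adapt(acc, target)
    return lmu, acc


# ============================================================== fit_confusion


def _run_confusion_chain(data: _ClipData, cfg, priors, rng, store_lam):
    K = data.n_rec
    init_mu = np.full((4, 4), 0.05) + np.diag(np.full(4, 0.55))
    lmu = np.log(init_mu) + 0.05 * rng.standard_normal((4, 4))
    zal = np.log(2.0) + 0.2 * rng.standard_normal((4, 4))
    ltau = 0.1 * rng.standard_normal()
    lg = 0.1 * rng.standard_normal((K, 4, 4))  # log relative rates, mean ~1

    s_g = [AdaptiveScales((K,), init=0.25) for _ in range(4)]
    s_mu = [AdaptiveCovProposal(4, init=0.15) for _ in range(4)]
    s_al = AdaptiveScales((4, 4), init=0.4)
    s_asis = AdaptiveScales((4, 4), init=0.4)
    s_tau = AdaptiveScales((), init=0.15)

    m_hi = 3.0 * float(max(data.V.max(initial=1), 1)) + 8.0

    def make_table(t, warm=None):
        return None if K == 0 else LognormTable(t, m_hi, n_grid=288, m_lo=1e-4, warm_from=warm)

    def col_ll_j(j, t, table, lmu_=None, lg_=None):
        lmu_ = lmu if lmu_ is None else lmu_
        lg_ = lg if lg_ is None else lg_
        lam_col = np.exp(lmu_[:, j])[None, :] * np.exp(lg_[:, :, j])
        return data.col_loglik(lam_col, t, j, table=table)

    def all_cols(t, table):
        if K == 0:
            return np.zeros((0, 4))
        return np.stack([col_ll_j(j, t, table) for j in range(4)], axis=1)

    tau = float(np.exp(ltau))
    table = make_table(tau)
    col_ll = all_cols(tau, table)
    n_iter = cfg.warmup + cfg.samples
    out = {"mu": [], "alpha": [], "tau": []}
    if store_lam:
        out["lam"] = []
    accepts = {"g": 0.0, "mu": 0.0, "alpha": 0.0, "tau": 0.0}

    for it in range(n_iter):
        warm = it < cfg.warmup
        alpha = 1.0 + np.exp(zal)
        # -- per-recording relative rates, one target class at a time
        for j in range(4):
            if K == 0:
                break
            cur = lg[:, :, j]
            prop = cur + s_g[j].scale[:, None] * rng.standard_normal((K, 4))
            prop_ll = col_ll_j(j, tau, table, lg_=_set_col(lg, j, prop))
            delta = (
                prop_ll
                - col_ll[:, j]
                + _g_col_prior(prop, alpha[:, j])
                - _g_col_prior(cur, alpha[:, j])
            )
            acc = _mh(delta, rng)
            lg[acc, :, j] = prop[acc]
            col_ll[acc, j] = prop_ll[acc]
            if warm:
                s_g[j].adapt(acc, cfg.target_accept)
            accepts["g"] += acc.mean() / 4.0
        # -- population mean rates, one 4-vector column block at a time
        for j in range(4):
            prop_col = lmu[:, j] + s_mu[j].step(rng)
            lmu_p = _set_col(lmu, j, prop_col)
            if K:
                prop_ll = col_ll_j(j, tau, table, lmu_=lmu_p)
            else:
                prop_ll = np.zeros(0)
            delta = (
                prop_ll.sum()
                - col_ll[:, j].sum()
                + _mu_col_lp(prop_col, priors)
                - _mu_col_lp(lmu[:, j], priors)
            )
            if bool(_mh(np.array(delta), rng)):
                lmu = lmu_p
                if K:
                    col_ll[:, j] = prop_ll
                a = 1.0
            else:
                a = 0.0
            if warm:
                s_mu[j].update(lmu[:, j], a, cfg.target_accept)
            accepts["mu"] += a / 4.0
        # -- prior-refresh independence move for single cells
        if K:
            lmu = _prior_refresh_mu(
                lmu, col_ll, lambda j, lmu_p: col_ll_j(j, tau, table, lmu_=lmu_p), priors, rng
            )
        # -- interweaving: slide (mu, g) along the likelihood-invariant ridge
        if K:
            lmu, _ = _asis_scale_move(
                lmu, zal, [lg], s_asis, priors, rng, warm, cfg.target_accept
            )
        # -- consistency shapes, cell by cell (prior-only given g)
        prop_zal = zal + s_al.scale * rng.standard_normal((4, 4))
        new_al = 1.0 + np.exp(prop_zal)
        delta = _alpha_hyper_lp(prop_zal, priors) - _alpha_hyper_lp(zal, priors)
        if K:
            g = np.exp(lg)
            delta += _gamma_lp(g, new_al[None], new_al[None]).sum(axis=0)
            delta -= _gamma_lp(g, alpha[None], alpha[None]).sum(axis=0)
        acc = _mh(delta.ravel(), rng).reshape(4, 4)
        zal = np.where(acc, prop_zal, zal)
        if warm:
            s_al.adapt(acc, cfg.target_accept)
        accepts["alpha"] += acc.mean()
        # -- shared dispersion (alternate sweeps; it mixes fast anyway)
        if it % 2:
            prop_ltau = ltau + float(s_tau.scale) * rng.standard_normal()
            new_tau = float(np.exp(prop_ltau))
            new_table = make_table(new_tau, warm=table)
            prop_cols = all_cols(new_tau, new_table)
            delta = (
                prop_cols.sum()
                - col_ll.sum()
                + _halfnormal_lp(new_tau, priors.tau_sd)
                + prop_ltau
                - _halfnormal_lp(tau, priors.tau_sd)
                - ltau
            )
            acc_t = bool(_mh(np.array(delta), rng))
            if acc_t:
                ltau, tau, col_ll, table = prop_ltau, new_tau, prop_cols, new_table
            if warm:
                s_tau.adapt(float(acc_t), cfg.target_accept)
            accepts["tau"] += acc_t

        if not warm:
            out["mu"].append(np.exp(lmu))
            out["alpha"].append(1.0 + np.exp(zal))
            out["tau"].append(tau)
            if store_lam:
                out["lam"].append(np.exp(lmu)[None] * np.exp(lg))
    draws = {k: np.asarray(v) for k, v in out.items()}
    rates = {k: v / n_iter for k, v in accepts.items()}
    return draws, rates


def _set_col(arr: np.ndarray, j: int, col: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[..., j] = col
    return out


def _alpha_hyper_lp(zal, priors: ConfusionPriors):
    return -(priors.alpha_shape + 1.0) * np.log1p(np.exp(zal)) + zal


def fit_confusion(
    clips: Sequence[ClipCounts],
    mcmc_config: MCMCConfig | None = None,
    classifier: str | None = None,
    priors: ConfusionPriors = ConfusionPriors(),
    store_lam: bool = False,
) -> PosteriorSamples:
    """Posterior over a classifier's confusion profile from annotated clips.

    With no clips at all the sampler simply explores the prior (useful as a
    no-data sanity check); a single annotated recording is rejected because
    across-recording rate variation is then unidentifiable.
    """
    cfg = mcmc_config or MCMCConfig()
    data = _ClipData.from_clips(clips, classifier)
    if data.n_rec == 1:
        raise ValueError("need clips from at least 2 recordings (or none for a prior check)")
    per_chain, rates = [], []
    for seq in np.random.SeedSequence(cfg.seed).spawn(cfg.chains):
        draws, acc = _run_confusion_chain(data, cfg, priors, np.random.default_rng(seq), store_lam)
        per_chain.append(draws)
        rates.append(acc)
    post = PosteriorSamples.combine(per_chain)
    post.accept_rates = {k: float(np.mean([r[k] for r in rates])) for k in rates[0]}
    post.check_convergence(names=("mu", "tau"))
    return post


# ===================================================== behavior-model sampler


@dataclass
class _RecData:
    n_obs: np.ndarray  # (Kr, 4) classifier counts
    ageb: np.ndarray  # (Kr,) age basis in [0, 1]
    sib: np.ndarray  # (Kr,) sibling covariate
    child_idx: np.ndarray  # (Kr,)
    corpus_idx: np.ndarray  # (Kr,)
    child_corpus: np.ndarray  # (Ch,)
    n_child: int
    n_corpus: int
    rec_ids: list[str]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sib_coding: str) -> "_RecData":
        required = ["recording_id", "child_id", "corpus_id", "age_months", "n_siblings"] + [
            f"n_{s}" for s in SPEAKER_LABELS
        ]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"recordings table is missing columns: {missing}")
        if frame[required].isna().any().any():
            bad = frame.loc[frame[required].isna().any(axis=1), "recording_id"].tolist()
            raise ValueError(f"missing covariates for recordings: {bad}")
        children = sorted(frame["child_id"].unique())
        corpora = sorted(frame["corpus_id"].unique())
        ch_index = {c: k for k, c in enumerate(children)}
        co_index = {c: k for k, c in enumerate(corpora)}
        child_idx = frame["child_id"].map(ch_index).to_numpy()
        corpus_idx = frame["corpus_id"].map(co_index).to_numpy()
        child_corpus = np.zeros(len(children), dtype=np.int64)
        child_corpus[child_idx] = corpus_idx
        n_sib = frame["n_siblings"].to_numpy(dtype=float)
        sib = (n_sib > 0).astype(float) if sib_coding == "binary" else n_sib
        return cls(
            n_obs=frame[[f"n_{s}" for s in SPEAKER_LABELS]].to_numpy(dtype=np.int64),
            ageb=np.asarray(age_basis(frame["age_months"].to_numpy(dtype=float))),
            sib=sib,
            child_idx=child_idx,
            corpus_idx=corpus_idx,
            child_corpus=child_corpus,
            n_child=len(children),
            n_corpus=len(corpora),
            rec_ids=frame["recording_id"].tolist(),
        )


class _BehaviorCore:
    """Behavior-model state and Metropolis blocks shared by all fits.

    ``obs_fn(rates, phi)`` returns the (Kr, 4) observation log likelihood of
    whatever plays the role of the data — integer counts for the naive fit,
    the continuous latent counts for the joint fit.
    """

    SCALARS = ("b_och", "b_adu", "a_dev", "b_dev", "lsig_c", "lsig_ch", "lsig_dev", "lphi")

    def __init__(self, rec: _RecData, cfg: BehaviorConfig, rng: np.random.Generator, init_mu_pop):
        self.rec = rec
        self.cfg = cfg
        self.mu_pop = init_mu_pop + 0.2 * rng.standard_normal(4)
        self.corpus_raw = 0.1 * rng.standard_normal((rec.n_corpus, 4))
        self.child_raw = 0.1 * rng.standard_normal((rec.n_child, 4))
        self.a_raw = 0.1 * rng.standard_normal(rec.n_child)
        self.b_och = 0.1 * rng.standard_normal()
        self.b_adu = 0.1 * rng.standard_normal()
        self.a_dev = 0.3 + 0.1 * rng.standard_normal()
        self.b_dev = 0.1 * rng.standard_normal()
        self.lsig_c = np.log(0.2) + 0.1 * rng.standard_normal()
        self.lsig_ch = np.log(0.3) + 0.1 * rng.standard_normal()
        self.lsig_dev = np.log(0.2) + 0.1 * rng.standard_normal()
        self.lphi = np.log(8.0) + 0.1 * rng.standard_normal()
        self.s_child = AdaptiveScales((rec.n_child,), init=0.2)
        self.s_araw = AdaptiveScales((rec.n_child,), init=0.3)
        self.s_corpus = AdaptiveScales((rec.n_corpus,), init=0.2)
        self.s_mu_pop = AdaptiveScales((), init=0.1)
        self.s_scalar = {name: AdaptiveScales((), init=0.1) for name in self.SCALARS}
        # joint proposal over the strongly correlated fixed effects and
        # variance parameters: mu_pop (4), sibling effects, age slope,
        # long-term input effect, log hierarchy SDs, log dispersion
        self.s_glob = AdaptiveCovProposal(12, init=0.03)
        self.s_shift_child = AdaptiveScales((4,), init=0.1)
        self.s_shift_corpus = AdaptiveScales((4,), init=0.1)
        self.s_shift_slope = AdaptiveScales((), init=0.15)
        self.s_scale_dev = AdaptiveScales((), init=0.3)
        self.s_scale_ch = AdaptiveScales((), init=0.2)
        self.s_scale_c = AdaptiveScales((), init=0.2)

    # ------------------------------------------------------------ deterministic
    @property
    def phi(self) -> float:
        return float(np.exp(self.lphi))

    def log_rates(self, **override) -> np.ndarray:
        get = lambda name: override.get(name, getattr(self, name))
        rec = self.rec
        mu_pop = get("mu_pop")
        sig_c, sig_ch = np.exp(get("lsig_c")), np.exp(get("lsig_ch"))
        mu_child = (
            mu_pop[None, :]
            + sig_c * get("corpus_raw")[rec.child_corpus]
            + sig_ch * get("child_raw")
        )
        s0 = float(np.hypot(sig_c, sig_ch)) + 1e-3
        ail = (
            np.logaddexp(mu_child[:, 2], mu_child[:, 3])
            - np.logaddexp(mu_pop[2], mu_pop[3])
        ) / s0
        slope = get("a_dev") + np.exp(get("lsig_dev")) * get("a_raw") + get("b_dev") * ail
        lr = mu_child[rec.child_idx].copy()
        lr[:, 1] += get("b_och") * rec.sib
        lr[:, 2] += get("b_adu") * rec.sib
        lr[:, 3] += get("b_adu") * rec.sib
        lr[:, 0] += slope[rec.child_idx] * rec.ageb
        return lr

    def ail(self) -> np.ndarray:
        """Per-child standardized adult-input covariate at the current state."""
        sig_c, sig_ch = float(np.exp(self.lsig_c)), float(np.exp(self.lsig_ch))
        mu_child = (
            self.mu_pop[None, :]
            + sig_c * self.corpus_raw[self.rec.child_corpus]
            + sig_ch * self.child_raw
        )
        s0 = float(np.hypot(sig_c, sig_ch)) + 1e-3
        return (
            np.logaddexp(mu_child[:, 2], mu_child[:, 3])
            - np.logaddexp(self.mu_pop[2], self.mu_pop[3])
        ) / s0

    # ------------------------------------------------------------------ priors
    def _scalar_prior(self, name: str, value: float) -> float:
        cfg = self.cfg
        if name in ("b_och", "b_adu", "a_dev", "b_dev"):
            return float(-0.5 * (value / cfg.effect_sd) ** 2)
        if name in ("lsig_c", "lsig_ch", "lsig_dev"):
            sigma = np.exp(value)
            return float(_halfnormal_lp(sigma, cfg.sigma_sd) + value)
        if name == "lphi":
            return float(-0.5 * ((value - cfg.phi_log_loc) / cfg.phi_log_sd) ** 2)
        raise KeyError(name)

    # ------------------------------------------------------------------- sweep
    def sweep(self, obs_fn: Callable, obs: np.ndarray, rng, warm: bool, target: float):
        """One pass over all behavior blocks; returns the updated obs cache."""
        rec, cfg = self.rec, self.cfg

        def block(field, scales, unit_idx, n_unit):
            nonlocal obs
            cur = getattr(self, field)
            eps = rng.standard_normal(cur.shape)
            if cur.ndim == 2:
                prop = cur + scales.scale[:, None] * eps
            else:
                prop = cur + scales.scale * eps
            rates_p = self.log_rates(**{field: prop})
            obs_p = obs_fn(rates_p, self.phi)
            d_obs = np.bincount(unit_idx, weights=(obs_p - obs).sum(axis=1), minlength=n_unit)
            if cur.ndim == 2:
                d_prior = -0.5 * (prop**2 - cur**2).sum(axis=1)
            else:
                d_prior = -0.5 * (prop**2 - cur**2)
            acc = _mh(d_obs + d_prior, rng)
            new = np.where((acc[:, None] if cur.ndim == 2 else acc), prop, cur)
            setattr(self, field, new)
            acc_rec = acc[unit_idx]
            obs = np.where(acc_rec[:, None], obs_p, obs)
            if warm:
                scales.adapt(acc, target)

        block("child_raw", self.s_child, rec.child_idx, rec.n_child)
        block("a_raw", self.s_araw, rec.child_idx, rec.n_child)
        block("corpus_raw", self.s_corpus, rec.corpus_idx, rec.n_corpus)

        # population log-rates as one 4-dim block
        prop = self.mu_pop + float(self.s_mu_pop.scale) * rng.standard_normal(4)
        obs_p = obs_fn(self.log_rates(mu_pop=prop), self.phi)
        delta = (obs_p - obs).sum()
        delta += (-0.5 * ((prop - cfg.mu_pop_loc) / cfg.mu_pop_sd) ** 2).sum()
        delta -= (-0.5 * ((self.mu_pop - cfg.mu_pop_loc) / cfg.mu_pop_sd) ** 2).sum()
        if bool(_mh(np.array(delta), rng)):
            self.mu_pop, obs = prop, obs_p
            acc = 1.0
        else:
            acc = 0.0
        if warm:
            self.s_mu_pop.adapt(acc, target)

        for name in self.SCALARS:
            cur = getattr(self, name)
            prop = cur + float(self.s_scalar[name].scale) * rng.standard_normal()
            phi = float(np.exp(prop)) if name == "lphi" else self.phi
            obs_p = obs_fn(self.log_rates(**({} if name == "lphi" else {name: prop})), phi)
            delta = (obs_p - obs).sum() + self._scalar_prior(name, prop) - self._scalar_prior(name, cur)
            if bool(_mh(np.array(delta), rng)):
                setattr(self, name, prop)
                obs = obs_p
                acc = 1.0
            else:
                acc = 0.0
            if warm:
                self.s_scalar[name].adapt(acc, target)

        # joint move along the correlated global directions
        glob_names = ("b_och", "b_adu", "a_dev", "b_dev", "lsig_c", "lsig_ch", "lsig_dev", "lphi")
        x = np.concatenate([self.mu_pop, [getattr(self, n) for n in glob_names]])
        prop = x + self.s_glob.step(rng)
        override = {"mu_pop": prop[:4]}
        override.update({n: prop[4 + i] for i, n in enumerate(glob_names) if n != "lphi"})
        phi_p = float(np.exp(prop[4 + glob_names.index("lphi")]))
        obs_p = obs_fn(self.log_rates(**override), phi_p)
        delta = (obs_p - obs).sum()
        delta += (-0.5 * ((prop[:4] - cfg.mu_pop_loc) / cfg.mu_pop_sd) ** 2).sum()
        delta -= (-0.5 * ((self.mu_pop - cfg.mu_pop_loc) / cfg.mu_pop_sd) ** 2).sum()
        for i, n in enumerate(glob_names):
            delta += self._scalar_prior(n, prop[4 + i]) - self._scalar_prior(n, getattr(self, n))
        if bool(_mh(np.array(delta), rng)):
            self.mu_pop = prop[:4].copy()
            for i, n in enumerate(glob_names):
                setattr(self, n, float(prop[4 + i]))
            obs = obs_p
            a = 1.0
        else:
            a = 0.0
        if warm:
            x_now = np.concatenate([self.mu_pop, [getattr(self, n) for n in glob_names]])
            self.s_glob.update(x_now, a, target)

        obs = self._translation_moves(obs_fn, obs, rng, warm, target)
        return obs

    def _translation_moves(self, obs_fn, obs, rng, warm, target):
        """Interweaving moves along hierarchical location ridges.

        Shifting a population log-rate while counter-shifting the child (or
        corpus) deviations leaves every child-level rate — and hence the
        likelihood — unchanged for CHI and OCH; for the adult classes the
        standardized-input covariate moves slightly, so the likelihood is
        re-evaluated.  Same idea for the mean age slope against the child
        slopes.  Without these moves the population means and the mean
        slope mix at the pace of the slowest random-effect average."""
        sig_ch = float(np.exp(self.lsig_ch))
        sig_c = float(np.exp(self.lsig_c))
        for field, scales, sig in (
            ("child_raw", self.s_shift_child, sig_ch),
            ("corpus_raw", self.s_shift_corpus, sig_c),
        ):
            raw = getattr(self, field)
            for cls in range(4):
                delta = float(scales.scale[cls]) * rng.standard_normal()
                d = delta / max(sig, 1e-8)
                mu_p = self.mu_pop.copy()
                mu_p[cls] += delta
                col = raw[:, cls]
                lp = -0.5 * ((col - d) ** 2 - col**2).sum()
                lp += -0.5 * ((mu_p[cls] - self.cfg.mu_pop_loc) ** 2 - (self.mu_pop[cls] - self.cfg.mu_pop_loc) ** 2) / self.cfg.mu_pop_sd**2
                if cls >= 2:
                    # adult reference in the input covariate moves: re-evaluate
                    raw_p = raw.copy()
                    raw_p[:, cls] -= d
                    obs_p = obs_fn(self.log_rates(mu_pop=mu_p, **{field: raw_p}), self.phi)
                    lp += (obs_p - obs).sum()
                acc = bool(_mh(np.array(lp), rng))
                if acc:
                    self.mu_pop = mu_p
                    raw[:, cls] -= d
                    if cls >= 2:
                        obs = obs_p
                if warm:
                    vec = np.zeros(4)
                    vec[cls] = float(acc) - target
                    scales.log_scale += min(0.25, 3.0 / np.sqrt(scales._t + 10.0)) * vec
                    scales._t += 0.25
        # mean age slope against child slopes (fully likelihood-invariant)
        sig_dev = float(np.exp(self.lsig_dev))
        delta = float(self.s_shift_slope.scale) * rng.standard_normal()
        d = delta / max(sig_dev, 1e-8)
        a_dev_p = self.a_dev + delta
        lp = -0.5 * ((self.a_raw - d) ** 2 - self.a_raw**2).sum()
        lp += self._scalar_prior("a_dev", a_dev_p) - self._scalar_prior("a_dev", self.a_dev)
        acc = bool(_mh(np.array(lp), rng))
        if acc:
            self.a_dev = float(a_dev_p)
            self.a_raw = self.a_raw - d
        if warm:
            self.s_shift_slope.adapt(float(acc), target)

        # scale interweaves: grow a hierarchy SD while shrinking its raw
        # deviations, keeping the realized effects — and so the likelihood —
        # fixed (exactly for the slope SD; up to the input-covariate
        # standardization for the corpus/child SDs, which is re-evaluated)
        for name, raw_field, scl in (
            ("lsig_dev", "a_raw", self.s_scale_dev),
            ("lsig_ch", "child_raw", self.s_scale_ch),
            ("lsig_c", "corpus_raw", self.s_scale_c),
        ):
            delta = float(scl.scale) * rng.standard_normal()
            cur = getattr(self, name)
            raw = getattr(self, raw_field)
            raw_p = raw * np.exp(-delta)
            lp = -0.5 * (raw_p**2 - raw**2).sum() - raw.size * delta
            lp += self._scalar_prior(name, cur + delta) - self._scalar_prior(name, cur)
            obs_p = None
            if name != "lsig_dev":
                obs_p = obs_fn(
                    self.log_rates(**{name: cur + delta, raw_field: raw_p}), self.phi
                )
                lp += (obs_p - obs).sum()
            acc = bool(_mh(np.array(lp), rng))
            if acc:
                setattr(self, name, float(cur + delta))
                setattr(self, raw_field, raw_p)
                if obs_p is not None:
                    obs = obs_p
            if warm:
                scl.adapt(float(acc), target)
        return obs

    def theta_draws(self) -> dict[str, np.ndarray | float]:
        return {
            "mu_pop": self.mu_pop.copy(),
            "sigma_corpus": float(np.exp(self.lsig_c)),
            "sigma_child": float(np.exp(self.lsig_ch)),
            "beta_sib_och": float(self.b_och),
            "beta_sib_adu": float(self.b_adu),
            "alpha_dev": float(self.a_dev),
            "sigma_dev": float(np.exp(self.lsig_dev)),
            "beta_dev": float(self.b_dev),
            "phi": self.phi,
        }


def _nb_logpmf(y, mean, phi):
    return (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1.0)
        + phi * np.log(phi / (phi + mean))
        + y * np.log(mean / (phi + mean))
    )


def _gamma_obs_lp(v, log_rates, phi):
    """Continuous relaxation of the gamma-Poisson count law for latent v.

    A Gamma density matched to the negative binomial's first two moments
    (mean r, variance r + r^2/phi): shape = r phi / (phi + r).
    """
    r = np.exp(log_rates)
    shape = r * phi / (phi + r)
    rate = shape / r
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(v) - rate * v


# ================================================================== naive fit


def naive_fit(
    dataset: CalibrationDataset,
    behavior_config: BehaviorConfig | None = None,
    mcmc_config: MCMCConfig | None = None,
) -> PosteriorSamples:
    """Behavior-model fit that treats classifier counts as true counts."""
    bcfg = behavior_config or BehaviorConfig()
    cfg = mcmc_config or MCMCConfig()
    rec = _RecData.from_frame(dataset.recordings, bcfg.sib_coding)
    y = rec.n_obs.astype(float)
    init_mu_pop = np.log(np.maximum(y.mean(axis=0), 1.0))

    def obs_fn(log_rates, phi):
        return _nb_logpmf(y, np.exp(log_rates), phi)

    per_chain = []
    for seq in np.random.SeedSequence(cfg.seed).spawn(cfg.chains):
        rng = np.random.default_rng(seq)
        core = _BehaviorCore(rec, bcfg, rng, init_mu_pop)
        obs = obs_fn(core.log_rates(), core.phi)
        draws: dict[str, list] = {k: [] for k in THETA_NAMES}
        for it in range(cfg.warmup + cfg.samples):
            obs = core.sweep(obs_fn, obs, rng, it < cfg.warmup, cfg.target_accept)
            if it >= cfg.warmup:
                for k, val in core.theta_draws().items():
                    draws[k].append(val)
        per_chain.append({k: np.asarray(v) for k, v in draws.items()})
    post = PosteriorSamples.combine(per_chain)
    post.check_convergence(names=("beta", "alpha_dev", "mu_pop"))
    return post


# ================================================================== joint fit


def _run_joint_chain(rec, clip_data, cfg, bcfg, priors, fixed, rng, store_v):
    Kr = rec.n_obs.shape[0]
    Kc = clip_data.n_rec
    m_max = float(rec.n_obs.max()) * 4.0 + 100.0
    m_hi_clip = 3.0 * float(max(clip_data.V.max(initial=1), 1)) + 8.0

    if fixed is not None:
        lmu = np.log(np.maximum(fixed.mu, 1e-4))
        zal = np.log(np.maximum(fixed.alpha - 1.0, 1e-6))
        ltau = float(np.log(fixed.tau))
    else:
        init_mu = np.full((4, 4), 0.05) + np.diag(np.full(4, 0.55))
        lmu = np.log(init_mu) + 0.05 * rng.standard_normal((4, 4))
        zal = np.log(2.0) + 0.2 * rng.standard_normal((4, 4))
        ltau = 0.1 * rng.standard_normal()
    tau = float(np.exp(ltau))
    lg_r = 0.25 * rng.standard_normal((Kr, 4, 4))
    lg_c = 0.25 * rng.standard_normal((Kc, 4, 4))

    diag0 = np.clip(np.exp(np.diagonal(lmu)), 0.2, None)
    # overdispersed chain starts so that pooled chains expose, rather than
    # hide, incomplete exploration of the latent counts
    lv = np.log(np.maximum(rec.n_obs / diag0[None, :], 0.5)) + 0.25 * rng.standard_normal(
        (Kr, 4)
    )

    init_mu_pop = np.log(np.maximum(np.exp(lv).mean(axis=0), 1.0))
    core = _BehaviorCore(rec, bcfg, rng, init_mu_pop)

    def obs_fn(log_rates, phi):
        return _gamma_obs_lp(np.exp(lv), log_rates, phi)

    table = LognormTable(tau, m_max, n_grid=320, m_lo=1e-4)
    ctable = None if Kc == 0 else LognormTable(tau, m_hi_clip, n_grid=288, m_lo=1e-4)

    from . import _fast

    def eq4_col(j, tab, lmu_=None, lg_=None, lv_=None):
        lmu_ = lmu if lmu_ is None else lmu_
        lg_ = lg_r if lg_ is None else lg_
        lv_ = lv if lv_ is None else lv_
        lam_col = np.exp(lmu_[:, j])[None, :] * np.exp(lg_[:, :, j])
        if _fast.HAVE_NUMBA:
            return _fast.recording_col_kernel(
                lam_col,
                np.exp(lv_),
                rec.n_obs[:, j],
                tab.tau,
                tab._log_grid,
                tab._log_raw,
                tab._values,
                tab.m_lo,
                tab.m_hi,
            )
        m = (np.exp(lv_) * lam_col).sum(axis=1)
        return tab.logpmf(rec.n_obs[:, j], np.maximum(m, 1e-10))

    def eq4_all(tab, lv_=None):
        return np.stack([eq4_col(j, tab, lv_=lv_) for j in range(4)], axis=1)

    def clip_col(j, t, ctab, lmu_=None, lg_=None):
        lmu_ = lmu if lmu_ is None else lmu_
        lg_ = lg_c if lg_ is None else lg_
        lam_col = np.exp(lmu_[:, j])[None, :] * np.exp(lg_[:, :, j])
        return clip_data.col_loglik(lam_col, t, j, table=ctab)

    def clip_all(t, ctab):
        if Kc == 0:
            return np.zeros((0, 4))
        return np.stack([clip_col(j, t, ctab) for j in range(4)], axis=1)

    obs = obs_fn(core.log_rates(), core.phi)
    ll_eq4 = eq4_all(table)  # (Kr, 4)
    col_ll = clip_all(tau, ctable)  # (Kc, 4)

    s_v = AdaptiveScales((Kr, 4), init=0.15)
    s_vg = AdaptiveScales((Kr, 4), init=0.2)
    s_v4 = AdaptiveScales((Kr,), init=0.08)
    s_g_r = [AdaptiveScales((Kr,), init=0.2) for _ in range(4)]
    s_g_c = [AdaptiveScales((Kc,), init=0.25) for _ in range(4)]
    s_mu = [AdaptiveCovProposal(4, init=0.1) for _ in range(4)]
    s_al = AdaptiveScales((4, 4), init=0.4)
    s_asis = AdaptiveScales((4, 4), init=0.4)
    s_row = [AdaptiveScales((), init=0.1) for _ in range(4)]
    s_phi_iw = AdaptiveScales((), init=0.2)
    s_carry = {n: AdaptiveScales((), init=0.1) for n in ("b_och", "b_adu", "a_dev", "b_dev")}
    s_tau = AdaptiveScales((), init=0.08)

    names = list(THETA_NAMES) + (["mu", "alpha", "tau"] if fixed is None else [])
    out: dict[str, list] = {k: [] for k in names}
    if store_v:
        out["v"] = []

    for it in range(cfg.warmup + cfg.samples):
        warm = it < cfg.warmup
        alpha = 1.0 + np.exp(zal)

        # -- latent true counts: one source class at a time, elementwise per
        #    recording (the four classes differ in scale by orders of
        #    magnitude, so each (recording, class) pair adapts its own step)
        rates_now = core.log_rates()
        for s_cls in range(4):
            prop_lv = lv.copy()
            prop_lv[:, s_cls] += s_v.scale[:, s_cls] * rng.standard_normal(Kr)
            eq4_p = eq4_all(table, lv_=prop_lv)
            obs_p = _gamma_obs_lp(np.exp(prop_lv), rates_now, core.phi)
            delta = (
                (eq4_p - ll_eq4).sum(1)
                + obs_p[:, s_cls]
                - obs[:, s_cls]
                + prop_lv[:, s_cls]
                - lv[:, s_cls]
            )
            acc = _mh(delta, rng)
            lv[acc, s_cls] = prop_lv[acc, s_cls]
            ll_eq4 = np.where(acc[:, None], eq4_p, ll_eq4)
            obs[acc, s_cls] = obs_p[acc, s_cls]
            if warm:
                s_v.scale_col_adapt(s_cls, acc, cfg.target_accept)

        # -- joint 4-vector proposal per recording (captures the
        #    cross-class anti-correlations that elementwise steps miss)
        prop_lv = lv + s_v4.scale[:, None] * rng.standard_normal((Kr, 4))
        eq4_p = eq4_all(table, lv_=prop_lv)
        obs_p = _gamma_obs_lp(np.exp(prop_lv), rates_now, core.phi)
        delta = (eq4_p - ll_eq4).sum(1) + (obs_p - obs).sum(1) + (prop_lv - lv).sum(1)
        acc = _mh(delta, rng)
        lv = np.where(acc[:, None], prop_lv, lv)
        ll_eq4 = np.where(acc[:, None], eq4_p, ll_eq4)
        obs = np.where(acc[:, None], obs_p, obs)
        if warm:
            s_v4.adapt(acc, cfg.target_accept)

        # -- per-recording scale interweave: v_ki and the i-th row of that
        #    recording's relative rates trade off (their product is what the
        #    classifier output constrains); sliding them jointly leaves the
        #    recording likelihood invariant and costs only prior terms
        rates_now = core.log_rates()
        alpha = 1.0 + np.exp(zal)
        for i in range(4):
            step = s_vg.scale[:, i] * rng.standard_normal(Kr)
            lv_p = lv[:, i] + step
            lg_rows = lg_r[:, i, :]  # (Kr, 4)
            lg_p = lg_rows - step[:, None]
            obs_col_p = _gamma_obs_lp(
                np.exp(lv_p)[:, None], rates_now[:, i][:, None], core.phi
            )[:, 0]
            a_row = alpha[i, :][None, :]
            d_prior = (
                (a_row - 1.0) * lg_p - a_row * np.exp(lg_p) + lg_p
                - (a_row - 1.0) * lg_rows + a_row * np.exp(lg_rows) - lg_rows
            ).sum(axis=1)
            delta = obs_col_p - obs[:, i] + step + d_prior
            acc = _mh(delta, rng)
            lv[acc, i] = lv_p[acc]
            lg_r[acc, i, :] = lg_p[acc]
            obs[acc, i] = obs_col_p[acc]
            if warm:
                s_vg.scale_col_adapt(i, acc, cfg.target_accept)

        # -- per-recording relative confusion rates for the corpus
        for j in range(4):
            cur = lg_r[:, :, j]
            prop = cur + s_g_r[j].scale[:, None] * rng.standard_normal((Kr, 4))
            ll_p = eq4_col(j, table, lg_=_set_col(lg_r, j, prop))
            delta = (
                ll_p
                - ll_eq4[:, j]
                + _g_col_prior(prop, alpha[:, j])
                - _g_col_prior(cur, alpha[:, j])
            )
            acc = _mh(delta, rng)
            lg_r[acc, :, j] = prop[acc]
            ll_eq4[acc, j] = ll_p[acc]
            if warm:
                s_g_r[j].adapt(acc, cfg.target_accept)

        if fixed is None:
            # -- relative rates in the calibration clips
            for j in range(4):
                if Kc == 0:
                    break
                cur = lg_c[:, :, j]
                prop = cur + s_g_c[j].scale[:, None] * rng.standard_normal((Kc, 4))
                ll_p = clip_col(j, tau, ctable, lg_=_set_col(lg_c, j, prop))
                delta = (
                    ll_p
                    - col_ll[:, j]
                    + _g_col_prior(prop, alpha[:, j])
                    - _g_col_prior(cur, alpha[:, j])
                )
                acc = _mh(delta, rng)
                lg_c[acc, :, j] = prop[acc]
                col_ll[acc, j] = ll_p[acc]
                if warm:
                    s_g_c[j].adapt(acc, cfg.target_accept)

            # -- population mean rates, column blocks (clips + corpus jointly)
            for j in range(4):
                prop_col = lmu[:, j] + s_mu[j].step(rng)
                lmu_p = _set_col(lmu, j, prop_col)
                eq4_pj = eq4_col(j, table, lmu_=lmu_p)
                clip_pj = clip_col(j, tau, ctable, lmu_=lmu_p) if Kc else np.zeros(0)
                delta = (
                    eq4_pj.sum()
                    - ll_eq4[:, j].sum()
                    + clip_pj.sum()
                    - col_ll[:, j].sum()
                    + _mu_col_lp(prop_col, priors)
                    - _mu_col_lp(lmu[:, j], priors)
                )
                if bool(_mh(np.array(delta), rng)):
                    lmu = lmu_p
                    ll_eq4[:, j] = eq4_pj
                    if Kc:
                        col_ll[:, j] = clip_pj
                    a = 1.0
                else:
                    a = 0.0
                if warm:
                    s_mu[j].update(lmu[:, j], a, cfg.target_accept)

            # -- prior-refresh independence move for single cells (the
            #    half-normal prior is the proposal, so the acceptance ratio
            #    is the likelihood ratio over both likelihood pieces)
            if Kc:
                for j in range(4):
                    i = int(rng.integers(4))
                    mu_star = abs(rng.normal(0.0, priors.mu_sd)) + 1e-12
                    lmu_p = lmu.copy()
                    lmu_p[i, j] = np.log(mu_star)
                    eq4_pj = eq4_col(j, table, lmu_=lmu_p)
                    clip_pj = clip_col(j, tau, ctable, lmu_=lmu_p)
                    delta = (
                        eq4_pj.sum()
                        + clip_pj.sum()
                        - ll_eq4[:, j].sum()
                        - col_ll[:, j].sum()
                    )
                    if bool(_mh(np.array(delta), rng)):
                        lmu = lmu_p
                        ll_eq4[:, j] = eq4_pj
                        col_ll[:, j] = clip_pj
            # -- interweaving: slide (mu, g) along the likelihood-invariant ridge
            lmu, _ = _asis_scale_move(
                lmu, zal, [lg_r, lg_c], s_asis, priors, rng, warm, cfg.target_accept
            )
            # -- row-scale interweaving: scaling every latent count of source
            #    class i up while scaling row i of the confusion means down
            #    leaves the recording-level likelihood invariant; carrying
            #    the population log-rate along keeps the behavior term nearly
            #    invariant too.  This is the slow global v <-> lambda ridge.
            for i in range(4):
                delta = float(s_row[i].scale) * rng.standard_normal()
                lv_p = lv.copy()
                lv_p[:, i] += delta
                lmu_p = lmu.copy()
                lmu_p[i, :] -= delta
                mu_pop_p = core.mu_pop.copy()
                mu_pop_p[i] += delta
                cols_p = np.stack(
                    [clip_col(j, tau, ctable, lmu_=lmu_p) for j in range(4)], axis=1
                ) if Kc else np.zeros((0, 4))
                obs_p = _gamma_obs_lp(
                    np.exp(lv_p), core.log_rates(mu_pop=mu_pop_p), core.phi
                )
                d = (obs_p - obs).sum() + cols_p.sum() - col_ll.sum() + Kr * delta
                d += (
                    _halfnormal_lp(np.exp(lmu_p[i, :]), priors.mu_sd) + lmu_p[i, :]
                    - _halfnormal_lp(np.exp(lmu[i, :]), priors.mu_sd) - lmu[i, :]
                ).sum()
                d += (
                    -0.5 * ((mu_pop_p[i] - bcfg.mu_pop_loc) ** 2 - (core.mu_pop[i] - bcfg.mu_pop_loc) ** 2)
                    / bcfg.mu_pop_sd**2
                )
                if bool(_mh(np.array(d), rng)):
                    lv, lmu, obs, col_ll = lv_p, lmu_p, obs_p, cols_p
                    core.mu_pop = mu_pop_p
                    a = 1.0
                else:
                    a = 0.0
                if warm:
                    s_row[i].adapt(a, cfg.target_accept)
            # -- consistency shapes (prior-only given relative rates)
            prop_zal = zal + s_al.scale * rng.standard_normal((4, 4))
            new_al = 1.0 + np.exp(prop_zal)
            delta = _alpha_hyper_lp(prop_zal, priors) - _alpha_hyper_lp(zal, priors)
            for g_set in (lg_r, lg_c):
                if g_set.shape[0] == 0:
                    continue
                g = np.exp(g_set)
                delta += _gamma_lp(g, new_al[None], new_al[None]).sum(axis=0)
                delta -= _gamma_lp(g, alpha[None], alpha[None]).sum(axis=0)
            acc = _mh(delta.ravel(), rng).reshape(4, 4)
            zal = np.where(acc, prop_zal, zal)
            if warm:
                s_al.adapt(acc, cfg.target_accept)

            # -- shared dispersion (alternate sweeps; it mixes fast anyway)
            if it % 2:
                prop_ltau = ltau + float(s_tau.scale) * rng.standard_normal()
                new_tau = float(np.exp(prop_ltau))
                new_table = LognormTable(new_tau, m_max, n_grid=320, m_lo=1e-4, warm_from=table)
                new_ctable = (
                    None
                    if Kc == 0
                    else LognormTable(new_tau, m_hi_clip, n_grid=288, m_lo=1e-4, warm_from=ctable)
                )
                eq4_t = eq4_all(new_table)
                cols_t = clip_all(new_tau, new_ctable)
                delta = (
                    eq4_t.sum()
                    - ll_eq4.sum()
                    + cols_t.sum()
                    - col_ll.sum()
                    + _halfnormal_lp(new_tau, priors.tau_sd)
                    + prop_ltau
                    - _halfnormal_lp(tau, priors.tau_sd)
                    - ltau
                )
                if bool(_mh(np.array(delta), rng)):
                    ltau, tau = prop_ltau, new_tau
                    table, ctable = new_table, new_ctable
                    ll_eq4, col_ll = eq4_t, cols_t
                    acc_t = 1.0
                else:
                    acc_t = 0.0
                if warm:
                    s_tau.adapt(acc_t, cfg.target_accept)

        # -- behavior blocks (the latent v are the observations here); run
        #    twice per sweep: they are cheap relative to the count likelihoods
        #    and the global parameters are the slowest-mixing quantities
        obs = core.sweep(obs_fn, obs, rng, warm, cfg.target_accept)
        obs = core.sweep(obs_fn, obs, rng, warm, cfg.target_accept)

        # -- effect-carry moves: shift an effect and carry the latent counts
        #    of the affected class along, so the behavior residuals stay put
        #    and only the recording-level count likelihood arbitrates
        ail_rec = core.ail()[rec.child_idx]
        for name, cls_cols, exposure in (
            ("b_och", (1,), rec.sib),
            ("b_adu", (2, 3), rec.sib),
            ("a_dev", (0,), rec.ageb),
            ("b_dev", (0,), rec.ageb * ail_rec),
        ):
            delta = float(s_carry[name].scale) * rng.standard_normal()
            cur = getattr(core, name)
            lv_p = lv.copy()
            for ccol in cls_cols:
                lv_p[:, ccol] += delta * exposure
            setattr(core, name, cur + delta)
            obs_p = _gamma_obs_lp(np.exp(lv_p), core.log_rates(), core.phi)
            setattr(core, name, cur)
            eq4_p = eq4_all(table, lv_=lv_p)
            d = (obs_p - obs).sum() + (eq4_p - ll_eq4).sum()
            d += core._scalar_prior(name, cur + delta) - core._scalar_prior(name, cur)
            d += delta * float(exposure.sum()) * len(cls_cols)  # log-v Jacobian
            if bool(_mh(np.array(d), rng)):
                setattr(core, name, float(cur + delta))
                lv, obs, ll_eq4 = lv_p, obs_p, eq4_p
                a = 1.0
            else:
                a = 0.0
            if warm:
                s_carry[name].adapt(a, cfg.target_accept)

        # -- dispersion vs latent-count spread: move phi while rescaling the
        #    latent counts' log deviations from their expected rates (the
        #    spread of v is what identifies phi, so moving them together
        #    escapes the hyperparameter funnel)
        delta = float(s_phi_iw.scale) * rng.standard_normal()
        lphi_p = core.lphi + delta
        c = float(np.exp(-delta / 2.0))
        lr = core.log_rates()
        lv_p = lr + (lv - lr) * c
        obs_p = _gamma_obs_lp(np.exp(lv_p), lr, float(np.exp(lphi_p)))
        eq4_p = eq4_all(table, lv_=lv_p)
        d = (obs_p - obs).sum() + (eq4_p - ll_eq4).sum()
        d += core._scalar_prior("lphi", lphi_p) - core._scalar_prior("lphi", core.lphi)
        d += lv.size * np.log(c) + (lv_p - lv).sum()  # transform + log-scale Jacobians
        if bool(_mh(np.array(d), rng)):
            core.lphi = float(lphi_p)
            lv, obs, ll_eq4 = lv_p, obs_p, eq4_p
            a = 1.0
        else:
            a = 0.0
        if warm:
            s_phi_iw.adapt(a, cfg.target_accept)

        if not warm:
            for k, val in core.theta_draws().items():
                out[k].append(val)
            if fixed is None:
                out["mu"].append(np.exp(lmu))
                out["alpha"].append(1.0 + np.exp(zal))
                out["tau"].append(tau)
            if store_v:
                out["v"].append(np.exp(lv))
    return {k: np.asarray(v) for k, v in out.items()}


def fit_joint(
    dataset: CalibrationDataset,
    behavior_config: BehaviorConfig | None = None,
    mcmc_config: MCMCConfig | None = None,
    priors: ConfusionPriors = ConfusionPriors(),
    fix_confusion: ConfusionProfile | None = None,
    store_v: bool = True,
) -> PosteriorSamples:
    """Calibrated joint fit: behavior parameters, confusion parameters and
    latent true counts, conditioned on classifier output plus calibration
    clips.

    If ``fix_confusion`` is given, the population confusion parameters are
    held at that profile (per-recording rates remain latent) and calibration
    clips are not needed — useful for coverage studies conditioned on a
    known classifier.
    """
    bcfg = behavior_config or BehaviorConfig()
    cfg = mcmc_config or MCMCConfig()
    rec = _RecData.from_frame(dataset.recordings, bcfg.sib_coding)
    clip_data = _ClipData.from_clips(dataset.clips, dataset.classifier)
    if fix_confusion is None and clip_data.n_rec < 2:
        raise ValueError(
            "joint calibration needs clips from >= 2 recordings (or fix_confusion=)"
        )
    per_chain = []
    for seq in np.random.SeedSequence(cfg.seed).spawn(cfg.chains):
        per_chain.append(
            _run_joint_chain(
                rec, clip_data, cfg, bcfg, priors, fix_confusion, np.random.default_rng(seq), store_v
            )
        )
    post = PosteriorSamples.combine(per_chain)
    post.check_convergence(names=("beta", "alpha_dev", "mu_pop", "tau"))
    return post


# ================================================================== coverage


def default_coverage_prior(rng: np.random.Generator) -> BehaviorParams:
    """Plausible behavior-parameter draws for coverage simulations."""
    base = BehaviorParams()
    return BehaviorParams(
        mu_pop=base.mu_pop + rng.normal(0.0, 0.4, size=4),
        sigma_corpus=rng.uniform(0.1, 0.35),
        sigma_child=rng.uniform(0.15, 0.4),
        beta_sib_och=rng.normal(0.0, 0.5),
        beta_sib_adu=rng.normal(0.0, 0.5),
        alpha_dev=rng.normal(0.5, 0.3),
        sigma_dev=rng.uniform(0.1, 0.3),
        beta_dev=rng.normal(0.0, 0.3),
        phi=rng.uniform(5.0, 15.0),
    )


def simulate_classifier_counts(
    corpus: SyntheticCorpus, profile: ConfusionProfile, rng, classifier: str = "classifier"
) -> pd.DataFrame:
    """Apply the confusion model to a synthetic corpus's true counts.

    Draws one confusion-rate matrix per recording, then double-Poisson
    counts; returns the recordings table with added ``n_*`` columns.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    frame = corpus.recordings.copy()
    v = corpus.true_counts()
    n = np.zeros_like(v)
    for k in range(v.shape[0]):
        draw = sample_confusion(profile, rng)
        n[k] = simulate_counts(v[k], draw, profile.tau, rng)
    for s, col in zip(SPEAKER_LABELS, n.T):
        frame[f"n_{s}"] = col
    frame["classifier"] = classifier
    return frame


def coverage_calibration(
    n_sims: int,
    params_prior: Callable[[np.random.Generator], BehaviorParams] | None = None,
    mcmc_config: MCMCConfig | None = None,
    profile: ConfusionProfile | None = None,
    levels: Sequence[float] = (0.5, 0.8, 0.9, 0.95),
    n_children: int = 15,
    recordings_per_child: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical coverage of latent-count credible intervals.

    Repeatedly: draw behavior parameters, simulate a corpus and its
    classifier counts, run the joint fit (conditioned on the true confusion
    profile), and check whether the central credible interval at each level
    contains the true count.  A well-calibrated posterior covers at the
    nominal rate.  Returns a table (level, coverage, se, n) with binomial
    standard errors.
    """
    if n_sims < 20:
        raise ValueError("n_sims must be >= 20 for a meaningful coverage estimate")
    params_prior = params_prior or default_coverage_prior
    profile = profile or _default_profile()
    cfg = mcmc_config or MCMCConfig(chains=2, warmup=400, samples=400)
    hits = {level: 0 for level in levels}
    total = 0
    for sim, seq in enumerate(np.random.SeedSequence(seed).spawn(n_sims)):
        rng = np.random.default_rng(seq)
        params = params_prior(rng)
        corpus = simulate_true_counts(params, n_children, recordings_per_child, rng)
        frame = simulate_classifier_counts(corpus, profile, rng)
        dataset = CalibrationDataset(clips=[], recordings=frame, classifier="classifier")
        post = fit_joint(
            dataset,
            mcmc_config=MCMCConfig(
                chains=cfg.chains, warmup=cfg.warmup, samples=cfg.samples, seed=int(sim)
            ),
            fix_confusion=profile,
        )
        truth = corpus.true_counts().astype(float)
        for level in levels:
            lo, hi = post.ci("v", level)
            hits[level] += int(((truth >= lo) & (truth <= hi)).sum())
        total += truth.size
    rows = []
    for level in levels:
        p = hits[level] / total
        rows.append(
            {
                "level": level,
                "coverage": p,
                "se": float(np.sqrt(max(p * (1 - p), 1e-12) / total)),
                "n": total,
            }
        )
    return pd.DataFrame(rows)


def _default_profile() -> ConfusionProfile:
    from .confusion import recall_biased_profile

    return recall_biased_profile()
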