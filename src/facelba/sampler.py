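"""Differential-evolution MCMC (DE-MCMC) for the hierarchical LBA.

Proposals for a chain are formed from the scaled difference of two
other randomly chosen chains' states plus a small uniform jitter,
``theta* = theta_i + gamma (theta_m - theta_n) + U(-b0, b0)``, which is
symmetric, so plain Metropolis acceptance applies.  The joint model is
updated in blocks: each subject's 7-parameter vector conditional on
its group's hypers (all subject blocks are conditionally independent
given the hypers, so they are proposed and accepted in parallel), then
each group's 14 hyperparameters conditional on the subject parameters.
During burn-in an occasional migration step rotates whole states among
a random subset of chains to stop isolated chains from stalling on a
mode.

Positivity constraints are enforced through the target: proposals
outside the support get ``-inf`` posterior density and are rejected,
never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .errors import (ConsistencyError, DataError, NumericalError,
                     SamplerLogicError)
from .hierarchy import HyperPriorConfig
from .lba_core import PARAM_NAMES

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_INIT_RETRIES = 100
#: evidence-unit parameter columns (A, k and the four drift means; not t0)
_EVID_COLS = np.array([0, 1, 3, 4, 5, 6])


def default_gamma(block_dim: int) -> float:
    """The standard DE-MCMC jump factor 2.38 / sqrt(2 d)."""
    return 2.38 / math.sqrt(2.0 * block_dim)


@dataclass(frozen=True)
class SamplerConfig:
    """DE-MCMC run settings.

    Defaults mirror the study's sampling effort: 20 interacting chains
    retaining 5000 samples each.  Burn-in, migration and jitter are
    unreported there and are configuration choices here.
    """

    n_chains: int = 20
    n_samples: int = 5000
    burn_in: int = 2500
    gamma: float | None = None  # None -> 2.38/sqrt(2d) per block
    jitter_b0: float = 0.001
    migration_prob: float = 0.1
    rescale_every: int = 2  # group evidence-scale move cadence; 0 disables
    rescale_step: float = 0.06  # SD of log scale factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 3:
            raise SamplerLogicError("DE crossover needs n_chains >= 3")
        if self.n_samples < 1 or self.burn_in < 0:
            raise SamplerLogicError("need n_samples >= 1 and burn_in >= 0")
        if self.jitter_b0 < 0:
            raise SamplerLogicError("jitter_b0 must be >= 0")
        if self.rescale_every < 0 or self.rescale_step <= 0:
            raise SamplerLogicError("invalid rescale settings")
        if not 0 <= self.migration_prob <= 1:
            raise SamplerLogicError("migration_prob must be in [0, 1]")


def de_propose(states: np.ndarray, i: int, m: int, n: int,
               gamma: float | None, jitter_b0: float,
               rng: np.random.Generator) -> np.ndarray:
    """Crossover proposal for chain ``i`` from partner chains ``m`` and ``n``.

    ``states`` is the (n_chains, d) block matrix.  The proposal is
    symmetric in the Metropolis sense, so no proposal-density
    correction is needed.
    """
    if m == n or m == i or n == i:
        raise SamplerLogicError(
            f"partner chains must be distinct from each other and from the "
            f"current chain (i={i}, m={m}, n={n})")
    d = states.shape[1]
    g = default_gamma(d) if gamma is None else gamma
    eps = rng.uniform(-jitter_b0, jitter_b0, size=d) if jitter_b0 > 0 else 0.0
    return states[i] + g * (states[m] - states[n]) + eps


def metropolis_accept(log_post_current: float, log_post_proposed: float,
                      rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(proposed - current))."""
    if math.isnan(log_post_current) or math.isnan(log_post_proposed):
        raise NumericalError("NaN log posterior in Metropolis step")
    if log_post_proposed == -np.inf:
        return False
    delta = log_post_proposed - log_post_current
    if delta >= 0:
        return True
    return math.log(rng.random()) < delta


def _partners(shape, n_chains: int, rng: np.random.Generator):
    """Two distinct partner chains (also distinct from self) per entry.

    ``shape`` is (n_chains,) or (n_chains, n_blocks); the first axis
    indexes the chain whose proposal is being built.
    """
    i = np.arange(n_chains).reshape((-1,) + (1,) * (len(shape) - 1))
    i = np.broadcast_to(i, shape)
    r1 = rng.integers(0, n_chains - 1, size=shape)
    r1 = r1 + (r1 >= i)
    r2 = rng.integers(0, n_chains - 2, size=shape)
    lo = np.minimum(i, r1)
    hi = np.maximum(i, r1)
    r2 = r2 + (r2 >= lo)
    r2 = r2 + (r2 >= hi)
    return r1, r2


def _tn_logpdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Positive-truncated normal log density; -inf where x <= 0.

    Assumes sigma > 0 (callers mask invalid sigma rows themselves).
    """
    z = (x - mu) / sigma
    logp = (-0.5 * z * z - _LOG_SQRT_2PI - np.log(sigma)
            - _log_ndtr(mu / sigma))
    return np.where(x > 0, logp, -np.inf)


def _log_ndtr(z):
    from scipy.special import log_ndtr
    return log_ndtr(z)


@dataclass
class PosteriorDraws:
    """Retained posterior draws, indexed (chain, iteration, parameter).

    Parameter names follow ``"<param>|<subject_id>"`` for subject-level
    entries and ``"mu_<param>|<group>"`` / ``"sigma_<param>|<group>"``
    for hyper-level entries.
    """

    values: np.ndarray  # (n_chains, n_samples, n_params)
    names: list[str]
    subject_ids: list[str]
    group_of: dict[str, str]
    groups: list[str]
    accept_rates: dict[str, float]
    config: SamplerConfig

    def __post_init__(self) -> None:
        self._index = {n: j for j, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_samples)."""
        try:
            return self.values[:, :, self._index[name]]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def hyper_draws(self, group: str, parameter: str) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (mu, sigma) draws of one group x parameter hyper pair."""
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        if parameter not in PARAM_NAMES:
            raise KeyError(f"unknown parameter {parameter!r}")
        mu = self.get(f"mu_{parameter}|{group}").ravel()
        sigma = self.get(f"sigma_{parameter}|{group}").ravel()
        return mu, sigma

    def subject_matrix(self, parameter: str) -> np.ndarray:
        """Draws of one subject-level parameter, shape (chain, iter, subject)."""
        cols = [self._index[f"{parameter}|{sid}"] for sid in self.subject_ids]
        return self.values[:, :, cols]

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per (chain, iteration), one column per parameter."""
        C, N, P = self.values.shape
        df = pd.DataFrame(self.values.reshape(C * N, P), columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(C), N))
        df.insert(1, "iteration", np.tile(np.arange(N), C))
        return df

    def save(self, path) -> None:
        """Persist as a compressed columnar (parquet) table."""
        self.to_frame().to_parquet(path)

    def rhat(self, names: Sequence[str] | None = None) -> pd.Series:
        """Rank-normalised split R-hat per parameter (via arviz)."""
        return self._diag("rhat", names)

    def ess(self, names: Sequence[str] | None = None) -> pd.Series:
        """Bulk effective sample size per parameter (via arviz)."""
        return self._diag("ess", names)

    def _diag(self, which: str, names: Sequence[str] | None) -> pd.Series:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import arviz as az
        names = list(names) if names is not None else list(self.names)
        cols = [self._index[n] for n in names]
        data = {f"p{j}": self.values[:, :, c] for j, c in enumerate(cols)}
        ds = az.convert_to_dataset(data)
        fn = az.rhat if which == "rhat" else az.ess
        out = fn(ds, method="rank" if which == "rhat" else "bulk")
        return pd.Series([float(out[f"p{j}"].values) for j in range(len(names))],
                         index=names)


def load_draws(path, trials: pd.DataFrame) -> PosteriorDraws:
    """Rebuild a :class:`PosteriorDraws` from a saved parquet table.

    ``trials`` (the trial table the fit consumed) supplies the
    subject-to-group mapping, which the columnar store does not carry.
    """
    df = pd.read_parquet(path)
    C = int(df["chain"].max()) + 1
    names = [c for c in df.columns if c not in ("chain", "iteration")]
    values = df[names].to_numpy().reshape(C, -1, len(names))
    subject_ids = sorted({n.split("|", 1)[1] for n in names
                          if not n.startswith(("mu_", "sigma_"))})
    present = sorted({n.split("|", 1)[1] for n in names
                      if n.startswith("mu_")})
    groups = [g for g in ("MDD", "HCL") if g in present] + \
             [g for g in present if g not in ("MDD", "HCL")]
    group_of = {str(s): str(g) for s, g in
                trials.groupby("subject_id")["group"].first().items()}
    return PosteriorDraws(values=values, names=names,
                          subject_ids=subject_ids, group_of=group_of,
                          groups=groups, accept_rates={},
                          config=SamplerConfig())


# ---------------------------------------------------------------------------
# Generic single-block DE-MCMC (used for analytic-target validation)

def sample_logpdf(logpdf: Callable[[np.ndarray], float], ndim: int,
                  config: SamplerConfig,
                  init: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """DE-MCMC on an arbitrary log density.

    Returns retained draws of shape (n_chains, n_samples, ndim) and
    the mean acceptance rate.  Used to validate the crossover/accept
    machinery against targets with known moments.
    """
    rng = np.random.default_rng(config.seed)
    C = config.n_chains
    g = default_gamma(ndim) if config.gamma is None else config.gamma
    x = (rng.standard_normal((C, ndim)) if init is None
         else np.array(init, dtype=float))
    if x.shape != (C, ndim):
        raise SamplerLogicError(f"init must have shape {(C, ndim)}")
    if np.allclose(x.std(axis=0), 0):
        raise SamplerLogicError("degenerate initialization: zero chain spread")
    lp = np.array([logpdf(row) for row in x], dtype=float)
    if np.isnan(lp).any():
        raise NumericalError("NaN log density at initialization")
    if not np.all(np.isfinite(lp)):
        raise SamplerLogicError("non-finite log density at initialization")
    draws = np.empty((C, config.n_samples, ndim))
    accepted = 0
    total = 0
    for it in range(config.burn_in + config.n_samples):
        r1, r2 = _partners((C,), C, rng)
        prop = x + g * (x[r1] - x[r2]) + rng.uniform(
            -config.jitter_b0, config.jitter_b0, size=(C, ndim))
        lp_prop = np.array([logpdf(row) for row in prop], dtype=float)
        if np.isnan(lp_prop).any():
            raise NumericalError("NaN log density in proposal")
        delta = lp_prop - lp
        acc = np.log(rng.random(C)) < delta
        x[acc] = prop[acc]
        lp[acc] = lp_prop[acc]
        accepted += int(acc.sum())
        total += C
        if it >= config.burn_in:
            draws[:, it - config.burn_in, :] = x
    return draws, accepted / total


# ---------------------------------------------------------------------------
# Hierarchical LBA sampler

class _Problem:
    """Preprocessed trial data and bookkeeping for one fit."""

    def __init__(self, trials: pd.DataFrame):
        if len(trials) == 0:
            raise DataError("no trials to fit")
        gmap = trials.groupby("subject_id")["group"].nunique()
        if (gmap > 1).any():
            bad = list(gmap.index[gmap > 1])
            raise ConsistencyError(f"subjects in multiple groups: {bad}")
        self.subject_ids = sorted(trials["subject_id"].astype(str).unique())
        self.group_of = {
            str(s): str(g) for s, g in
            trials.groupby("subject_id")["group"].first().items()}
        preferred = [g for g in ("MDD", "HCL")
                     if g in set(self.group_of.values())]
        rest = sorted(set(self.group_of.values()) - set(preferred))
        self.groups = preferred + rest
        self.S = len(self.subject_ids)
        self.G = len(self.groups)
        self.g_of_s = np.array(
            [self.groups.index(self.group_of[s]) for s in self.subject_ids])
        self.group_subjects = [np.flatnonzero(self.g_of_s == g)
                               for g in range(self.G)]
        order = {s: j for j, s in enumerate(self.subject_ids)}
        df = trials.assign(_s=trials["subject_id"].astype(str).map(order))
        df = df.sort_values("_s", kind="stable")
        self.rt = df["rt_sec"].to_numpy(dtype=np.float64)
        self.correct = df["correct"].to_numpy(dtype=np.uint8)
        self.face = (df["condition"] == "FACE").to_numpy().astype(np.uint8)
        counts = np.bincount(df["_s"].to_numpy(), minlength=self.S)
        self.offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self.min_rt = np.array(
            [self.rt[self.offsets[s]:self.offsets[s + 1]].min()
             for s in range(self.S)])


def _loglik_all(subj: np.ndarray, prob: _Problem) -> np.ndarray:
    out = np.empty(subj.shape[:2])
    _kernels.loglik_all(subj, prob.rt, prob.correct, prob.face,
                        prob.offsets, out)
    return out


def _heuristic_subject_init(prob: _Problem) -> np.ndarray:
    """Moment-based start values per subject.

    ``t0`` starts below the subject's fastest response.  The evidence
    scale is read off the decision-time coefficient of variation: with
    drift noise fixed at s = 1 and winning drift v, decision time
    T ~ (b - U) / v has CV^2 ~ (s/v)^2 + (A^2/12) / (b - A/2)^2, so
    (b - A/2) ~ s * mean(T) / sqrt(CV^2 - const) once A/b is pinned at
    a typical 0.4.  The correct drift then follows from the mean
    decision time and the error drift from the accuracy through the
    approximate race probability Phi((v_c - v_e) / sqrt(2)).  Only
    used to seat the chains in a plausible region; the target is
    untouched.
    """
    from scipy.special import ndtri

    init = np.empty((prob.S, 7))
    for s in range(prob.S):
        lo, hi = prob.offsets[s], prob.offsets[s + 1]
        rt = prob.rt[lo:hi]
        correct = prob.correct[lo:hi].astype(bool)
        face = prob.face[lo:hi].astype(bool)
        t0 = 0.5 * rt.min()
        dt_all = rt - t0
        # trim the slow tail so near-zero winning drifts do not blow
        # up the moment estimates
        dt_trim = np.minimum(dt_all, 5.0 * np.median(dt_all))
        mean_dt = float(dt_trim.mean())
        cv2 = float(dt_trim.std() / max(mean_dt, 1e-6)) ** 2
        # A/b = 0.4 contributes ~0.021 to CV^2
        b_bar = mean_dt / math.sqrt(max(cv2 - 0.021, 0.04))
        b_bar = min(max(b_bar, 0.5), 8.0)
        b = b_bar / 0.8
        A, k = 0.4 * b, 0.6 * b
        row = [A, k, t0]
        for m in (face, ~face):
            mc = m & correct
            mdt = dt_trim[mc] if mc.any() else dt_trim
            acc = float(correct[m].mean()) if m.any() else 0.75
            acc = min(max(acc, 0.55), 0.98)
            v_c = b_bar / max(float(np.median(mdt)), 0.05)
            v_e = max(v_c - math.sqrt(2.0) * float(ndtri(acc)), 0.05)
            row += [v_c, v_e]
        init[s] = row
    return init


def _initial_state(prob: _Problem, priors: HyperPriorConfig,
                   config: SamplerConfig, rng: np.random.Generator):
    """Overdispersed, ridge-aligned start.

    Hyperprior-draw initialization is prone to stranding whole chains
    in the small-sigma funnel (subjects pinned at a bad value that the
    shrunken hyperdistribution then refuses to release), so chains
    start instead from data-informed heuristic subject values.  The
    threshold scale and the drift rates trade off along a likelihood
    ridge (a larger b with faster drifts predicts nearly the same
    behavior), so each chain gets its own geometry scale with drifts
    derived consistently; the resulting chain spread lies along the
    ridge and DE crossover proposals inherit that direction.  Up to
    100 rejitters per chain to reach a finite posterior.
    """
    C, S, G = config.n_chains, prob.S, prob.G
    subj = np.empty((C, S, 7))
    hyp_mu = np.empty((C, G, 7))
    hyp_sigma = np.empty((C, G, 7))
    t0_col = PARAM_NAMES.index("t0")
    base = _heuristic_subject_init(prob)
    for c in range(C):
        for attempt in range(_INIT_RETRIES):
            scale = math.exp(0.2 * rng.standard_normal())
            jit = np.exp(0.1 * rng.standard_normal((S, 7)))
            subj[c] = base * jit
            subj[c][:, _EVID_COLS] *= scale
            subj[c, :, t0_col] = np.minimum(subj[c, :, t0_col],
                                            0.9 * prob.min_rt)
            for g in range(G):
                vals = subj[c, prob.group_subjects[g]]
                hyp_mu[c, g] = vals.mean(axis=0) * np.exp(
                    0.1 * rng.standard_normal(7))
                hyp_sigma[c, g] = np.maximum(vals.std(axis=0), 0.05) * np.exp(
                    0.1 * rng.standard_normal(7))
            ll = _loglik_all(subj[c:c + 1], prob)
            if np.all(np.isfinite(ll)):
                break
        else:
            raise SamplerLogicError(
                f"chain {c}: no finite posterior after {_INIT_RETRIES} "
                "initialization attempts")
    return subj, hyp_mu, hyp_sigma


def run_sampler(trials: pd.DataFrame, priors: HyperPriorConfig,
                config: SamplerConfig) -> PosteriorDraws:
    """Fit the two-group hierarchical LBA by blocked DE-MCMC.

    ``trials`` is a trial table (columns as in
    :data:`facelba.lba_core.TRIAL_COLUMNS`); every subject present is
    fitted.  Fully reproducible from ``config.seed``.
    """
    prob = _Problem(trials)
    rng = np.random.default_rng(config.seed)
    C, S, G = config.n_chains, prob.S, prob.G
    g_subj = (default_gamma(7) if config.gamma is None else config.gamma)
    g_hyp = (default_gamma(14) if config.gamma is None else config.gamma)
    b0 = config.jitter_b0

    subj, hyp_mu, hyp_sigma = _initial_state(prob, priors, config, rng)

    mu_loc, mu_scale, s_loc, s_scale = priors.arrays()

    def subject_prior(subj_arr, mu_arr, sigma_arr):
        # (C, S, 7) against per-subject group hypers -> (C, S)
        mu = mu_arr[:, prob.g_of_s, :]
        sig = sigma_arr[:, prob.g_of_s, :]
        return _tn_logpdf(subj_arr, mu, sig).sum(axis=2)

    def hyperprior(mu_arr, sigma_arr):
        # (C, G, 7) pairs -> (C, G); rows with sigma <= 0 are -inf
        ok = np.all(sigma_arr > 0, axis=2)
        safe = np.where(sigma_arr > 0, sigma_arr, 1.0)
        lp = (_tn_logpdf(mu_arr, mu_loc, mu_scale)
              + _tn_logpdf(sigma_arr, s_loc, s_scale)).sum(axis=2)
        return np.where(ok, lp, -np.inf), ok, safe

    ll = _loglik_all(subj, prob)                    # (C, S)
    pp = subject_prior(subj, hyp_mu, hyp_sigma)     # (C, S)
    hp, _, _ = hyperprior(hyp_mu, hyp_sigma)        # (C, G)

    P = S * 7 + G * 14
    draws = np.empty((C, config.n_samples, P))
    acc_subj = 0
    acc_hyp = 0
    acc_rescale = 0
    n_subj_props = 0
    n_hyp_props = 0
    n_rescale_props = 0
    ll_buf = np.empty((C, S))

    for it in range(config.burn_in + config.n_samples):
        # --- subject blocks (conditionally independent given hypers) ---
        # gamma is rescaled by U(0.5, 1) per update, a standard guard
        # against the interacting chains collapsing onto one point
        r1, r2 = _partners((C, S), C, rng)
        sidx = np.arange(S)
        gs = g_subj * rng.uniform(0.5, 1.0)
        prop = (subj
                + gs * (subj[r1, sidx[None, :], :]
                        - subj[r2, sidx[None, :], :])
                + rng.uniform(-b0, b0, size=(C, S, 7)))
        pp_prop = subject_prior(prop, hyp_mu, hyp_sigma)
        _kernels.loglik_all(prop, prob.rt, prob.correct, prob.face,
                            prob.offsets, ll_buf)
        with np.errstate(invalid="ignore"):
            delta = (ll_buf + pp_prop) - (ll + pp)
        if np.isnan(delta).any():
            raise NumericalError("NaN log posterior in subject block update")
        acc = np.log(rng.random((C, S))) < delta
        subj[acc] = prop[acc]
        ll[acc] = ll_buf[acc]
        pp[acc] = pp_prop[acc]
        acc_subj += int(acc.sum())
        n_subj_props += C * S

        # --- hyper blocks, one per group ---
        for g in range(G):
            idx = prob.group_subjects[g]
            block = np.concatenate([hyp_mu[:, g, :], hyp_sigma[:, g, :]],
                                   axis=1)  # (C, 14)
            r1h, r2h = _partners((C,), C, rng)
            gh = g_hyp * rng.uniform(0.5, 1.0)
            bprop = (block + gh * (block[r1h] - block[r2h])
                     + rng.uniform(-b0, b0, size=(C, 14)))
            pm = bprop[:, :7][:, None, :]          # (C, 1, 7)
            ps = bprop[:, 7:][:, None, :]
            hp_prop, ok, safe = hyperprior(pm[:, 0][:, None, :],
                                           ps[:, 0][:, None, :])
            hp_prop = hp_prop[:, 0]
            ps_safe = np.where(ps > 0, ps, 1.0)
            pp_prop_g = _tn_logpdf(subj[:, idx, :], pm, ps_safe).sum(axis=2)
            with np.errstate(invalid="ignore"):
                delta = ((hp_prop + pp_prop_g.sum(axis=1))
                         - (hp[:, g] + pp[:, idx].sum(axis=1)))
            if np.isnan(delta).any():
                raise NumericalError("NaN log posterior in hyper block update")
            accg = np.log(rng.random(C)) < delta
            hyp_mu[accg, g, :] = bprop[accg, :7]
            hyp_sigma[accg, g, :] = bprop[accg, 7:]
            hp[accg, g] = hp_prop[accg]
            pp[np.ix_(accg, idx)] = pp_prop_g[accg]
            acc_hyp += int(accg.sum())
            n_hyp_props += C

        # --- group evidence-scale move ---
        # The threshold geometry and all drift means trade off along a
        # multiplicative likelihood ridge (with s fixed at 1, a larger
        # b with proportionally faster drifts predicts similar
        # behavior), which plain crossover traverses very slowly.  A
        # joint multiplicative rescale of one group's evidence-unit
        # quantities -- every subject's A, k and drifts plus the
        # group's mu and sigma hypers for them -- walks the ridge
        # directly.  The move is a multiplicative random walk, so the
        # Metropolis ratio carries the n * log(lambda) Jacobian term.
        if config.rescale_every and it % config.rescale_every == 0:
            for g in range(G):
                idx = prob.group_subjects[g]
                z = rng.normal(0.0, config.rescale_step, size=C)
                lam = np.exp(z)
                prop_s = subj[:, idx, :].copy()
                prop_s[:, :, _EVID_COLS] *= lam[:, None, None]
                prop_mu = hyp_mu[:, g, :].copy()
                prop_sig = hyp_sigma[:, g, :].copy()
                prop_mu[:, _EVID_COLS] *= lam[:, None]
                prop_sig[:, _EVID_COLS] *= lam[:, None]
                ll_prop = np.empty((C, len(idx)))
                _kernels.loglik_subset(
                    np.ascontiguousarray(prop_s), prob.rt, prob.correct,
                    prob.face, prob.offsets[idx], prob.offsets[idx + 1],
                    ll_prop)
                pp_prop_g = _tn_logpdf(prop_s, prop_mu[:, None, :],
                                       prop_sig[:, None, :]).sum(axis=2)
                hp_prop, _, _ = hyperprior(prop_mu[:, None, :],
                                           prop_sig[:, None, :])
                hp_prop = hp_prop[:, 0]
                n_scaled = len(_EVID_COLS) * (len(idx) + 2)
                with np.errstate(invalid="ignore"):
                    delta = (ll_prop.sum(axis=1) + pp_prop_g.sum(axis=1)
                             + hp_prop + n_scaled * z
                             - (ll[:, idx].sum(axis=1)
                                + pp[:, idx].sum(axis=1) + hp[:, g]))
                if np.isnan(delta).any():
                    raise NumericalError("NaN log posterior in rescale move")
                accr = np.log(rng.random(C)) < delta
                if accr.any():
                    subj[np.ix_(accr, idx)] = prop_s[accr]
                    hyp_mu[accr, g, :] = prop_mu[accr]
                    hyp_sigma[accr, g, :] = prop_sig[accr]
                    ll[np.ix_(accr, idx)] = ll_prop[accr]
                    pp[np.ix_(accr, idx)] = pp_prop_g[accr]
                    hp[accr, g] = hp_prop[accr]
                acc_rescale += int(accr.sum())
                n_rescale_props += C

        # --- migration among a random chain subset (burn-in only) ---
        if it < config.burn_in and rng.random() < config.migration_prob:
            k = int(rng.integers(2, C + 1))
            sel = rng.permutation(C)[:k]
            logpost = ll.sum(axis=1) + pp.sum(axis=1) + hp.sum(axis=1)
            snap = (subj[sel].copy(), hyp_mu[sel].copy(),
                    hyp_sigma[sel].copy(), ll[sel].copy(), pp[sel].copy(),
                    hp[sel].copy(), logpost[sel].copy())
            for j in range(k):
                donor = j - 1  # cyclic: chain sel[j] may adopt sel[j-1]'s state
                tgt = sel[j]
                if metropolis_accept(logpost[tgt], snap[6][donor], rng):
                    subj[tgt] = snap[0][donor]
                    hyp_mu[tgt] = snap[1][donor]
                    hyp_sigma[tgt] = snap[2][donor]
                    ll[tgt] = snap[3][donor]
                    pp[tgt] = snap[4][donor]
                    hp[tgt] = snap[5][donor]

        if it >= config.burn_in:
            j = it - config.burn_in
            draws[:, j, :S * 7] = subj.reshape(C, -1)
            hy = np.concatenate([hyp_mu, hyp_sigma], axis=2)  # (C, G, 14)
            draws[:, j, S * 7:] = hy.reshape(C, -1)

    names = [f"{p}|{sid}" for sid in prob.subject_ids for p in PARAM_NAMES]
    for g in prob.groups:
        names += [f"mu_{p}|{g}" for p in PARAM_NAMES]
        names += [f"sigma_{p}|{g}" for p in PARAM_NAMES]
    return PosteriorDraws(
        values=draws,
        names=names,
        subject_ids=prob.subject_ids,
        group_of=prob.group_of,
        groups=prob.groups,
        accept_rates={
            "subject_blocks": acc_subj / max(n_subj_props, 1),
            "hyper_blocks": acc_hyp / max(n_hyp_props, 1),
            "rescale_moves": acc_rescale / max(n_rescale_props, 1),
        },
        config=config,
    )
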