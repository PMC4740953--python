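"""Two-group hierarchical layer over the LBA.

Each subject's seven parameters (A, k, t0 and the four condition
drifts) are exchangeable draws from positive-truncated normal
hyperdistributions, parameterised by a mean ``mu`` and SD ``sigma``
per parameter and estimated separately per group (MDD, HCL).  The
groups share no hyperparameters; fitting them in one joint state is a
code convenience, not statistical pooling.

Hyperpriors are weakly informative on the scale fixed by the drift SD
``s = 1``: positive-truncated Normal(1, 3) on each ``mu`` (Normal(0.3,
0.3) for ``t0``, whose natural scale is a few hundred milliseconds)
and positive-truncated Normal(0, 1) — a half-normal — on each
``sigma``.  All of them are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from . import lba_core
from .errors import ConsistencyError, ParameterDomainError
from .lba_core import PARAM_NAMES, SubjectParams

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def truncnorm_logpdf(x, mu, sigma):
    """Log density of a Normal(mu, sigma) truncated to ``(0, inf)``.

    ``phi((x - mu)/sigma) / (sigma * Phi(mu/sigma))`` for ``x > 0``,
    zero otherwise.  Vectorised over any broadcastable combination of
    arguments.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ParameterDomainError("sigma must be > 0")
    z = (x - mu) / sigma
    logp = -0.5 * z * z - _LOG_SQRT_2PI - np.log(sigma) - log_ndtr(mu / sigma)
    out = np.where(x > 0, logp, -np.inf)
    return float(out) if out.ndim == 0 else out


def truncnorm_rvs(mu, sigma, size, rng: np.random.Generator) -> np.ndarray:
    """Draw from a positive-truncated Normal(mu, sigma) by rejection.

    The acceptance rate is ``Phi(mu / sigma)``; for the hyperprior and
    hyperdistribution regimes used here that is never small enough to
    need the specialised tail algorithms.
    """
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size).copy()
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ParameterDomainError("sigma must be > 0")
    out = rng.normal(mu, sigma, size=size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mu[bad], np.broadcast_to(sigma, size)[bad])
        bad = out <= 0
    return out


@dataclass(frozen=True)
class GroupHypers:
    """Per-group (mu, sigma) of the positive-truncated normal hyperdistributions."""

    group: str
    mu: Mapping[str, float]
    sigma: Mapping[str, float]

    def __post_init__(self) -> None:
        for p in PARAM_NAMES:
            if p not in self.mu or p not in self.sigma:
                raise ParameterDomainError(f"missing hyper for parameter {p!r}")
            if not self.sigma[p] > 0:
                raise ParameterDomainError(f"sigma[{p!r}] must be > 0")

    def mu_array(self) -> np.ndarray:
        return np.array([self.mu[p] for p in PARAM_NAMES], dtype=float)

    def sigma_array(self) -> np.ndarray:
        return np.array([self.sigma[p] for p in PARAM_NAMES], dtype=float)

    @classmethod
    def from_arrays(cls, group: str, mu: np.ndarray, sigma: np.ndarray) -> "GroupHypers":
        return cls(group, dict(zip(PARAM_NAMES, map(float, mu))),
                   dict(zip(PARAM_NAMES, map(float, sigma))))


@dataclass(frozen=True)
class HyperPriorConfig:
    """Priors on every (mu_p, sigma_p): positive-truncated normals.

    ``mu_loc/mu_scale`` give, per subject-level parameter, the location
    and scale of the truncated-normal prior on the hyper mean;
    ``sigma_loc/sigma_scale`` likewise for the hyper SD.
    """

    mu_loc: Mapping[str, float] = field(default_factory=dict)
    mu_scale: Mapping[str, float] = field(default_factory=dict)
    sigma_loc: Mapping[str, float] = field(default_factory=dict)
    sigma_scale: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "HyperPriorConfig":
        mu_loc = {p: 1.0 for p in PARAM_NAMES}
        mu_scale = {p: 3.0 for p in PARAM_NAMES}
        mu_loc["t0"] = 0.3
        mu_scale["t0"] = 0.3
        return cls(
            mu_loc=mu_loc,
            mu_scale=mu_scale,
            sigma_loc={p: 0.0 for p in PARAM_NAMES},
            sigma_scale={p: 1.0 for p in PARAM_NAMES},
        )

    def __post_init__(self) -> None:
        for table in (self.mu_loc, self.mu_scale, self.sigma_loc, self.sigma_scale):
            for p in PARAM_NAMES:
                if p not in table:
                    raise ParameterDomainError(f"hyperprior missing entry for {p!r}")
        for p in PARAM_NAMES:
            if self.mu_scale[p] <= 0 or self.sigma_scale[p] <= 0:
                raise ParameterDomainError(f"hyperprior scales must be > 0 ({p!r})")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        get = lambda m: np.array([m[p] for p in PARAM_NAMES], dtype=float)
        return get(self.mu_loc), get(self.mu_scale), get(self.sigma_loc), get(self.sigma_scale)

    def log_density(self, hypers: GroupHypers) -> float:
        """Log hyperprior density of one group's (mu, sigma) vectors."""
        mu_loc, mu_scale, s_loc, s_scale = self.arrays()
        lp = truncnorm_logpdf(hypers.mu_array(), mu_loc, mu_scale)
        lp = lp + truncnorm_logpdf(hypers.sigma_array(), s_loc, s_scale)
        return float(np.sum(lp))

    def sample_hypers(self, group: str, rng: np.random.Generator) -> GroupHypers:
        mu_loc, mu_scale, s_loc, s_scale = self.arrays()
        mu = truncnorm_rvs(mu_loc, mu_scale, (len(PARAM_NAMES),), rng)
        sigma = truncnorm_rvs(s_loc, s_scale, (len(PARAM_NAMES),), rng)
        return GroupHypers.from_arrays(group, mu, sigma)


@dataclass
class ParameterState:
    """One full configuration of the joint model.

    ``subject_params`` maps subject id -> :class:`SubjectParams`;
    ``group_of`` maps subject id -> group label; ``hypers`` maps group
    label -> :class:`GroupHypers`.
    """

    subject_params: dict[str, SubjectParams]
    group_of: dict[str, str]
    hypers: dict[str, GroupHypers]

    def subject_prior_logdensity(self, subject_id: str) -> float:
        """Sum of the 7 truncated-normal terms tying a subject to its group."""
        g = self.hypers[self.group_of[subject_id]]
        vals = self.subject_params[subject_id].as_array()
        return float(np.sum(truncnorm_logpdf(vals, g.mu_array(), g.sigma_array())))

    def to_frame(self) -> pd.DataFrame:
        """Serialise as (level, group, subject_id, parameter, value) rows."""
        rows = []
        for sid, params in self.subject_params.items():
            g = self.group_of[sid]
            for p, v in zip(PARAM_NAMES, params.as_array()):
                rows.append(("subject", g, sid, p, v))
        for g, h in self.hypers.items():
            for p in PARAM_NAMES:
                rows.append(("hyper_mu", g, "", p, h.mu[p]))
                rows.append(("hyper_sigma", g, "", p, h.sigma[p]))
        return pd.DataFrame(rows, columns=["level", "group", "subject_id",
                                           "parameter", "value"])


def joint_log_posterior(state: ParameterState, trials: pd.DataFrame,
                        priors: HyperPriorConfig) -> float:
    """Unnormalised log posterior of a full parameter state.

    Sum of (i) the LBA log likelihood of every trial under its
    subject's parameters, (ii) the truncated-normal log densities of
    every subject parameter under its group's hypers, and (iii) the
    hyperprior log densities.  ``-inf`` from any component propagates.

    ``trials`` may be empty (the joint then reduces to the hierarchical
    prior), but every subject that does appear must have a parameter
    state.
    """
    total = 0.0
    if len(trials) > 0:
        for sid, sub in trials.groupby("subject_id", sort=False):
            sid = str(sid)
            if sid not in state.subject_params:
                raise ConsistencyError(f"no parameter state for subject {sid!r}")
            total += lba_core.trials_loglik(
                sub["rt_sec"].to_numpy(dtype=float),
                sub["correct"].to_numpy(dtype=bool),
                (sub["condition"] == "FACE").to_numpy(),
                state.subject_params[sid],
            )
            if total == -np.inf:
                return -np.inf
    for sid in state.subject_params:
        total += state.subject_prior_logdensity(sid)
        if total == -np.inf:
            return -np.inf
    for h in state.hypers.values():
        total += priors.log_density(h)
        if total == -np.inf:
            return -np.inf
    return float(total)
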