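"""Linear ballistic accumulator (LBA) race model.

Two accumulators race linearly from a uniform start point on ``[0, A]``
toward a threshold ``b = A + k``; the trial-to-trial drift of each
accumulator is normal with mean ``v`` and standard deviation ``s``
(fixed at 1 to set the evidence scale).  There is no within-trial
noise — the paths are ballistic — so the first-passage time of one
accumulator is ``(b - start) / drift`` for positive drift, and the
observed response time adds a non-decision offset ``t0``.

This module provides the single-accumulator first-passage CDF/PDF in
closed form, the defective two-choice trial likelihood (the density of
responding *i* at time *t*, which integrates to the probability of
choice *i*, not to 1), and a forward simulator whose output
distribution matches that likelihood.

Conventions
-----------
* Response times are in seconds, measured from stimulus (morph) onset.
* The drift mean of the accumulator matching the correct response is
  ``v_c`` ("perceptual processing efficiency"), the error accumulator's
  is ``v_e``; both differ between FACE and OVAL trials while ``A``,
  ``k`` and ``t0`` are shared.
* When *both* sampled drifts are negative no accumulator ever
  finishes; the simulator redraws drifts in that event (the task
  forces a response), and the trial likelihood correspondingly
  conditions on a response occurring by dividing the defective density
  by ``1 - Phi(-v_c)Phi(-v_e)``.  Fitting the unconditioned defective
  form to forced-response data biases drift rates upward; pass
  ``condition_on_response=False`` to get the raw defective likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import DataError, ParameterDomainError

GROUPS = ("MDD", "HCL")
CONDITIONS = ("FACE", "OVAL")
EMOTIONS = ("FEAR", "HAPPY", "SAD")
#: OVAL trials carry no emotion; the table sentinel is the string "NA".
NO_EMOTION = "NA"

#: Subject-level parameter names, in canonical vector order.
PARAM_NAMES = ("A", "k", "t0", "v_c_face", "v_e_face", "v_c_oval", "v_e_oval")
N_PARAMS = len(PARAM_NAMES)

#: Below this start-point range the uniform-start closed form is
#: numerically unstable and the A -> 0 limiting density is used instead.
SMALL_A = 1e-6

_LOG_FLOOR = 1e-300
_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _npdf(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * np.square(z)) / _SQRT_2PI


@dataclass(frozen=True)
class SubjectParams:
    """One subject's LBA parameter vector.

    ``A`` is the start-point range, ``k = b - A > 0`` the threshold
    offset (so the threshold ``b = A + k`` always exceeds the largest
    possible start point), ``t0`` the non-decision time in seconds, and
    the four ``v_*`` fields the mean drift rates (evidence units per
    second) of the correct/error accumulators in the FACE and OVAL
    conditions.  ``s`` is the between-trial drift SD, fixed at 1.
    """

    A: float
    k: float
    t0: float
    v_c_face: float
    v_e_face: float
    v_c_oval: float
    v_e_oval: float
    s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.k > 0 and self.t0 > 0 and self.s > 0):
            raise ParameterDomainError(
                f"require A, k, t0, s > 0; got A={self.A}, k={self.k}, "
                f"t0={self.t0}, s={self.s}"
            )
        for name in ("v_c_face", "v_e_face", "v_c_oval", "v_e_oval"):
            if not math.isfinite(getattr(self, name)):
                raise ParameterDomainError(f"drift mean {name} must be finite")

    @property
    def b(self) -> float:
        """Response threshold ``A + k``."""
        return self.A + self.k

    def drifts(self, condition: str, correct: bool) -> tuple[float, float]:
        """(winner, loser) drift means for the observed outcome of a trial."""
        if condition == "FACE":
            v_c, v_e = self.v_c_face, self.v_e_face
        elif condition == "OVAL":
            v_c, v_e = self.v_c_oval, self.v_e_oval
        else:
            raise DataError(f"unknown condition {condition!r}")
        return (v_c, v_e) if correct else (v_e, v_c)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray, s: float = 1.0) -> "SubjectParams":
        return cls(*(float(v) for v in values), s=s)

    def replace(self, **kwargs) -> "SubjectParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial of the emotion-identification task."""

    subject_id: str
    group: str
    condition: str
    emotion: str
    correct: bool
    rt: float
    valid: bool = True

    def __post_init__(self) -> None:
        if not self.rt > 0:
            raise DataError(f"rt must be positive, got {self.rt}")
        if (self.emotion == NO_EMOTION) != (self.condition == "OVAL"):
            raise DataError(
                f"emotion must be {NO_EMOTION!r} iff condition is OVAL "
                f"(got emotion={self.emotion!r}, condition={self.condition!r})"
            )


def _check_acc_params(A: float, b: float, s: float) -> None:
    if not (A > 0 and s > 0 and b >= A):
        raise ParameterDomainError(
            f"require A > 0, s > 0, b >= A; got A={A}, b={b}, s={s}"
        )


def accumulator_cdf(t, A: float, b: float, v: float, s: float = 1.0):
    """First-passage CDF of a single LBA accumulator.

    Probability that an accumulator with start ~ Uniform[0, A] and
    drift ~ Normal(v, s) has crossed threshold ``b`` by decision time
    ``t`` (seconds, excluding non-decision time).  The limit as
    ``t -> inf`` is ``Phi(v / s)``: trials whose sampled drift is
    negative never cross.

    Accepts scalar or array ``t``; returns the same shape.
    """
    _check_acc_params(A, b, s)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise DataError("decision time t must be >= 0")
    out = np.zeros_like(t)
    pos = t > 0
    if np.any(pos):
        tp = t[pos]
        if A < SMALL_A:
            # A -> 0 limit: crossing by t iff drift >= b / t.
            out[pos] = ndtr((v - b / tp) / s)
        else:
            ts = tp * s
            z1 = (b - A - tp * v) / ts
            z2 = (b - tp * v) / ts
            out[pos] = (
                1.0
                + ((b - A - tp * v) / A) * ndtr(z1)
                - ((b - tp * v) / A) * ndtr(z2)
                + (ts / A) * (_npdf(z1) - _npdf(z2))
            )
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def accumulator_pdf(t, A: float, b: float, v: float, s: float = 1.0):
    """First-passage density (per second) of a single LBA accumulator.

    Integrates over ``(0, inf)`` to ``Phi(v / s)`` — the density is
    defective because negative sampled drifts never reach threshold.
    """
    _check_acc_params(A, b, s)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise DataError("decision time t must be >= 0")
    out = np.zeros_like(t)
    pos = t > 0
    if np.any(pos):
        tp = t[pos]
        if A < SMALL_A:
            z = (b / tp - v) / s
            out[pos] = (b / (s * np.square(tp))) * _npdf(z)
        else:
            ts = tp * s
            z1 = (b - A - tp * v) / ts
            z2 = (b - tp * v) / ts
            out[pos] = (
                -v * ndtr(z1) + s * _npdf(z1) + v * ndtr(z2) - s * _npdf(z2)
            ) / A
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out


def defective_logpdf(dt, v_win: float, v_lose: float, A: float, b: float,
                     s: float = 1.0):
    """Log defective density of the observed response at decision time ``dt``.

    ``f_win(dt) * (1 - F_lose(dt))``: the winning accumulator crosses at
    ``dt`` while the other has not yet crossed.  ``dt <= 0`` maps to
    ``-inf``.  Vectorised over ``dt``.
    """
    dt = np.atleast_1d(np.asarray(dt, dtype=float))
    f = accumulator_pdf(np.maximum(dt, 0.0), A, b, v_win, s)
    F = accumulator_cdf(np.maximum(dt, 0.0), A, b, v_lose, s)
    dens = np.atleast_1d(f * (1.0 - F))
    # Floor the density before the log so deep-underflow regions stay
    # finite and comparable; -inf is reserved for impossible responses.
    out = np.log(np.maximum(dens, _LOG_FLOOR))
    out[dt <= 0] = -np.inf
    return out


def response_log_norm(v_c: float, v_e: float, s: float = 1.0) -> float:
    """log P(some accumulator ever finishes) = log(1 - Phi(-v_c/s) Phi(-v_e/s))."""
    c = ndtr(-v_c / s) * ndtr(-v_e / s)
    return float(np.log(max(1.0 - c, _LOG_FLOOR)))


def trial_loglik(trial: TrialRecord, params: SubjectParams,
                 condition_on_response: bool = True) -> float:
    """Log likelihood of one trial's (choice, RT) under the LBA.

    The observed choice picks which accumulator won: correct responses
    use the condition's ``v_c`` for the winner and ``v_e`` for the
    loser, errors the reverse.  Responses at or before ``t0`` have zero
    density (``-inf`` log likelihood).

    By default the defective density is conditioned on a response
    occurring at all (divided by ``1 - Phi(-v_c)Phi(-v_e)``), because
    the task forces a response on every recorded trial; fitting the
    unconditioned defective form to forced-response data biases the
    drift rates upward by a surprisingly practical amount.  Set
    ``condition_on_response=False`` for the raw defective density.
    """
    v_win, v_lose = params.drifts(trial.condition, trial.correct)
    dt = trial.rt - params.t0
    ll = float(
        defective_logpdf(dt, v_win, v_lose, params.A, params.b, params.s)[0]
    )
    if condition_on_response and np.isfinite(ll):
        v_c, v_e = params.drifts(trial.condition, True)
        ll -= response_log_norm(v_c, v_e, params.s)
    return ll


def trials_loglik(rts: np.ndarray, correct: np.ndarray, is_face: np.ndarray,
                  params: SubjectParams,
                  condition_on_response: bool = True) -> float:
    """Summed log likelihood over a subject's trials (numpy reference path).

    Parameters are arrays of equal length: RT in seconds, a boolean
    correctness flag, and a boolean FACE-condition flag.  See
    :func:`trial_loglik` for the response-conditioning convention.
    """
    rts = np.asarray(rts, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    is_face = np.asarray(is_face, dtype=bool)
    dt = rts - params.t0
    total = 0.0
    for face, v_c, v_e in ((True, params.v_c_face, params.v_e_face),
                           (False, params.v_c_oval, params.v_e_oval)):
        norm = (response_log_norm(v_c, v_e, params.s)
                if condition_on_response else 0.0)
        for corr, v_win, v_lose in ((True, v_c, v_e), (False, v_e, v_c)):
            m = (is_face == face) & (correct == corr)
            if not np.any(m):
                continue
            ll = defective_logpdf(dt[m], v_win, v_lose, params.A, params.b,
                                  params.s)
            total += float(np.sum(ll)) - norm * int(np.sum(m))
            if not np.isfinite(total):
                return -np.inf
    return total


def simulate_trials(params: SubjectParams, conditions: Iterable[str],
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (correct, rt) for a sequence of trials.

    Starts are Uniform[0, A], drifts Normal(v, s) per accumulator; the
    finishing time of an accumulator is ``(b - start) / drift`` for
    positive drift.  If both sampled drifts are non-positive the drifts
    are redrawn (the task forces a response), which is the simulator's
    deliberate departure from the defective likelihood.

    Returns ``(correct, rt)`` arrays; ``rt > t0`` always.
    """
    conditions = list(conditions)
    n = len(conditions)
    face = np.array([c == "FACE" for c in conditions], dtype=bool)
    if not np.all(face | np.array([c == "OVAL" for c in conditions])):
        raise DataError("conditions must be FACE or OVAL")
    v_c = np.where(face, params.v_c_face, params.v_c_oval)
    v_e = np.where(face, params.v_e_face, params.v_e_oval)
    b = params.b

    starts = rng.uniform(0.0, params.A, size=(2, n))
    drifts = np.stack([rng.normal(v_c, params.s), rng.normal(v_e, params.s)])
    # Redraw both drifts wherever neither accumulator would ever finish.
    stuck = np.all(drifts <= 0, axis=0)
    while np.any(stuck):
        idx = np.flatnonzero(stuck)
        drifts[0, idx] = rng.normal(v_c[idx], params.s)
        drifts[1, idx] = rng.normal(v_e[idx], params.s)
        stuck[idx] = np.all(drifts[:, idx] <= 0, axis=0)

    with np.errstate(divide="ignore"):
        times = np.where(drifts > 0, (b - starts) / drifts, np.inf)
    winner = np.argmin(times, axis=0)
    rt = params.t0 + times[winner, np.arange(n)]
    correct = winner == 0
    return correct, rt


def simulate_trial(params: SubjectParams, condition: str,
                   rng: np.random.Generator) -> tuple[bool, float]:
    """Simulate a single trial; see :func:`simulate_trials`."""
    c, rt = simulate_trials(params, [condition], rng)
    return bool(c[0]), float(rt[0])


# ---------------------------------------------------------------------------
# Trial-table I/O

TRIAL_COLUMNS = ["subject_id", "group", "condition", "emotion", "correct",
                 "rt_sec", "valid"]


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [(t.subject_id, t.group, t.condition, t.emotion, int(t.correct),
             t.rt, int(t.valid)) for t in trials]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"trial table missing columns: {sorted(missing)}")
    return [
        TrialRecord(str(r.subject_id), str(r.group), str(r.condition),
                    str(r.emotion), bool(int(r.correct)), float(r.rt_sec),
                    bool(int(r.valid)))
        for r in df.itertuples(index=False)
    ]


def read_trials(path) -> pd.DataFrame:
    """Read a trial table (comma- or tab-separated, header row)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"trial table {path} missing columns: {sorted(missing)}")
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)
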