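"""Numba-accelerated LBA likelihood kernels.

The sampler evaluates the defective trial likelihood hundreds of
thousands of times; these kernels compute it for whole (chain x trial)
blocks in compiled code.  ``facelba.lba_core`` remains the readable
reference implementation and the two paths are equality-tested.

If numba is unavailable the module transparently falls back to a
numpy implementation with identical semantics.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)
_LOG_FLOOR = 1e-300
_SMALL_A = 1e-6


@njit(cache=True, inline="always", fastmath=True)
def _phi(z):
    return math.exp(-0.5 * z * z) * _INV_SQRT_2PI


@njit(cache=True, inline="always", fastmath=True)
def _Phi(z):
    return 0.5 * math.erfc(-z / _SQRT2)


@njit(cache=True, inline="always", fastmath=True)
def _phi_Phi(z):
    """(phi(z), Phi(z)) sharing one exponential.

    Phi uses the Zelen-Severo rational approximation (absolute error
    < 7.5e-8), which costs a handful of multiplies on top of the
    normal pdf already needed by the LBA closed form.  The sampler's
    hot loop uses this pair; the erfc-based `_Phi` remains for
    contexts where full double precision matters.
    """
    p = _phi(z)
    az = -z if z < 0.0 else z
    t = 1.0 / (1.0 + 0.2316419 * az)
    poly = t * (0.319381530 + t * (-0.356563782 + t * (1.781477937
               + t * (-1.821255978 + t * 1.330274429))))
    tail = p * poly
    return p, (tail if z < 0.0 else 1.0 - tail)


@njit(cache=True, inline="always")
def _trial_logdens(dt, vw, vl, A, b):
    """log of f_win(dt) * (1 - F_lose(dt)); -inf iff dt <= 0."""
    if dt <= 0.0:
        return -np.inf
    inv_dt = 1.0 / dt
    if A < _SMALL_A:
        ratio = b * inv_dt
        pdf = b * inv_dt * inv_dt * _phi(ratio - vw)
        _, Fl = _phi_Phi(vl - ratio)
        surv = 1.0 - Fl
    else:
        inv_A = 1.0 / A
        z1 = (b - A - dt * vw) * inv_dt
        z2 = (b - dt * vw) * inv_dt
        p1, P1 = _phi_Phi(z1)
        p2, P2 = _phi_Phi(z2)
        pdf = (-vw * P1 + p1 + vw * P2 - p2) * inv_A
        y1 = (b - A - dt * vl) * inv_dt
        y2 = (b - dt * vl) * inv_dt
        q1, Q1 = _phi_Phi(y1)
        q2, Q2 = _phi_Phi(y2)
        F = (1.0
             + (b - A - dt * vl) * inv_A * Q1
             - (b - dt * vl) * inv_A * Q2
             + dt * inv_A * (q1 - q2))
        surv = 1.0 - F
        if pdf < 0.0:
            pdf = 0.0
    if surv < 0.0:
        surv = 0.0
    elif surv > 1.0:
        surv = 1.0
    dens = pdf * surv
    if dens < _LOG_FLOOR:
        dens = _LOG_FLOOR
    return math.log(dens)


@njit(cache=True, inline="always")
def _response_log_norm(vc, ve):
    # log P(some accumulator finishes) = log(1 - Phi(-vc) Phi(-ve));
    # full-precision erfc here, the term is evaluated once per subject
    c = _Phi(-vc) * _Phi(-ve)
    r = 1.0 - c
    if r < _LOG_FLOOR:
        r = _LOG_FLOOR
    return math.log(r)


@njit(cache=True)
def _subject_ll(A, k, t0, vcf, vef, vco, veo, rt, correct, face, lo, hi):
    # Out-of-domain parameter vectors (possible as DE proposals) get
    # zero posterior support rather than NaN arithmetic.
    if A <= 0.0 or k <= 0.0 or t0 <= 0.0:
        return -np.inf
    b = A + k
    norm_f = _response_log_norm(vcf, vef)
    norm_o = _response_log_norm(vco, veo)
    total = 0.0
    for i in range(lo, hi):
        dt = rt[i] - t0
        if face[i]:
            vc, ve = vcf, vef
            norm = norm_f
        else:
            vc, ve = vco, veo
            norm = norm_o
        if correct[i]:
            vw, vl = vc, ve
        else:
            vw, vl = ve, vc
        ll = _trial_logdens(dt, vw, vl, A, b)
        if ll == -np.inf:
            return -np.inf
        total += ll - norm
    return total


@njit(cache=True)
def loglik_block(params, rt, correct, face, lo, hi, out):
    """Per-chain trial log likelihood of one subject.

    params: (n_chains, 7) in canonical order (A, k, t0, v_c_face,
    v_e_face, v_c_oval, v_e_oval); trials are ``rt[lo:hi]`` etc.
    Writes into ``out`` (n_chains,).
    """
    for c in range(params.shape[0]):
        out[c] = _subject_ll(params[c, 0], params[c, 1], params[c, 2],
                             params[c, 3], params[c, 4], params[c, 5],
                             params[c, 6], rt, correct, face, lo, hi)


@njit(cache=True)
def loglik_all(params, rt, correct, face, offsets, out):
    """Trial log likelihood for every (chain, subject).

    params: (n_chains, n_subjects, 7); subject s owns trials
    ``offsets[s]:offsets[s+1]``.  Writes into ``out``
    (n_chains, n_subjects).
    """
    C, S = params.shape[0], params.shape[1]
    for c in range(C):
        for s in range(S):
            out[c, s] = _subject_ll(
                params[c, s, 0], params[c, s, 1], params[c, s, 2],
                params[c, s, 3], params[c, s, 4], params[c, s, 5],
                params[c, s, 6], rt, correct, face,
                offsets[s], offsets[s + 1])


@njit(cache=True)
def loglik_subset(params, rt, correct, face, lo_arr, hi_arr, out):
    """Trial log likelihood for a subset of subjects.

    params: (n_chains, n_subset, 7); subject j of the subset owns
    trials ``lo_arr[j]:hi_arr[j]``.  Writes into ``out``
    (n_chains, n_subset).
    """
    C, S = params.shape[0], params.shape[1]
    for c in range(C):
        for s in range(S):
            out[c, s] = _subject_ll(
                params[c, s, 0], params[c, s, 1], params[c, s, 2],
                params[c, s, 3], params[c, s, 4], params[c, s, 5],
                params[c, s, 6], rt, correct, face, lo_arr[s], hi_arr[s])


if not HAVE_NUMBA:  # pragma: no cover - numpy fallback
    from . import lba_core

    def _subject_ll_py(row, rt, correct, face, lo, hi):
        params = lba_core.SubjectParams.from_array(row)
        return lba_core.trials_loglik(rt[lo:hi], correct[lo:hi].astype(bool),
                                      face[lo:hi].astype(bool), params)

    def loglik_block(params, rt, correct, face, lo, hi, out):  # noqa: F811
        for c in range(params.shape[0]):
            try:
                out[c] = _subject_ll_py(params[c], rt, correct, face, lo, hi)
            except Exception:
                out[c] = -np.inf

    def loglik_all(params, rt, correct, face, offsets, out):  # noqa: F811
        for s in range(params.shape[1]):
            loglik_block(params[:, s, :], rt, correct, face,
                         offsets[s], offsets[s + 1], out[:, s])

    def loglik_subset(params, rt, correct, face, lo_arr, hi_arr, out):  # noqa: F811
        for s in range(params.shape[1]):
            loglik_block(params[:, s, :], rt, correct, face,
                         int(lo_arr[s]), int(hi_arr[s]), out[:, s])
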