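"""Race-model building blocks: first-passage CDF/PDF, defective trial
likelihood, and agreement between the simulator and the likelihood."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate
from scipy.special import ndtr

from facelba import _kernels
from facelba.errors import DataError, ParameterDomainError
from facelba.lba_core import (SubjectParams, TrialRecord, accumulator_cdf,
                              accumulator_pdf, defective_logpdf,
                              frame_to_trials, read_trials, simulate_trial,
                              simulate_trials, trial_loglik, trials_loglik,
                              trials_to_frame, write_trials)


class TestAccumulatorCDF:
    def test_zero_time_has_zero_mass(self):
        assert accumulator_cdf(0.0, A=1.0, b=2.0, v=1.0) == 0.0

    def test_total_mass_is_positive_drift_probability(self):
        # with v = 0 only half the sampled drifts ever reach threshold
        assert accumulator_cdf(1e7, A=1.0, b=2.0, v=0.0) == pytest.approx(0.5, abs=1e-6)
        assert accumulator_cdf(1e7, A=0.5, b=1.0, v=1.5) == pytest.approx(
            ndtr(1.5), abs=1e-6)

    def test_matches_monte_carlo_first_passage(self, rng):
        # direct simulation of start ~ U[0,A], drift ~ N(v,s)
        n = 10**6
        A, b, v, t = 1.0, 2.0, 1.0, 2.0
        start = rng.uniform(0, A, n)
        drift = rng.normal(v, 1.0, n)
        hit = (drift > 0) & ((b - start) / drift <= t)
        p_mc = hit.mean()
        se = np.sqrt(p_mc * (1 - p_mc) / n)
        assert accumulator_cdf(t, A, b, v) == pytest.approx(p_mc, abs=3 * se)

    def test_monotone_in_time(self):
        t = np.linspace(0, 6, 200)
        F = accumulator_cdf(t, A=0.7, b=1.9, v=1.2)
        assert np.all(np.diff(F) >= -1e-12)

    @pytest.mark.parametrize("bad", [dict(A=-1, b=2), dict(A=1, b=0.5),
                                     dict(A=1, b=2, s=0)])
    def test_domain_errors(self, bad):
        kw = dict(A=1.0, b=2.0, v=1.0, s=1.0)
        kw.update(bad)
        with pytest.raises(ParameterDomainError):
            accumulator_cdf(1.0, **kw)


class TestAccumulatorPDF:
    def test_vanishing_time_vanishing_density(self):
        assert accumulator_pdf(1e-12, A=0.5, b=1.0, v=1.0) == pytest.approx(0.0)

    def test_consistent_with_cdf_derivative(self):
        grid = np.linspace(0.05, 5.0, 60)
        h = 1e-6
        args = dict(A=0.8, b=1.7, v=1.1, s=1.0)
        num = (accumulator_cdf(grid + h, **args)
               - accumulator_cdf(grid - h, **args)) / (2 * h)
        assert np.max(np.abs(num - accumulator_pdf(grid, **args))) < 1e-5

    def test_integrates_to_positive_drift_probability(self):
        # the slow P(0 < v < b/t) ~ 1/t tail carries real mass, so the
        # upper limit must be infinite for 1e-4 accuracy
        val, _ = integrate.quad(
            lambda t: accumulator_pdf(t, A=0.5, b=1.0, v=1.5), 0, np.inf,
            limit=400)
        assert val == pytest.approx(ndtr(1.5), abs=1e-4)

    def test_small_A_limit_continuous(self):
        # the A -> 0 branch should join smoothly with tiny-but-finite A
        t = np.linspace(0.2, 4, 50)
        close = accumulator_pdf(t, A=2e-6, b=1.0, v=1.2)
        limit = accumulator_pdf(t, A=1e-9, b=1.0, v=1.2)
        assert np.allclose(close, limit, atol=1e-4)


class TestTrialLoglik:
    def test_response_before_nondecision_impossible(self, params):
        trial = TrialRecord("s1", "MDD", "FACE", "FEAR", True, params.t0 / 2)
        assert trial_loglik(trial, params) == -np.inf

    def test_race_symmetry_when_drifts_equal(self, params):
        p = params.replace(v_c_face=1.3, v_e_face=1.3)
        hit = TrialRecord("s1", "MDD", "FACE", "SAD", True, 1.4)
        miss = TrialRecord("s1", "MDD", "FACE", "SAD", False, 1.4)
        assert trial_loglik(hit, p) == pytest.approx(trial_loglik(miss, p))

    def test_defective_mass_sums_to_race_completion_probability(self):
        # P(some accumulator finishes) = 1 - Phi(-v_c) Phi(-v_e)
        p = SubjectParams(A=0.5, k=0.5, t0=0.2, v_c_face=2.0, v_e_face=1.0,
                          v_c_oval=2.0, v_e_oval=1.0)

        def dens(rt, vw, vl):
            return float(np.exp(defective_logpdf(rt - p.t0, vw, vl,
                                                 p.A, p.b)[0]))

        m_c, _ = integrate.quad(lambda t: dens(t, 2.0, 1.0), p.t0, np.inf,
                                limit=400)
        m_e, _ = integrate.quad(lambda t: dens(t, 1.0, 2.0), p.t0, np.inf,
                                limit=400)
        expect = 1 - ndtr(-2.0) * ndtr(-1.0)
        assert m_c + m_e == pytest.approx(expect, abs=1e-4)

    def test_conditioned_likelihood_is_a_proper_density(self):
        # once conditioned on a response occurring, the two
        # choice-conditional trial likelihoods integrate to 1
        p = SubjectParams(A=0.5, k=0.5, t0=0.2, v_c_face=2.0, v_e_face=1.0,
                          v_c_oval=2.0, v_e_oval=1.0)

        def dens(rt, correct):
            t = TrialRecord("s", "MDD", "FACE", "FEAR", correct, rt)
            return np.exp(trial_loglik(t, p))

        m_c, _ = integrate.quad(lambda t: dens(t, True), p.t0, np.inf,
                                limit=400)
        m_e, _ = integrate.quad(lambda t: dens(t, False), p.t0, np.inf,
                                limit=400)
        assert m_c + m_e == pytest.approx(1.0, abs=1e-4)

    @given(st.floats(0.2, 3.0), st.floats(0.2, 3.0), st.floats(0.05, 0.6),
           st.floats(0.1, 4.0), st.floats(0.1, 4.0), st.floats(0.05, 5.0))
    def test_finite_for_any_valid_trial(self, A, k, t0, v_c, v_e, dt):
        p = SubjectParams(A=A, k=k, t0=t0, v_c_face=v_c, v_e_face=v_e,
                          v_c_oval=v_c, v_e_oval=v_e)
        trial = TrialRecord("s", "HCL", "FACE", "HAPPY", True, t0 + dt)
        assert np.isfinite(trial_loglik(trial, p))

    def test_kernel_agrees_with_reference(self, rng):
        # compiled path uses a rational Phi (|err| < 7.5e-8), so the
        # two routes agree to ~1e-3 on a 40-trial log likelihood
        for _ in range(10):
            vals = rng.uniform([0.3, 0.3, 0.1, 0.2, 0.1, 0.2, 0.1],
                               [2.0, 2.5, 0.6, 3.0, 1.5, 3.0, 1.5])
            p = SubjectParams.from_array(vals)
            conds = ["FACE"] * 30 + ["OVAL"] * 10
            correct, rt = simulate_trials(p, conds, rng)
            face = np.array([c == "FACE" for c in conds])
            ref = trials_loglik(rt, correct, face, p)
            out = np.empty(1)
            _kernels.loglik_block(vals[None, :], rt, correct.astype(np.uint8),
                                  face.astype(np.uint8), 0, len(rt), out)
            assert out[0] == pytest.approx(ref, abs=2e-3)


class TestSimulator:
    def test_ballistic_limit_deterministic(self, rng):
        p = SubjectParams(A=1e-9, k=1.0, t0=0.2, v_c_face=1.0, v_e_face=-10,
                          v_c_oval=1.0, v_e_oval=-10, s=1e-9)
        correct, rt = simulate_trials(p, ["FACE"] * 100, rng)
        assert correct.all()
        assert np.allclose(rt, p.b / 1.0 + 0.2, atol=1e-6)

    def test_rt_always_exceeds_nondecision_time(self, params, rng):
        _, rt = simulate_trials(params, ["FACE"] * 500, rng)
        assert (rt > params.t0).all()

    def test_choice_probability_matches_quadrature(self, rng):
        p = SubjectParams(A=0.5, k=0.5, t0=0.2, v_c_face=2.0, v_e_face=1.0,
                          v_c_oval=2.0, v_e_oval=1.0)
        n = 20_000
        correct, _ = simulate_trials(p, ["FACE"] * n, rng)
        m_c, _ = integrate.quad(
            lambda t: np.exp(defective_logpdf(t - p.t0, 2.0, 1.0, p.A, p.b)[0]),
            p.t0, 60, limit=300)
        # simulator renormalises the both-negative-drift event
        p_c = m_c / (1 - ndtr(-2.0) * ndtr(-1.0))
        se = np.sqrt(p_c * (1 - p_c) / n)
        assert correct.mean() == pytest.approx(p_c, abs=3 * se)

    def test_single_trial_wrapper(self, params, rng):
        c, rt = simulate_trial(params, "OVAL", rng)
        assert isinstance(c, bool) and rt > params.t0


class TestTypesAndIO:
    def test_params_invariants(self):
        with pytest.raises(ParameterDomainError):
            SubjectParams(A=0, k=1, t0=0.3, v_c_face=1, v_e_face=1,
                          v_c_oval=1, v_e_oval=1)
        with pytest.raises(ParameterDomainError):
            SubjectParams(A=1, k=-0.1, t0=0.3, v_c_face=1, v_e_face=1,
                          v_c_oval=1, v_e_oval=1)
        p = SubjectParams(A=1, k=0.5, t0=0.3, v_c_face=1, v_e_face=1,
                          v_c_oval=1, v_e_oval=1)
        assert p.b == pytest.approx(1.5)
        assert p.s == 1.0

    def test_trial_record_invariants(self):
        with pytest.raises(DataError):
            TrialRecord("s", "MDD", "FACE", "NA", True, 1.0)
        with pytest.raises(DataError):
            TrialRecord("s", "MDD", "OVAL", "FEAR", True, 1.0)
        with pytest.raises(DataError):
            TrialRecord("s", "MDD", "FACE", "SAD", True, -1.0)

    def test_trial_table_round_trip(self, tmp_path, small_cohort):
        _, trials, _, _ = small_cohort
        for name in ("t.csv", "t.tsv"):
            path = tmp_path / name
            write_trials(trials, path)
            back = read_trials(path)
            assert back.shape == trials.shape
            assert np.allclose(back["rt_sec"], trials["rt_sec"])
            assert (back["subject_id"] == trials["subject_id"]).all()
        records = frame_to_trials(trials.head(20))
        assert trials_to_frame(records).equals(
            trials.head(20).reset_index(drop=True))
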