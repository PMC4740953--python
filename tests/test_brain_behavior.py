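"""Validity filter, behavioral summaries, posterior medians, Spearman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from facelba.brain_behavior import (correlate_rois,
                                    filter_valid, posterior_medians,
                                    read_roi_table, spearman,
                                    summarize_behavior, write_roi_table)
from facelba.errors import ConfigError, ConsistencyError, DataError
from facelba.sampler import PosteriorDraws, SamplerConfig


def _trials(rts, correct=None, group="MDD", emotion="FEAR", subject="s1"):
    n = len(rts)
    correct = correct if correct is not None else [1] * n
    return pd.DataFrame({
        "subject_id": [subject] * n, "group": [group] * n,
        "condition": ["FACE"] * n, "emotion": [emotion] * n,
        "correct": correct, "rt_sec": rts, "valid": [1] * n})


class TestFilterValid:
    def test_boundary_inclusive_at_150ms(self):
        out = filter_valid(_trials([0.100, 0.150, 0.200]))
        assert len(out) == 2
        assert out["rt_sec"].min() == pytest.approx(0.150)
        assert (out["valid"] == 1).all()

    def test_zero_threshold_keeps_all(self):
        assert len(filter_valid(_trials([0.01, 0.5]), min_rt=0.0)) == 2

    def test_idempotent_and_order_preserving(self):
        t = _trials([0.9, 0.1, 0.5, 0.3])
        once = filter_valid(t)
        twice = filter_valid(once)
        assert once.equals(twice)
        assert list(once["rt_sec"]) == [0.9, 0.5, 0.3]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigError):
            filter_valid(_trials([1.0]), min_rt=-0.1)


class TestSummaries:
    def test_all_correct_is_full_accuracy(self):
        out = summarize_behavior(_trials([1.0, 2.0], correct=[1, 1]))
        assert out["mean_accuracy"].iloc[0] == pytest.approx(100.0)

    def test_single_subject_mean_rt(self):
        out = summarize_behavior(_trials([1.0, 2.0, 3.0]))
        assert out["mean_rt"].iloc[0] == pytest.approx(2.0)

    def test_subjects_weighted_equally(self):
        t = pd.concat([_trials([1.0] * 9, subject="a"),
                       _trials([3.0], subject="b")])
        out = summarize_behavior(t)
        assert out["mean_rt"].iloc[0] == pytest.approx(2.0)

    def test_empty_raises(self):
        with pytest.raises(DataError):
            summarize_behavior(_trials([]))

    def test_group_mean_rt_matches_defective_distribution(self, small_cohort):
        # simulated cohort RT mean vs quadrature of the renormalised
        # defective RT density, averaged over the true subject params
        from scipy import integrate
        from scipy.special import ndtr
        from facelba.lba_core import PARAM_NAMES, SubjectParams, defective_logpdf
        _, trials, _, truth = small_cohort
        face = trials[trials.condition == "FACE"]
        expected = []
        for r in truth.subject_params.itertuples(index=False):
            p = SubjectParams.from_array(
                np.array([getattr(r, q) for q in PARAM_NAMES]))
            def mean_num(correct):
                vw, vl = (p.v_c_face, p.v_e_face) if correct else \
                         (p.v_e_face, p.v_c_face)
                f = lambda t: float(np.exp(defective_logpdf(
                    t - p.t0, vw, vl, p.A, p.b)[0]))
                m0, _ = integrate.quad(f, p.t0, 300, limit=400)
                m1, _ = integrate.quad(lambda t: t * f(t), p.t0, 300, limit=400)
                return m0, m1
            mc0, mc1 = mean_num(True)
            me0, me1 = mean_num(False)
            denom = 1 - ndtr(-p.v_c_face) * ndtr(-p.v_e_face)
            expected.append((mc1 + me1) / denom)
        # Monte-Carlo error of 10 subjects x 60 heavy-tailed trials is
        # substantial; a coarse agreement band is the honest check
        assert face["rt_sec"].mean() == pytest.approx(
            np.mean(expected), rel=0.15)


class TestPosteriorMedians:
    def _draws(self, values, sids):
        C, N, P = values.shape
        names = []
        for sid in sids:
            from facelba.lba_core import PARAM_NAMES
            names += [f"{p}|{sid}" for p in PARAM_NAMES]
        return PosteriorDraws(values=values, names=names, subject_ids=sids,
                              group_of={s: "MDD" for s in sids},
                              groups=["MDD"], accept_rates={},
                              config=SamplerConfig())

    def test_constant_and_outlier_robustness(self):
        vals = np.ones((2, 3, 7))
        vals[:, :, 3] = [[1, 2, 100], [2, 1, 100]]
        d = self._draws(vals, ["s1"])
        med = posterior_medians(d, "v_c_face")
        assert med.loc["s1"] == pytest.approx(2.0)
        assert posterior_medians(d, "A").loc["s1"] == pytest.approx(1.0)

    def test_large_sample_median_near_location(self, rng):
        vals = np.ones((2, 5000, 7))
        vals[:, :, 3] = rng.normal(0, 1, (2, 5000))
        d = self._draws(vals, ["s1"])
        assert abs(posterior_medians(d, "v_c_face").loc["s1"]) < 0.03

    def test_missing_subject_raises(self, small_fit):
        with pytest.raises(KeyError):
            small_fit.get("v_c_face|ghost")


class TestSpearman:
    def test_hand_enumeration_example(self):
        # ranks (1,2,3,4) vs (2,1,4,3): rho = 1 - 6*4/(4*15) = 0.6
        res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.rho == pytest.approx(0.6)
        assert res.n == 4

    def test_perfect_monotone(self):
        x = np.array([0.3, 1.2, 2.9, 4.0, 9.0])
        up = spearman(x, np.exp(x))
        dn = spearman(x, -x ** 3)
        assert up.rho == pytest.approx(1.0) and up.p_two_sided == 0.0
        assert dn.rho == pytest.approx(-1.0) and dn.p_two_sided == 0.0

    @given(st.permutations(list(range(8))))
    def test_monotone_transform_invariance(self, perm):
        x = np.arange(8, dtype=float)
        y = np.array(perm, dtype=float)
        base = spearman(x, y).rho
        assert spearman(np.exp(x / 3), y).rho == pytest.approx(base)
        assert spearman(x, 2 * y + 5).rho == pytest.approx(base)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert spearman(x, y).rho == pytest.approx(spearman(y, x).rho)

    def test_matches_scipy_reference(self, rng):
        from scipy import stats
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = spearman(x, y)
        ref_r, ref_p = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(float(ref_r))
        assert res.p_two_sided == pytest.approx(float(ref_p))

    def test_permutation_p_agrees_with_t_approximation(self, rng):
        x = rng.normal(size=25)
        y = 0.6 * x + rng.normal(size=25)
        t_res = spearman(x, y)
        p_res = spearman(x, y, method="permutation", n_permutations=20_000,
                         rng=rng)
        assert p_res.rho == t_res.rho
        assert p_res.p_two_sided == pytest.approx(t_res.p_two_sided, abs=0.02)

    def test_error_conditions(self):
        with pytest.raises(DataError):
            spearman([1, 2], [1, 2])
        with pytest.raises(DataError):
            spearman([1, 1, 1], [1, 2, 3])
        with pytest.raises(DataError):
            spearman([1, 2, 3], [1, 2])


class TestCorrelateROIs:
    def test_within_group_and_consistency(self, tmp_path, rng):
        medians = pd.Series(rng.normal(size=6) + 2,
                            index=pd.Index([f"s{i}" for i in range(6)],
                                           name="subject_id"))
        group_of = {f"s{i}": ("MDD" if i < 3 else "HCL") for i in range(6)}
        roi = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(6)],
            "roi": ["L_fusiform"] * 6,
            "psc": medians.to_numpy(),  # identical values -> rho = 1
        })
        res = correlate_rois(medians, roi, group_of)
        assert {r.group for r in res} == {"MDD", "HCL"}
        assert all(r.rho == pytest.approx(1.0) for r in res)
        path = tmp_path / "roi.csv"
        write_roi_table(roi, path)
        assert read_roi_table(path).shape == roi.shape
        bad = roi.copy()
        bad.loc[0, "subject_id"] = "ghost"
        with pytest.raises(ConsistencyError, match="ghost"):
            correlate_rois(medians, bad, group_of)
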