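"""Synthetic study cohorts with known ground truth.

No raw data accompany the study this pipeline emulates, so this module
generates complete stand-in inputs that mirror its design: 26 MDD and
37 HCL adolescents, one 490-s run of 60 FACE + 20 OVAL trials (6 s
each plus a terminal 10-s blank), behavior simulated from the LBA with
subject parameters drawn from group-specific positive-truncated normal
hyperdistributions, and a per-subject ROI table whose percent signal
change carries a controlled monotone association with each subject's
true correct-drift rate.

The ROI association uses a Gaussian copula: the subjects' true
``v_c_face`` values are rank-transformed to normal scores and mixed
with independent Gaussian noise at the Pearson weight
``r = 2 sin(pi rho_s / 6)``, which makes the *expected* Spearman
correlation equal the requested ``roi_assoc``.  The association
targets the true drift, not its later estimate, so estimation noise
attenuates the correlation recovered by the full pipeline — expect
``|observed rho| <= |roi_assoc|``.

All output is reproducible to the byte from the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import ConfigError
from .hierarchy import GroupHypers, truncnorm_rvs
from .lba_core import (EMOTIONS, NO_EMOTION, PARAM_NAMES, SubjectParams,
                       simulate_trials, trials_to_frame, write_trials,
                       TrialRecord)
from .brain_behavior import write_roi_table


def default_true_hypers() -> dict[str, GroupHypers]:
    """Generating hyperparameters calibrated to the study's behavioral scale.

    Chosen so a default cohort lands near 80% accuracy and a 2.2-s
    mean RT on FACE trials, with the MDD group's correct-drift
    hyperdistribution slightly above the control group's (the
    direction, not the magnitude, of the study's descriptive result).
    """
    shared = {
        "A": (1.2, 0.30), "k": (1.8, 0.30), "t0": (0.5, 0.10),
        "v_e_face": (0.8, 0.15), "v_c_oval": (2.4, 0.30),
        "v_e_oval": (1.0, 0.15),
    }
    out = {}
    for group, v_c_face in (("MDD", (2.10, 0.25)), ("HCL", (2.00, 0.25))):
        mu = {p: shared[p][0] for p in shared}
        sigma = {p: shared[p][1] for p in shared}
        mu["v_c_face"], sigma["v_c_face"] = v_c_face
        out[group] = GroupHypers(group, mu, sigma)
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic-cohort settings; the defaults reproduce the study design."""

    n_mdd: int = 26
    n_hcl: int = 37
    n_face: int = 60
    n_oval: int = 20
    trial_duration: float = 6.0
    terminal_blank: float = 10.0
    true_hypers: dict[str, GroupHypers] = field(default_factory=default_true_hypers)
    roi_name: str = "L_fusiform"
    roi_assoc: float = -0.45
    noise_sd: float = 0.30
    psc_mean: dict[str, float] = field(
        default_factory=lambda: {"MDD": 0.32, "HCL": 0.77})
    block_len: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mdd, self.n_hcl, self.n_face, self.n_oval,
               self.block_len) <= 0:
            raise ConfigError("all counts must be positive")
        if self.trial_duration <= 0 or self.terminal_blank < 0:
            raise ConfigError("invalid durations")
        if not abs(self.roi_assoc) < 1:
            raise ConfigError(
                f"roi_assoc must satisfy |rho| < 1 (the Gaussian copula's "
                f"feasible bound); got {self.roi_assoc}")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        for g in ("MDD", "HCL"):
            if g not in self.true_hypers:
                raise ConfigError(f"true_hypers missing group {g!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_hypers"] = {
            g: {"mu": dict(h.mu), "sigma": dict(h.sigma)}
            for g, h in self.true_hypers.items()}
        return d


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score recovery against a generated cohort."""

    subject_params: pd.DataFrame  # subject_id, group + 7 parameter columns
    hypers: dict[str, GroupHypers]
    roi_assoc: float
    copula_pearson: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.subject_params.itertuples(index=False):
            for p in PARAM_NAMES:
                rows.append(("subject", r.group, r.subject_id, p, getattr(r, p)))
        for g, h in self.hypers.items():
            for p in PARAM_NAMES:
                rows.append(("hyper_mu", g, "", p, h.mu[p]))
                rows.append(("hyper_sigma", g, "", p, h.sigma[p]))
        return pd.DataFrame(rows, columns=["level", "group", "subject_id",
                                           "parameter", "value"])


def build_schedule(config: CohortConfig) -> pd.DataFrame:
    """Ordered trial plan with onsets.

    Emotions are dealt into fixed blocks of ``block_len`` trials whose
    order rotates across cycles (counterbalanced, never shuffled),
    with an OVAL block closing each cycle.  Total duration is
    ``(n_face + n_oval) * trial_duration + terminal_blank`` seconds.
    """
    per = {e: config.n_face // len(EMOTIONS) for e in EMOTIONS}
    for i in range(config.n_face % len(EMOTIONS)):
        per[EMOTIONS[i]] += 1

    def chunks(total):
        out, left = [], total
        while left > 0:
            c = min(config.block_len, left)
            out.append(c)
            left -= c
        return out

    emo_chunks = {e: chunks(per[e]) for e in EMOTIONS}
    oval_chunks = chunks(config.n_oval)
    plan: list[tuple[str, str]] = []
    cycle = 0
    while any(emo_chunks.values()) or oval_chunks:
        order = EMOTIONS[cycle % len(EMOTIONS):] + EMOTIONS[:cycle % len(EMOTIONS)]
        for e in order:
            if emo_chunks[e]:
                plan.extend([("FACE", e)] * emo_chunks[e].pop(0))
        if oval_chunks:
            plan.extend([("OVAL", NO_EMOTION)] * oval_chunks.pop(0))
        cycle += 1

    n = len(plan)
    df = pd.DataFrame(plan, columns=["condition", "emotion"])
    df.insert(0, "trial", np.arange(n))
    df["onset_sec"] = np.arange(n) * config.trial_duration
    df["duration_sec"] = config.trial_duration
    df.attrs["total_duration_sec"] = n * config.trial_duration + config.terminal_blank
    return df


def total_duration(config: CohortConfig) -> float:
    """Run length in seconds implied by the schedule."""
    return ((config.n_face + config.n_oval) * config.trial_duration
            + config.terminal_blank)


def sample_subject_params(hypers: GroupHypers,
                          rng: np.random.Generator) -> SubjectParams:
    """One subject's parameters drawn from the group hyperdistributions."""
    vals = truncnorm_rvs(hypers.mu_array(), hypers.sigma_array(), (7,), rng)
    return SubjectParams.from_array(vals)


def _copula_psc(v_true: np.ndarray, rho_s: float, mean: float, sd: float,
                rng: np.random.Generator) -> np.ndarray:
    """PSC values with expected Spearman ``rho_s`` against ``v_true``."""
    n = len(v_true)
    r = 2.0 * math.sin(math.pi * rho_s / 6.0)
    ranks = pd.Series(v_true).rank(method="average").to_numpy()
    z = ndtri((ranks - 0.5) / n)
    latent = r * z + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return mean + sd * latent


def generate_cohort(config: CohortConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Full synthetic study inputs: trial table, ROI table, ground truth.

    Behavior is simulated trial-by-trial on the task schedule for
    every subject; the ROI table carries one percent-signal-change
    value per subject for ``config.roi_name``, associated with the
    true ``v_c_face`` per group through the Gaussian copula.
    """
    rng = np.random.default_rng(config.seed)
    schedule = build_schedule(config)
    conditions = schedule["condition"].tolist()
    emotions = schedule["emotion"].tolist()

    trial_rows = []
    truth_rows = []
    roi_frames = []
    for group, n_sub in (("MDD", config.n_mdd), ("HCL", config.n_hcl)):
        hyp = config.true_hypers[group]
        v_true = np.empty(n_sub)
        sids = [f"{group}{i + 1:03d}" for i in range(n_sub)]
        for j, sid in enumerate(sids):
            params = sample_subject_params(hyp, rng)
            v_true[j] = params.v_c_face
            correct, rt = simulate_trials(params, conditions, rng)
            for cond, emo, corr, t in zip(conditions, emotions, correct, rt):
                trial_rows.append(TrialRecord(sid, group, cond, emo,
                                              bool(corr), float(t)))
            truth_rows.append((sid, group, *params.as_array()))
        psc = _copula_psc(v_true, config.roi_assoc, config.psc_mean[group],
                          config.noise_sd, rng)
        roi_frames.append(pd.DataFrame({
            "subject_id": sids, "roi": config.roi_name, "psc": psc}))

    trials = trials_to_frame(trial_rows)
    roi = pd.concat(roi_frames, ignore_index=True)
    truth = GroundTruth(
        subject_params=pd.DataFrame(
            truth_rows, columns=["subject_id", "group", *PARAM_NAMES]),
        hypers=dict(config.true_hypers),
        roi_assoc=config.roi_assoc,
        copula_pearson=2.0 * math.sin(math.pi * config.roi_assoc / 6.0),
    )
    return trials, roi, truth


def write_cohort(outdir, trials: pd.DataFrame, roi: pd.DataFrame,
                 truth: GroundTruth, config: CohortConfig) -> None:
    """Persist a generated cohort as delimited text plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_trials(trials, outdir / "trials.csv")
    write_roi_table(roi, outdir / "roi.csv")
    truth.to_frame().to_csv(outdir / "ground_truth.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"stage": "generate", "config": config.to_dict()}, fh,
                  indent=2, sort_keys=True)
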