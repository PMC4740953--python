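"""Behavioral summaries and brain-behavior rank correlations.

Links the model to the imaging side of the study: filters trials by
the response-validity threshold (responses faster than 150 ms are
treated as invalid), summarises RT/accuracy per group and emotion,
reduces each subject's posterior to its median, and rank-correlates
those medians with per-subject ROI activation (percent signal change,
FACE-OVAL contrast) within each group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ConsistencyError, DataError
from .sampler import PosteriorDraws

#: Minimum RT (seconds) for a response to count as valid.
DEFAULT_MIN_RT = 0.150

ROI_COLUMNS = ["subject_id", "roi", "psc"]


@dataclass(frozen=True)
class ROIRecord:
    """Per-subject percent signal change for one named region."""

    subject_id: str
    roi: str
    psc: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.psc):
            raise DataError(f"psc must be finite ({self.subject_id}/{self.roi})")


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation of one ROI against one behavioral measure."""

    roi: str
    group: str
    rho: float
    p_two_sided: float
    n: int

    def to_dict(self) -> dict:
        return {"roi": self.roi, "group": self.group, "rho": self.rho,
                "p_two_sided": self.p_two_sided, "n": self.n}


def filter_valid(trials: pd.DataFrame,
                 min_rt: float = DEFAULT_MIN_RT) -> pd.DataFrame:
    """Keep trials with ``rt >= min_rt`` (inclusive) and set the valid flag.

    Order-preserving and idempotent.
    """
    if min_rt < 0:
        raise ConfigError(f"min_rt must be >= 0, got {min_rt}")
    out = trials[trials["rt_sec"] >= min_rt].copy()
    out["valid"] = 1
    return out


def summarize_behavior(trials: pd.DataFrame,
                       groups: Iterable[str] | None = None) -> pd.DataFrame:
    """Group x emotion mean RT (s) and accuracy (%) with between-subject SEM.

    Trial data are first averaged within subject, then aggregated to
    the group mean +/- SEM, so subjects with unequal trial counts carry
    equal weight.  If ``groups`` is given, groups with no valid trials
    appear as explicit all-NaN marker rows (n_subjects 0) rather than
    silently vanishing.  An entirely empty input raises.
    """
    if len(trials) == 0:
        raise DataError("no trials to summarize")
    per_subj = (trials.groupby(["group", "emotion", "subject_id"])
                .agg(mean_rt=("rt_sec", "mean"), accuracy=("correct", "mean"))
                .reset_index())
    per_subj["accuracy"] *= 100.0

    def sem(x):
        x = np.asarray(x, dtype=float)
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    out = (per_subj.groupby(["group", "emotion"])
           .agg(n_subjects=("subject_id", "nunique"),
                mean_rt=("mean_rt", "mean"), sem_rt=("mean_rt", sem),
                mean_accuracy=("accuracy", "mean"),
                sem_accuracy=("accuracy", sem))
           .reset_index())
    if groups is not None:
        for g in groups:
            if g not in set(out["group"]):
                out = pd.concat([out, pd.DataFrame([{
                    "group": g, "emotion": pd.NA, "n_subjects": 0,
                    "mean_rt": np.nan, "sem_rt": np.nan,
                    "mean_accuracy": np.nan, "sem_accuracy": np.nan}])],
                    ignore_index=True)
    return out


def posterior_medians(draws: PosteriorDraws, parameter: str) -> pd.Series:
    """Per-subject posterior median of one subject-level parameter.

    The median is taken over all retained (chain, iteration) draws;
    indexed by subject id.
    """
    mat = draws.subject_matrix(parameter)  # (chain, iter, subject)
    med = np.median(mat.reshape(-1, mat.shape[2]), axis=0)
    return pd.Series(med, index=pd.Index(draws.subject_ids, name="subject_id"),
                     name=parameter)


def spearman(x, y, roi: str = "", group: str = "",
             method: str = "t",
             n_permutations: int = 100_000,
             rng: np.random.Generator | None = None) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive midranks; rho is the Pearson correlation of the
    ranked sequences.  ``method="t"`` (default) uses the
    t-approximation ``t = rho sqrt((n-2)/(1-rho^2))``; ``|rho| = 1``
    reports p = 0.  ``method="permutation"`` estimates p by seeded
    random permutation of ``y`` (requires ``rng``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-d sequences of equal length")
    if len(x) < 3:
        raise DataError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("inputs must be finite")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise DataError("constant input: rank correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) > 1.0 - 1e-12:  # snap exact monotone orderings to +/-1
        rho = math.copysign(1.0, rho)
    if method == "t":
        if abs(rho) == 1.0:
            p = 0.0
        else:
            n = len(x)
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    elif method == "permutation":
        if rng is None:
            raise DataError("permutation method needs a seeded rng")
        hits = 0
        for _ in range(n_permutations):
            rperm = rng.permutation(ry)
            r = np.corrcoef(rx, rperm)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise DataError(f"unknown method {method!r}")
    return CorrelationResult(roi=roi, group=group, rho=rho,
                             p_two_sided=p, n=len(x))


def correlate_rois(medians: pd.Series, roi_table: pd.DataFrame,
                   group_of: dict[str, str],
                   groups: Iterable[str] | None = None) -> list[CorrelationResult]:
    """Within-group Spearman correlations of posterior medians vs each ROI.

    ``roi_table`` is long-format (subject_id, roi, psc).  Subjects in
    the ROI table without a posterior median (or vice versa, within a
    correlated group) raise a consistency error naming the offenders.
    """
    missing = set(roi_table["subject_id"].astype(str)) - set(medians.index)
    if missing:
        raise ConsistencyError(
            f"ROI table has subjects with no posterior: {sorted(missing)}")
    groups = list(groups) if groups is not None else sorted(set(group_of.values()))
    results = []
    for roi_name, sub in roi_table.groupby("roi", sort=True):
        sub = sub.set_index(sub["subject_id"].astype(str))
        for g in groups:
            sids = [s for s in medians.index if group_of[s] == g
                    and s in sub.index]
            if len(sids) < 3:
                continue
            results.append(spearman(medians.loc[sids].to_numpy(),
                                    sub.loc[sids, "psc"].to_numpy(),
                                    roi=str(roi_name), group=g))
    return results


def read_roi_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    missing = set(ROI_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"ROI table {path} missing columns: {sorted(missing)}")
    return df


def write_roi_table(df: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)
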