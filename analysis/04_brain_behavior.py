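#!/usr/bin/env python
"""Brain-behavior linkage: drift medians vs ROI activation.

Reduces each subject's correct-drift (FACE) posterior to its median
and computes the within-group Spearman rank correlation against the
ROI table's percent signal change, mirroring how individual-level
perceptual processing efficiency is relates to fusiform activation.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from facelba.brain_behavior import (correlate_rois, posterior_medians,
                                    read_roi_table)
from facelba.lba_core import read_trials
from facelba.sampler import load_draws


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--fit", type=Path, default=Path("results/fit"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    trials = read_trials(args.cohort / "trials.csv")
    draws = load_draws(args.fit / "draws.parquet", trials)
    roi = read_roi_table(args.cohort / "roi.csv")
    medians = posterior_medians(draws, "v_c_face")

    results = correlate_rois(medians, roi, draws.group_of,
                             groups=draws.groups)
    args.outdir.mkdir(parents=True, exist_ok=True)
    medians.rename("v_c_face_median").to_csv(args.outdir / "drift_medians.csv")
    rows = [r.to_dict() for r in results]
    pd.DataFrame(rows).to_csv(args.outdir / "correlations.csv", index=False)
    with open(args.outdir / "correlations.json", "w") as fh:
        json.dump(rows, fh, indent=2)

    for r in results:
        print(f"{r.roi} [{r.group}]: Spearman rho = {r.rho:+.3f} "
              f"(two-sided p = {r.p_two_sided:.3f}, n = {r.n})")
    print(f"medians and correlations written to {args.outdir}")


if __name__ == "__main__":
    main()
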