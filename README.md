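# facelba

Hierarchical Bayesian Linear Ballistic Accumulator (LBA) analysis of
two-choice facial-emotion identification in two groups — depressed
adolescents (MDD) and healthy controls (HCL) — with a posterior
odds-ratio group comparison and brain–behavior rank correlation.

## Who this is for

Model-based cognitive neuroscientists who want to go beyond mean RT
and accuracy: decompose two-choice behavior into perceptual
processing efficiency (drift rate), response caution (threshold) and
non-decision time; compare those components between clinical groups
at the population level; and relate individual-level estimates to
fMRI ROI activation. The study design emulated here is an
emotion-identification task of dynamically morphing faces (60 FACE +
20 OVAL control trials, one 490-s run) in 26 MDD and 37 HCL
adolescents, with left-fusiform percent signal change as the ROI of
interest. Because no raw data are deposited for that design, the
package ships a seeded synthetic-cohort generator with known ground
truth, so every stage of the pipeline is testable end to end.

## The model

Each trial is a race between two ballistic accumulators. Accumulator
*i* starts at `U ~ Uniform[0, A]`, grows at rate `v ~ Normal(v_i, s)`
(`s = 1` fixed), and responds when it reaches `b = A + k`; observed
RT adds a non-decision time `t0`. The likelihood of choice *i* at
time `t` is the defective density

    f_i(t − t0) · (1 − F_j(t − t0)),

with `f`, `F` the closed-form first-passage density/CDF. Subject
parameters `(A, k, t0, v_c, v_e)` — drifts split by FACE/OVAL
condition — are drawn from positive-truncated normal
hyperdistributions `TN⁺(μ_p, σ_p)` per group, and everything is
estimated jointly by differential-evolution MCMC (20 chains × 5000
samples by default).

Group comparison: each posterior draw of a group's `(μ, σ)` for
correct drift is mapped to the truncated-normal mean
`μ + σφ(μ/σ)/Φ(μ/σ)`; the two groups' draw sequences are compared
over all cross-pairs, and the exceedance fraction `c` is reported as
the oriented odds ratio `OR = c/(1 − c) ≥ 1`. Brain–behavior linkage:
Spearman's `r_s` (midranks, two-sided t-approximation) between
per-subject posterior medians of `v_c` and ROI percent signal change,
within each group.

## Worked example

The numbered scripts under `analysis/` run the whole study pipeline
at desk scale (a 16 chain × 800 sample fit of the full 63-subject
cohort; under a minute on one core):

```bash
python analysis/01_generate_cohort.py
python analysis/02_fit_model.py
python analysis/03_compare_groups.py
python analysis/04_brain_behavior.py
```

Output of a run with the default seed (2016):

```
cohort: 63 subjects, 5040 trials (5040 valid at the 150 ms floor)
  MDD: n=26, mean RT 1.72 s, accuracy 81.3%
  HCL: n=37, mean RT 1.93 s, accuracy 80.4%

hyper-mean of v_c (FACE): MDD 2.134 +/- 0.057, HCL 2.038 +/- 0.049
exhaustive cross-pair count 0.904 over 163840000 pairs -> OR = 9.37 favouring MDD

L_fusiform [MDD]: Spearman rho = -0.153 (two-sided p = 0.456, n = 26)
L_fusiform [HCL]: Spearman rho = -0.320 (two-sided p = 0.053, n = 37)
```

Reading the numbers: behavior sits near the study's scale (~80%
accuracy, ~2 s mean RT; cohort-level mean RT is noisy because LBA
response times are heavy-tailed). The generator gives the MDD group a
slightly higher true correct-drift hyper mean (2.1 vs 2.0), and the
fit recovers both values and the direction — the odds ratio favours
MDD, i.e. a value drawn from the MDD drift hyperdistribution exceeds
an HCL draw far more often than not. The ROI table is built with an
expected Spearman of −0.45 against each subject's *true* drift, so
the recovered within-group correlations are negative but attenuated
by estimation noise on the per-subject medians (60 FACE trials each).
The fit script also logs acceptance rates and split R-hat per
hyperparameter; the drift hyper means this analysis consumes are the
best-mixing quantities, while `t0` and the group-scale sigmas
converge slowest at this design's 80 trials per subject (see
`docs/methods.md`).

The `facelba` CLI exposes the same stages against a config file
(`facelba generate|fit|compare|correlate|report --config configs/default.yaml
--outdir runs/demo`), with exit codes 2/3/4 distinguishing config,
data-consistency and numerical errors.

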