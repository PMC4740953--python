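# Methods

## The behavioral model

Two-choice decisions on each trial are modelled with the Linear
Ballistic Accumulator (LBA). Two accumulators — one per response —
start at independent values drawn uniformly from `[0, A]`, grow
linearly at a drift rate drawn once per trial from `Normal(v, s)`,
and the first to reach the threshold `b` determines the choice; the
observed response time is the winner's first-passage time plus a
non-decision offset `t0`. There is no within-trial noise: all
variability comes from the start points and the trial-to-trial drift
draws. `s = 1` fixes the evidence scale, which makes the remaining
parameters identifiable.

Each subject carries seven parameters: `A`, the threshold offset
`k = b − A` (parameterising the threshold this way keeps `b > A` by
construction, so no proposal ever needs rejection on that account),
`t0`, and four drift means — correct (`v_c`) and error (`v_e`)
accumulators in each of the FACE and OVAL conditions. Emotions are
collapsed into the single FACE condition; the trial table keeps the
emotion labels for behavioral summaries only.

The likelihood of an observed (choice, RT) pair starts from the
defective density `f_win(rt − t0) · (1 − F_lose(rt − t0))`, with `f`
and `F` the closed-form single-accumulator first-passage density and
CDF; the two choice-conditional defective densities jointly integrate
to `1 − Φ(−v_c)Φ(−v_e)`, the probability that any accumulator ever
finishes (a trial whose two sampled drifts are both negative never
produces a response). Because the task forces a response on every
recorded trial — and the forward simulator accordingly redraws the
drifts in the both-negative event — the trial likelihood conditions
on a response occurring, dividing the defective density by
`1 − Φ(−v_c)Φ(−v_e)`. This is not a cosmetic choice. The omitted
normalizer depends on the drifts, so fitting the *unconditioned*
defective form to forced-response data has a pseudo-true optimum with
`v_c` biased upward by roughly +0.15 at this package's default
generator settings (measured by direct maximum likelihood at 20,000
trials; the gain comes entirely from shrinking the model's predicted
no-response mass). That bias is comparable to the hyper-posterior
interval width at realistic cohort sizes and destroys parameter
recovery calibration. `condition_on_response=False` recovers the raw
defective likelihood for data where no-response trials were recorded
and discarded at random, and `defective_logpdf` itself always exposes
the standard defective closed form. The residual mismatch of the
redraw convention (redrawn trials reuse their start points) is below
detectability at 2 × 10⁶ simulated trials.

RTs are in seconds from stimulus (morph) onset and are not
truncated from above; the slow `P(0 < v < b/t) ~ 1/t` tail of the
first-passage distribution is real model mass, which is why
validation integrals run to infinity.

## The hierarchy

Subject parameters are exchangeable draws from positive-truncated
normal hyperdistributions, one `(μ_p, σ_p)` pair per parameter per
group, estimated separately for the MDD and HCL groups (one joint
sampler state, disjoint hypers — computationally one fit, statistically
two). Hyperpriors are weakly informative on the `s = 1` scale:
`μ_p ~ TN⁺(1, 3)` for the accumulator geometry and drifts,
`TN⁺(0.3, 0.3)` for `t0` (its natural scale is a few hundred
milliseconds), and `σ_p ~ TN⁺(0, 1)` (a half-normal). All are
configurable; nothing here is a reconstruction of unreported
choices elsewhere, they are this package's defaults.

## Sampling

The joint posterior is sampled by blocked differential-evolution
MCMC. Proposals are `θ* = θ_i + γ(θ_m − θ_n) + U(−b0, b0)` with
partners `m, n` drawn without replacement per block per iteration,
`γ = 2.38/√(2d)` rescaled by `U(0.5, 1)` per update (the rescaling
keeps the interacting chains from coalescing onto a point), and
`b0 = 0.001`. Blocks are each subject's 7 parameters (conditionally
independent given the hypers, so all subject blocks are proposed and
accepted in parallel) and each group's 14 hyperparameters. Defaults
are 20 chains and 5000 retained samples; burn-in defaults to half
the retained count. During burn-in only, a migration step
(probability 0.1 per iteration) rotates whole states among a random
chain subset through Metropolis swaps.

Two further choices matter in practice:

* **Evidence-scale move.** With `s` fixed, the threshold geometry and
  all drift means trade off along a multiplicative likelihood ridge
  (a larger `b` with proportionally faster drifts predicts nearly the
  same behavior). Plain crossover traverses that ridge very slowly,
  which first showed up as burn-in-dependent bias in recovered
  hyper means. Every second iteration the sampler therefore proposes,
  per group, a joint multiplicative rescale of every evidence-unit
  quantity (each subject's `A`, `k` and drifts plus the group's
  corresponding `μ` and `σ` hypers) with a log-normal step
  (SD 0.06) and the `n·log λ` Jacobian term in the acceptance ratio.
* **Initialization.** Chains start from moment-based per-subject
  heuristics — `t0` at half the fastest response, the threshold scale
  from the decision-time coefficient of variation, drifts from the
  median decision time and accuracy — jittered per chain, with each
  chain additionally assigned its own global evidence-scale factor so
  that the initial chain cloud is spread *along* the ridge and DE
  proposals inherit that direction. Initializing from hyperprior
  draws instead (the obvious alternative) frequently stranded whole
  chains in the small-`σ` funnel: subjects pinned at a bad value that
  the shrunken hyperdistribution then refuses to release.

Positivity is enforced through the target (out-of-support proposals
get `−inf` log posterior and are rejected, never clamped), so every
retained draw satisfies the domain constraints. Runs are reproducible
to the bit from the configuration seed. Rank-normalised split R-hat
and bulk ESS (via arviz) are reported per hyperparameter after each
fit; non-convergence warns but does not fail, matching how these fits
are inspected in practice.

The trial likelihood inside the sampler is a numba kernel whose
normal CDF uses the Zelen–Severo rational approximation (absolute
error < 7.5e−8; it reuses the normal pdf the LBA closed form needs
anyway, and roughly halves the sampler's runtime). The numpy/scipy
implementation in `lba_core` is the full-precision reference; the two
agree to ~1e−3 on an 80-trial subject log likelihood and are
equality-tested at that tolerance. Densities are floored at 1e−300
before logs; `−inf` is reserved for structurally impossible data
(`rt ≤ t0`). Start-point ranges below 1e−6 route to the analytic
`A → 0` limiting density.

## Group comparison

Following the figure-level definition of the group contrast, each
retained `(μ, σ)` draw of a group's correct-drift hyperdistribution
is mapped to the truncated-normal mean `μ + σφ(μ/σ)/Φ(μ/σ)`. The two
groups' sequences are compared exhaustively: `count` is the fraction
of cross-pairs in which one group's value strictly exceeds the
other's (ties count for neither side), and the odds ratio is
`count/(1 − count)`, oriented to be ≥ 1 with the favoured group
recorded. A count of exactly 0 or 1 is reported as an infinite odds
ratio with a degeneracy flag rather than an exception. The exhaustive
count is computed by sort-and-rank in O(N log N); the O(N²)
enumeration survives as a test oracle. An alternative reading of the
comparison — drawing one fresh value from each draw's plug-in
hyperdistribution instead of taking its mean — is available as
`mode="plugin"`; the hyper-mean reading is the default.

## Brain–behavior linkage

Responses faster than 150 ms are invalid and excluded before
modelling (inclusive threshold: a 150 ms response is valid).
Individual-level estimates are posterior medians over all retained
draws. Spearman's rank correlation uses midranks for ties with the
two-sided t-approximation `t = ρ√((n−2)/(1−ρ²))` (scipy's
definition; at n = 26–37 the approximation is standard practice), a
seeded permutation mode is available for verification, and `|ρ| = 1`
reports p = 0. Correlations are computed within group only, with no
multiple-comparison correction at this stage. Constant inputs raise
rather than return NaN.

## The synthetic cohort

No raw data accompany the study this pipeline emulates, so the
generator reproduces its design: 26 MDD and 37 HCL subjects, one run
of 60 FACE + 20 OVAL trials at 6 s per trial plus a terminal 10-s
blank (490 s total), emotions dealt into fixed counterbalanced blocks
of five (rotating order across cycles, never shuffled, mirroring a
counterbalanced-but-not-randomised design). Subject parameters come
from group truncated-normal hyperdistributions whose defaults were
calibrated by simulation to land near the study's behavioral scale —
about 80% accuracy and 2.2 s mean RT on FACE trials:
`A ~ TN⁺(1.2, 0.3)`, `k ~ TN⁺(1.8, 0.3)`, `t0 ~ TN⁺(0.5, 0.1)`,
`v_c_face ~ TN⁺(2.1, 0.25)` for MDD and `TN⁺(2.0, 0.25)` for HCL
(the direction, not the magnitude, of the study's descriptive
difference), `v_e_face ~ TN⁺(0.8, 0.15)`, and faster, easier OVAL
drifts (`2.4/1.0`).

The ROI table carries one percent-signal-change value per subject
(default region `L_fusiform`, group means 0.32/0.77 and SD 0.30 on
the scale of reported activation tables). Its association with
behavior is built by a Gaussian copula per group: the subjects' true
`v_c_face` values are rank-transformed to normal scores and mixed
with independent Gaussian noise at Pearson weight
`r = 2 sin(π ρ_s / 6)`, so the expected Spearman correlation equals
the requested `roi_assoc` (default −0.45). The association targets
the *true* drift, not its estimate; estimation noise therefore
attenuates the correlation the fitted pipeline recovers, and users
should expect `|observed ρ| ≤ |roi_assoc|`.

What the generator does not emulate: fMRI time series, censoring or
missing data, exclusions, response deadlines (simulated RTs are
untruncated and occasionally exceed the nominal trial window, which
real button boxes would cut off), and any within-emotion drift
differences. Tests passing on these cohorts show the pipeline's
statistical machinery is correct under the model's own assumptions;
they cannot show that the LBA is the right model for any particular
real dataset.

## Problem sizes used in validation

The packaged checks run at desk scale, chosen to keep the full suite
inside ordinary CI budgets while leaving each check statistically
meaningful: parameter recovery uses 20 replicates of 2 × 20 subjects
× 320 trials at 20 chains × 1000 retained draws (burn-in 400),
checking that the central 95% interval for each group's `v_c` hyper
mean covers the generating value at least 80% of the time; the
end-to-end linkage check uses 20 replicates of a 26 + 6 subject
cohort at 16 chains × 350 draws, requiring the recovered drift–ROI
correlation to be negative (and the group odds ratio to point the
right way) in at least 18. Simulator/likelihood agreement uses 1e5
trials; the analytic-target sampler check uses 20 chains × 2000
draws. The full 63-subject cohort fits in well under a minute per
thousand iterations on one core, so sampling effort is not the
binding constraint at this design — identifiability is (next
section).

## Known limitations

* The simulator's redraw convention resamples drifts but reuses the
  trial's start points in the (rare) both-drifts-negative event; the
  response-conditioned likelihood treats the redraw as independent.
  The difference was not detectable at 2 × 10⁶ simulated trials.
* At the study's design of 80 trials per subject, `t0` and the
  group-scale `σ` hypers are weakly identified and live in a
  hierarchical funnel. The blocked DE sampler handles the drift hyper
  means well (they are stable across settings and validated by the
  recovery suite at 320 trials per subject), but the funnel
  directions mix slowly, and in very long runs on 80-trial cohorts
  the chains can spread apart in the funnel, which shows up as
  falling acceptance rates and `t0`/`σ` R-hat well above 1. Always
  read the logged diagnostics; a non-centered reparameterisation
  would be the principled fix and is out of scope here.
* The t-approximation p-value for Spearman is approximate for n < ~10;
  use the permutation mode there.
* One fit holds all chains' states in memory; at the default study
  scale the posterior store is a few hundred MB.
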