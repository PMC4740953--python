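# Default run configuration. Every key is optional; omitted keys fall
# back to the package defaults shown here.

cohort:
  n_mdd: 26            # subjects per group
  n_hcl: 37
  n_face: 60           # trials per run
  n_oval: 20
  trial_duration: 6.0  # seconds
  terminal_blank: 10.0 # seconds
  roi_name: L_fusiform
  roi_assoc: -0.45     # expected Spearman of true v_c vs ROI signal
  noise_sd: 0.30       # percent-signal-change scale
  seed: 2016

sampler:
  n_chains: 20
  n_samples: 5000      # retained per chain
  burn_in: 2500
  jitter_b0: 0.001
  migration_prob: 0.1  # burn-in only
  rescale_every: 2     # group evidence-scale move cadence (0 disables)
  rescale_step: 0.06
  seed: 2016

analysis:
  parameter: v_c_face  # drift compared between groups / correlated with ROI
  min_rt: 0.150        # response-validity floor, seconds
  or_mode: mean        # "mean" (per-draw truncnorm means) or "plugin"
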