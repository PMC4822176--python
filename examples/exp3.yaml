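# Two-group comparison after a passive-mobilization-style manipulation
# (modelled only as a group label): effect planted in the motion group.
space: exp3
seed: 13
design:
  groups: [motion, no_motion]
  conditions: [real, fake, void]
  n_participants_per_group: 7
effects:
  motion:
    residual_sd_ms: 150.0
    cce_contra_ms: {real: 45.0, fake: 45.0, void: 45.0}
    cce_ipsi_extra_ms: {real: 70.0, fake: 70.0, void: 70.0}
    error_rate: 0.08
  no_motion:
    residual_sd_ms: 150.0
    cce_contra_ms: {real: 20.0, fake: 20.0, void: 20.0}
    error_rate: 0.08
mcmc: {n_chains: 3, burn_in: 1000, n_samples: 10000}
pilot: {n_chains: 2, burn_in: 200, n_samples: 500}
out: scratch/exp3_report.json
summary: scratch/exp3_summary.txt
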