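# Feet-centred CCT, three viewing conditions, one healthy-control-like
# group.  The generator plants the ipsi-vs-contra effect in the "real"
# condition only; the analysis should recover the pps:real hypothesis.
space: exp1
seed: 11
design:
  groups: [control]
  conditions: [real, fake, void]
  n_participants_per_group: 18
  n_blocks: 3
  trials_per_combo: 9
effects:
  control:
    baseline_rt_ms: 650.0
    participant_sd_ms: 40.0
    residual_sd_ms: 150.0
    cce_contra_ms: {real: 30.0, fake: 30.0, void: 30.0}
    cce_ipsi_extra_ms: {real: 70.0}
    error_rate: 0.07
mcmc: {n_chains: 3, burn_in: 1000, n_samples: 10000}
pilot: {n_chains: 2, burn_in: 200, n_samples: 500}
out: scratch/exp1_report.json
summary: scratch/exp1_summary.txt
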