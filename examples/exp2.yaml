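# Hand-centred CCT, two placement conditions; effect planted in the
# "within" condition only.
space: exp2
seed: 12
design:
  groups: [pcl]
  conditions: [within, outside]
  n_participants_per_group: 14
effects:
  pcl:
    baseline_rt_ms: 650.0
    participant_sd_ms: 40.0
    residual_sd_ms: 150.0
    cce_contra_ms: {within: 35.0, outside: 40.0}
    cce_ipsi_extra_ms: {within: 85.0}
    error_rate: 0.06
mcmc: {n_chains: 3, burn_in: 1000, n_samples: 10000}
pilot: {n_chains: 2, burn_in: 200, n_samples: 500}
out: scratch/exp2_report.json
summary: scratch/exp2_summary.txt
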