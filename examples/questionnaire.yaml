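# Ownership questionnaire analysis: 22 hypotheses per component via the
# ordinal-logit product space.  Reduced MCMC budget — the 22-model space
# with MH updates is the slowest analysis in the suite.
space: questionnaire
seed: 14
design:
  groups: [control]
  conditions: [real, fake, void]
  n_participants_per_group: 18
mcmc: {n_chains: 3, burn_in: 200, n_samples: 800}
pilot: {n_chains: 1, burn_in: 150, n_samples: 300}
out: scratch/questionnaire_report.json
summary: scratch/questionnaire_summary.txt
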