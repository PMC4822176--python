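# ppscct

Analysis toolkit for crossmodal congruency task (CCT) experiments:
synthetic data generation, voice-onset reaction-time extraction,
crossmodal congruency effect (CCE) preprocessing, hierarchical Bayesian
hypothesis models, and Bayesian model comparison via a from-scratch
transdimensional product-space (Carlin–Chib) MCMC sampler.

In a CCT, participants report the elevation (high/low) of tactile
stimuli while ignoring visual distractors placed ipsilaterally or
contralaterally to the stimulated hand, at congruent or incongruent
elevations. The CCE is mean RT(incongruent) − mean RT(congruent); a
peripersonal-space (PPS) representation is inferred when the
ipsilateral CCE exceeds the contralateral CCE. The package compares
hypothesis spaces over which conditions/groups carry that
ipsi-minus-contra effect, reporting posterior model probabilities as
index visit proportions with Monte-Carlo standard errors.

## Modules

| module | contents |
|---|---|
| `ppscct.synthgen` | factorial trial tables (162 trials/condition by default: 9 × 16 visuo-tactile combinations + 9 control-light + 9 false-stimulation), 1–10 Likert questionnaire tables, 8 kHz voice-response WAV with ground-truth onsets |
| `ppscct.rt_audio` | frame-based relative-energy voice-onset detector |
| `ppscct.preprocess` | trial scoring (TAH/TOH/LUCI/NIENTE), ≤44 % accuracy exclusion, per-participant CCE and ipsi−contra difference tables |
| `ppscct.bayes_models` | hierarchical Gaussian models (conjugate Gibbs) and cumulative-logit Likert models (MH-within-Gibbs), exact marginalized log-likelihoods, analytic normal–normal marginal oracle |
| `ppscct.product_space` | pseudo-prior fitting, the product-space sampler, Savage–Dickey Bayes factors, batch-means MC standard errors |
| `ppscct.pipeline` / `ppscct.cli` | hypothesis-space builders (8 / 4 / 4 / 22 models), YAML-driven end-to-end runs, JSON reports |

## CLI

```sh
# synthetic data
pps synth trials --config examples/exp1.yaml --seed 7 --out trials.csv
pps synth questionnaire --seed 7 --out answers.csv
pps synth audio --n 20 --seed 7 --out-dir wavs/

# RT extraction and preprocessing
pps rtaudio extract --in wavs/ --out rts.csv
pps preprocess --trials trials.csv --out cce.csv --report exclusions.json

# hypothesis spaces and full analyses
pps hypotheses --space exp1 --list
pps run --config examples/exp1.yaml
```

(`synth` and `rtaudio` are also installed as standalone commands.)

Example configs under `examples/` reproduce the three experiment
layouts and the questionnaire analysis on synthetic data; reports are
byte-identical given the same config and seed.

## Notes on modelling choices

- Effect-size priors default to null ≈ N(0, 5²) ms and active ≈
  N(40, 20²) ms on the CCE-difference scale; Likert cell priors to
  low ≈ N(−4, 2²) and high ≈ N(4, 2²) on the log-odds scale. All are
  configurable per run and echoed in every report.
- Pseudo-priors are moment-matched normals from single-model pilot
  runs. Correctness does not depend on their exact values — the test
  suite verifies that posterior model probabilities are invariant
  (within Monte-Carlo error) to deliberately widened pseudo-priors.
- The questionnaire hypothesis grammar (all-low, plus every non-empty
  condition subset × {both times, before only, after only} = 22 models
  for three conditions) is an explicit reconstruction and configurable.
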