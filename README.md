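# ponzopupil

Trial-level pupillometry pipeline for size-illusion (Ponzo / Emmert's-law)
experiments: it builds the experimental design, scores the AQ
(Autism-Spectrum Quotient) questionnaire, generates fully synthetic eye-tracker
sessions with ground truth, cleans 500 Hz pupil traces, and runs the
inferential battery — random-intercept mixed models, Pearson/partial
correlations with base-10 log JZS Bayes factors (lgBF), median-split and
control analyses.

## What it implements

- **Design & AQ** (`ponzopupil.design`): balanced 5-size x 2-location x
  10-repetition trial lists in two blocks of 50; figurine heights as
  ±20 %/±10 %/0 % of a 7.8° base; binary AQ scoring (0–50, clinical flag at
  32) against an externally supplied scoring key.
- **Synthetic sessions** (`ponzopupil.simulate`): 500 Hz pupil traces whose
  constriction amplitude follows a saturating function of *perceived* stimulus
  area; far stimuli are perceptually inflated by a context gain that decays
  with AQ; blink/signal-loss/spike artifacts with exact ground-truth indices;
  gaze offsets tied to location and size; magnitude-estimation reports.
  `simulate_summary_dataset` is a fast, trace-free marginal of the same model
  for large sweeps (equivalence with the trace path is asserted in the tests).
- **Preprocessing** (`ponzopupil.preprocess`): first-trial-per-block
  exclusion; gross filter (pupil < 0.1 mm or > 1 mm from the trial median);
  velocity filter (> 2.5 mm/s, ±10 ms excision); 10 Hz down-sampling into
  half-open 100 ms bins (empty bin = NaN, never zero); 200 ms baseline
  subtraction; 40 %-missing validity gate; pixel-to-degree gaze conversion.
- **Statistics** (`ponzopupil.stats`): random-intercept LMM via profiled REML
  with marginal (Type-III-style) F tests and residual denominator df —
  collapses exactly onto classical ANOVA when the intercept variance hits the
  zero boundary; JZS Bayes factors by stable log-space quadrature
  (correlations: unit prior scale; t tests: Cauchy scale 0.707); partial
  correlations; far-minus-near context effects; median split (ties to the low
  group); gender and gaze/baseline controls; leave-one-out robustness.
- **CLI** (`ponzopupil.cli`): `simulate`, `validate`, `preprocess`,
  `analyze`, `report` subcommands over TSV/CSV formats with a YAML config
  and per-run threshold echoing.

## CLI quick start

```bash
# write a synthetic dataset (samples.tsv, trials.csv, participants.csv,
# ground_truth.csv) for 10 participants
ponzopupil simulate --participants 10 --seed 1 --out data/

# check formats without touching the data
ponzopupil validate --data data/

# cleaning only (trial_summaries.csv + exclusions.csv);
# --median-dev-max 2.0 reruns the gross-filter robustness check
ponzopupil preprocess --data data/ --out prep/

# full analysis: preprocessing + inference bundle (report.json,
# cell_means.csv, context_effects.csv, exclusions.csv)
ponzopupil analyze --data data/ --out results/
ponzopupil report --report results/report.json
```

All thresholds and simulation knobs can live in a YAML config
(`--config run.yaml` with `simulation:`, `preprocessing:`, `statistics:`
sections); command-line flags override config keys.

## Layout

```
src/ponzopupil/    design.py simulate.py preprocess.py stats.py io.py cli.py
tests/             unit + property tests, test_acceptance.py (criteria 1-6)
scripts/           acceptance.py
```
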