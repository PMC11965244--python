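# flankerlab

Design generation, simulation, and distributional analysis for flanker-task
experiments with time-varying stimuli. The package builds balanced trial
schedules for three experiment families (target–flanker onset asynchrony,
mid-trial contrast change, and stimulus-location uncertainty), simulates
trial-level responses with controllable congruency effects, and runs the
full behavioral analysis chain:

- **design** — balanced, seeded trial schedules (8×108 SOA blocks, 12×80
  contrast-change blocks, 12×80 alternating fixed/variable location blocks
  with ABBA/BAAB counterbalancing), practice blocks, stimulus geometry
  helpers.
- **simulate** — ex-Gaussian base response times with quantile-coupled
  interference: the incongruent RT is `Q(u) + delta0 + delta1·(u − 0.5)`,
  so the median congruency effect (`delta0`) and the delta-plot slope sign
  (`delta1`) are directly controllable; per-cell error probabilities,
  premature/timeout responses, and location carry-over increments.
- **preprocess** — response classification (the RT < 200 ms rule, premature
  responses, timeouts), and carry-over labeling (first-trial exclusion,
  same/different-location sequence conditions).
- **fce** — per subject × condition summaries (mean error rate, median
  correct RT), flanker congruency effects (incongruent − congruent),
  within-subject standard errors (subject-centering with bias correction),
  and the composite block feedback score with optional accuracy/speed
  re-weighting.
- **deltaplot** — nine-decile delta plots, per-subject slope regression,
  group slope tests with Benjamini–Hochberg adjustment, group curves, and
  orthogonal polynomial (linear/quadratic) trend contrasts.
- **rmstats** — two-way within-subject ANOVA with Greenhouse–Geisser
  adjustment, simple effects and pairwise comparisons, the
  congruency-specific carry-over contrast with CI, and noncentral-t /
  noncentral-F power computations.
- **io / pipeline / cli** — validated trial-table CSV schema, JSON
  configuration, and a deterministic end-to-end driver.

## CLI

```sh
# simulate a trial table
flankerlab simulate --experiment EXP1 --n-subjects 40 --seed 1 --out trials.csv

# analyze an existing table
flankerlab analyze --experiment EXP1 --trials trials.csv --out results.json

# simulate + analyze + write the full results bundle
flankerlab all --experiment EXP3 --n-subjects 22 --seed 1 --outdir bundle/

# readable summary of a bundle
flankerlab report --results bundle/results.json
```

All commands accept `--config cfg.json` (a serialized `PipelineConfig`);
explicit flags override config keys. The results bundle contains the trial
table, tidy summary/FCE/delta-plot/ANOVA CSVs, block scores, a run log with
the config digest, and a machine-readable `results.json` that is
byte-identical across reruns of the same config.

## Library example

```python
from flankerlab import design, simulate, preprocess, fce

specs = design.build_exp1(seed=1)
params = simulate.preset_canonical("EXP1", seed=1)
table = simulate.simulate_experiment(specs, n_subjects=40, params=params)
table = preprocess.classify_trials(table)
summaries = fce.summarize_conditions(table)
effects = fce.compute_fce(summaries)
```

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact design
counts, printed-arithmetic checks, analytic power bounds, and
oracle-verified property suites (OLS/t/BH/GG against brute force, ANOVA
sum-of-squares conservation and the F = t² identity, simulator parameter
recovery, composite-score closed forms).

## Notes

- The simulator's quantile-coupled interference is a device for producing
  targeted distributional signatures, not a mechanistic process claim.
- The weighted composite score uses the convex combination
  `100·(w_acc·(accuracy − 0.5)/0.5 + w_speed·speed)`, clipped to [0, 100];
  weights default to 80/20 for the contrast-change designs and 75/25 for
  the location design.
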