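# timeavg

Simulation and analysis pipeline for ensemble averaging of time
intervals. The package answers a simple question about a comparison
experiment: when observers judge whether a probe interval is longer or
shorter than the *average* of five preceding intervals, which averaging
scheme — arithmetic, geometric, duration-weighted, or harmonic — best
explains their points of subjective equality (PSEs)?

It provides:

- **`timeavg.models`** — the four averaging schemes, their noisy
  generative versions under scalar timing noise (linear-scale Weber
  noise or log-scale noise with a multiplicative bias), and
  Monte-Carlo/closed-form PSE predictions per interval set. The three
  built-in stimulus sets (`SET1`, `SET2`, `SET3`) share either their
  arithmetic or their geometric means by construction.
- **`timeavg.adaptive`** — an updated-maximum-likelihood (UML) adaptive
  procedure: a grid posterior over the threshold, slope and lapse of a
  logistic psychometric function, updated after every response, with
  stimulus placement that minimizes the expected posterior variance of
  the threshold.
- **`timeavg.simulate`** — synthetic observers and full sessions:
  three concurrently tracked adaptive staircases (80 trials per set,
  randomly interleaved, initial comparison 500 ms), per-trial random
  permutation of the presented intervals, cohort generation with
  ground-truth sidecars.
- **`timeavg.fitting`** — offline maximum-likelihood psychometric
  fitting (logistic, logistic + lapse, and gamma- or logistic-based
  mixtures with a non-temporal response component), PSE/JND extraction
  (JND = 75% point − 50% point, `ln 3 / beta` for the logistic), and
  AIC-based variant comparison.
- **`timeavg.comparison`** — averaging-model fits to observed PSEs
  (closed-form bias fits; grid search for the noisy harmonic model),
  observer classification in the (PSE1−PSE2, PSE1−PSE3) difference
  plane by perpendicular-bisector side, and the end-to-end
  `run_full_analysis` report.

## Command line

```bash
# analytic means of the three built-in sets + qualitative model patterns
timeavg reproduce-predictions

# simulate a 16-observer cohort (70% geometric / 30% arithmetic)
timeavg simulate -n 16 --scheme geometric=0.7 --scheme arithmetic=0.3 \
    --seed 1 --out trials.csv --truth-out truth.csv

# psychometric fits per observer and set
timeavg fit trials.csv --out fits.csv

# full analysis: PSE table, model SSEs, classification, JSON report
timeavg compare trials.csv --out report.json
```

`simulate` also accepts a YAML config with `scheme_mix` and
`param_ranges` entries (see `timeavg.simulate.CohortRanges` for the
range fields).

## Report schema

`timeavg compare` / `run_full_analysis` emit a JSON object with keys
`pse_table` (per observer × set PSE/JND), `grand_means`,
`set_statistics` (analytic means per scheme), `ideal_points`,
`model_fits` (per-scheme predicted PSEs, fitted bias, SSE),
`best_model`, `classification` and `classification_counts`.
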