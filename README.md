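# ema-rt

Analysis pipeline for treating the response times (RTs) of noncognitive
ecological momentary assessment (EMA) survey items as ambulatory indicators of
cognitive processing speed. Implements:

- **datamodel** — a tidy long-table CSV format for per-item/per-trial RTs from
  three measures (EMA items, Symbol Search trials, Go–No Go trials), plus the
  default 22-item EMA catalog (16 slider, 3 multiple-choice, 3 checkbox) and
  named item-set selectors (`slider16`, `pa4`, `na4`, `activity3`, `stress3`,
  `mc3`, `check3`, `all22`).
- **preprocess** — validity filters (EMA RTs outside 0.2–30 s; Symbol Search
  trials outside 0.2–5 s or in sessions below 70% accuracy), exclusion
  accounting, natural-log transform, and session scoring (accuracy, mean log
  RT of accurate trials, median RT, signal-detection d′ with the 1/(2N)
  zero/one-rate correction).
- **varcomp** — exact maximum-likelihood variance components for 2-level
  (occasions in persons) and 3-level (items in occasions in persons)
  random-intercept models on unbalanced data, plus a balanced-design nested
  ANOVA moment oracle.
- **reliability** — between-person ICC, Spearman–Brown projections of
  between-person reliability over occasions and within-person reliability over
  items, the exact algebraic inverse, threshold search, and reliability
  curves.
- **latent_corr** — bivariate multilevel correlations between two measures:
  the between-person correlation among person intercepts and the
  within-person correlation among occasion deviations, in the unreliability-
  corrected 3-level form and the manifest occasion-mean 2-level form, plus
  correlations of the latent person intercept with person-level covariates.
- **cosinor** — one-harmonic (24 h) multilevel cosinor model of the diurnal RT
  cycle, with standardized amplitude, acrophase, and the peak-to-trough daily
  fluctuation (twice the amplitude).
- **synthgen** — a seeded generator of study-shaped synthetic data
  (198 persons × 14 days × 5–6 prompts/day by default; lognormal RTs with
  person/occasion/item components, cross-measure correlations, a diurnal
  cosine, fatigue coupling, careless ultrafast responses, interruption
  outliers, and MCAR missingness) together with the ground-truth parameters.

## Command-line use

```sh
# generate a synthetic study (records.csv, covariates.csv, truth.csv)
ema-rt simulate --seed 42 --out out/sim

# apply validity filters, write exclusion summary and session scores
ema-rt preprocess --in out/sim/records.csv --out out/pre

# variance components, ICCs, Spearman-Brown projections, reliability curves
ema-rt reliability --in out/pre/records_filtered.csv --item-set slider16 --out out/rel

# latent between-/within-person correlations with Symbol Search, fatigue,
# Go-No Go d', and person covariates
ema-rt correlate --in out/pre/records_filtered.csv \
    --covariates out/sim/covariates.csv --item-set slider16 --out out/corr

# diurnal cosinor fit (summary + predicted curve CSV + SVG)
ema-rt cosinor --in out/pre/records_filtered.csv --measure ema --out out/cos

# everything end to end, assembled into one markdown report
ema-rt report --in out/sim --out out/report
```

Generator settings can be given as YAML (`ema-rt simulate --config cfg.yaml`);
`SynthConfig.to_yaml`/`from_yaml` round-trip the full specification, and
`--seed` makes every run byte-reproducible.

## Library example

```python
import numpy as np
from ema_rt import (SynthConfig, generate_study, filter_ema_rts,
                    fit_varcomp3, icc_bp, bp_reliability_at)

study = generate_study(SynthConfig(n_persons=50, n_days=7, seed=0))
ema = filter_ema_rts(study.records)
ema = ema[(ema["measure"] == "EMA") & ema["valid"]]
vc = fit_varcomp3(ema["person_id"], ema["occasion_id"],
                  np.log(ema["rt_seconds"]))
print(vc.var_person, vc.var_occasion, vc.var_item)
```
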