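# panelmmc

Multimarker serum-biomarker panel analysis at fixed specificity, for
early-detection studies built on prospective cohorts with prediagnostic
blood draws.

The package is aimed at biostatisticians working with nested case-control
serum collections — incident cancer cases matched to controls on age, sex,
race and draw date, with a multiplexed panel of protein concentrations
measured on every sample.  It implements the complete analysis workflow
for such a study:

* **Univariate screening** — Mann–Whitney U per marker,
  Benjamini–Hochberg step-up FDR control over the panel, rank-formula
  AUC, and the concentration cut-point and sensitivity at a target
  specificity.
* **Multimarker panel optimization** — the core method.  A panel's
  scoring function is a linear combination of log concentrations,
  `SF(c) = Σᵢ wᵢ ln cᵢ`, calling a case when `SF ≥ t` with `t` calibrated
  so specificity stays at or above a preset level (default 95%).  The
  weights are assigned by a Metropolis algorithm maximizing
  cross-validated sensitivity at that specificity; all 2/3/4-marker
  combinations are enumerated exhaustively and ranked.
* **Correlated-performance statistics** — McNemar's χ² = (b−c)²/(b+c)
  for paired sensitivities, the Hanley–McNeil z-ratio for correlated AUC
  differences, and Pearson correlation of each marker with an anchor
  marker (e.g. CA 19-9) in cases.
* **Biomarker velocity** — OLS regression of marker level on days to
  diagnosis, overall and restricted to samples drawn >12 months before
  diagnosis.
* **Duplicate-sample QC** — per-marker coefficient-of-variation
  summaries over blinded duplicate pairs and diagnosis-consistency
  checks.
* **A five-step blinded protocol** — train on a retrospective set,
  validate blind on one half of the prospective cohort, unblind and
  retrain, validate blind on the other half, train on everything — with
  a structural blinding firewall and per-stratum (months-to-diagnosis)
  reporting.
* **A synthetic cohort generator** with recorded ground truth (matched
  log-normal markers, case shifts, velocity slopes, anchor correlation,
  embedded duplicates), so the whole pipeline is testable without any
  data download.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from panelmmc import (
    GeneratorConfig, generate_cohort, screen_markers,
    PanelModel, MetropolisConfig,
)

cohort, truth = generate_cohort(GeneratorConfig(seed=42))
print(screen_markers(cohort).summary())
```

```
Univariate marker screen (67 markers, BH q=0.05, m=67, SP target 95.0%)
Significant markers: 4 (realized p threshold 0.001293)
marker                 p     AUC   dir   cut-point     SN%     SP%
CA 19-9         2.66e-09   0.665    up       325.6    19.3    95.0
bHCG            4.45e-05   0.613    up      0.8955     8.9    95.0
IL-8            0.000206   0.603    up       20.74    11.1    95.0
CA 125           0.00129   0.589    up       242.5    11.9    95.0
```

The screen reports, per marker, the two-sided Mann–Whitney p-value, the
ROC area, the direction of the case shift, and the concentration
cut-point at which a sample would be called a case at 95% specificity
together with the sensitivity that cut-point achieves — here CA 19-9
catches 19.3% of cases 1–35 months before diagnosis while keeping 95% of
controls negative, values typical of the prediagnostic setting.

Fitting a two-marker scoring function:

```python
model = PanelModel(cohort, ("CA 19-9", "CEA"))
result = model.fit(MetropolisConfig(n_iterations=400, n_cv=100, seed=0))
print(result.summary())
```

```
Scoring-function fit (Metropolis/Monte-Carlo)
Panel: CA 19-9/CEA
SP target: 95.0%   threshold: 17.4587
Coefficients:
  CA 19-9        +1.0531
  CEA            +1.0000
Training SN at threshold: 14.8% (achieved SP 95.0%)
Full-data AUC: 0.606
Cross-validated SN: mean 14.8% (sd 4.2%, 100 replicates)
```

`result.predict(blinded_cohort)` scores new (possibly blinded) samples;
`result.plot_roc()` draws the empirical ROC.  Exhaustive panel discovery
(`search_panels`), the blinded five-step protocol (`run_protocol`),
velocity screens (`VelocityModel`) and duplicate QC (`duplicate_report`)
follow the same pattern; each returns an object with `summary()`,
`to_frame()` and CSV export.

## Command line

```bash
panelmmc simulate -o cohort.csv --seed 1 --groups groups.csv
panelmmc screen   -i cohort.csv -o table5.csv
panelmmc optimize -i cohort.csv -o panels.json --sizes 2,3
panelmmc velocity -i cohort.csv -o velocity.csv --log
panelmmc qc       -i cohort.csv -o qc.csv
panelmmc protocol --train retro.csv -i cohort.csv --groups groups.csv -o out/
```

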