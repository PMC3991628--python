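# Methods

## The problem

Prediagnostic serum collections from prospective screening trials make it
possible to ask whether a circulating biomarker — or a small panel of them
— could have flagged a cancer months to years before clinical diagnosis.
The statistical workflow this package implements is built around a nested
case-control design: incident cases of pancreatic ductal adenocarcinoma
with serum drawn 1–35 months before diagnosis, each matched to four
controls on age (±5 years), sex, race and blood-draw date (2-month
calendar blocks), with a 67-plex panel of serum protein concentrations
(pg/ml) measured on every sample.

## The scoring-function model

A panel of markers \(m_1,\dots,m_k\) is turned into a classifier by the
log-linear scoring function

\[ SF(c) = \sum_{i=1}^{k} w_i \,\ln c_{m_i}, \]

with a sample called a case when \(SF \ge t\).  The threshold \(t\) is not
a free parameter: it is calibrated on control scores so that specificity
is at least a preset target (default 95%, the regime relevant to cancer
screening), using the smallest threshold satisfying
\(\#\{s_{ctrl} \ge t\}/n_{ctrl} \le 1-SP/100\).  Ties among control scores
push the threshold upward (specificity-protective); when no finite
threshold qualifies, the threshold is placed just above the largest
control score (SP = 100%).

The weights \(w_i\) are assigned by a Metropolis algorithm with
Monte-Carlo objective evaluation:

* objective: mean test-set sensitivity over a fixed set of Monte-Carlo
  stratified train/test splits (default 16 splits at 2:1), with the
  threshold recalibrated on each split's training controls so specificity
  is enforced without leakage;
* proposal: one coefficient at a time perturbed by N(0, `proposal_sd`),
  default 0.25, starting from unit weights;
* acceptance: always when the objective improves, otherwise with
  Boltzmann probability exp(Δ/T); the temperature starts at 1.0 and
  decays geometrically by 0.995 per iteration (default 2000 iterations);
* the best-seen state is retained, so the incumbent objective is monotone
  and the returned coefficients are the best ever visited.

Two cross-validation knobs are deliberately separate.  The Metropolis
*objective* is evaluated on a small, fixed split set (`n_splits_objective`)
— fixed both for speed and as common random numbers, so that during an
exhaustive panel search every candidate panel faces exactly the same
splits and ranking differences are paired rather than noise-dominated.
The *reported* cross-validation of selected panels (`n_cv`, default 500
repeated random stratified subsampling splits at 2:1 train:test) is run
afterwards on the panels that survive ranking.  `cross_validate` with
`refit=True` refits weights inside every split (the fully honest but
expensive variant); `refit=False` keeps weights fixed and recalibrates
only the threshold per split, which is what the search uses for ranking
diagnostics.

Panel discovery enumerates every combination of 2, 3 or 4 markers
(larger panels are excluded to limit overfitting), fits each panel's SF,
and ranks by cross-validated sensitivity at the target specificity.

### A calibration property worth knowing

For a *fixed* scoring function, exchangeability of null cases and
controls makes cross-validated sensitivity equal the false-call rate,
about 5% at 95% specificity.  When weights are *refit* in every split, the
optimizer exploits the finite sample's chance separation between the case
and control clouds, and null sensitivity sits above that floor (about 10%
at n = 50/200, shrinking with cohort size).  This optimism is inherent to
optimized classifiers evaluated on a fixed cohort; the blinded-half
validation steps of the protocol exist precisely because of it.

## Univariate screen

Each marker is tested case vs. control with the Mann–Whitney U test
(U counts case-over-control wins, ties ½; p exact by enumeration when
n₁·n₂ ≤ 64, otherwise tie-corrected normal approximation with continuity
correction).  The false discovery rate over the 67 comparisons is
controlled by the Benjamini–Hochberg step-up rule: ranked p-values are
compared to i·q/m and every rank up to the largest i with p(i) ≤ i·q/m is
flagged.  The realized p threshold (the largest flagged p-value) is
reported rather than hard-coded.  AUC is the rank statistic U/(n₁·n₂),
identical to trapezoidal integration of the empirical ROC.  The
per-marker cut-point at a target specificity is the smallest observed
concentration (largest, for markers depressed in cases) whose exceedance
among controls is within the allowed fraction; both the nominal target
and the achieved specificity are reported, because on finite control sets
the achieved value is generally higher.

## Classifier and marker comparison

* **McNemar** for paired sensitivities: χ² = (b−c)²/(b+c) over discordant
  case calls, no continuity correction, significant above 3.841 (the 5%
  point of χ²₁).  b + c = 0 is defined as χ² = 0.
* **Hanley–McNeil** for correlated AUCs: SE² = [A(1−A) +
  (n₁−1)(Q₁−A²) + (n₀−1)(Q₂−A²)]/(n₁n₀) with Q₁ = A/(2−A),
  Q₂ = 2A²/(1+A); z = (A_a−A_b)/√(SE_a²+SE_b²−2r·SE_a·SE_b), significant
  at |z| ≥ 2.  The correlation r is estimated as the mean of the Pearson
  correlations of the two score sets within cases and within controls and
  used directly (the original table-lookup maps this quantity through the
  average AUC nearly linearly; the convention is a documented parameter
  of this implementation, not a claim about any other).
* **Anchor correlation**: Pearson r (and r², p from the t transform with
  n−2 df) of each marker against a designated anchor marker, computed in
  cases only; raw concentrations by default with a log-scale option,
  since the appropriate scale is a modelling choice.

## Velocity

Marker levels in cases are regressed on days to diagnosis by OLS; the
slope p-value is two-sided from the t statistic with n−2 df.  Because the
regressor is time *until* diagnosis, markers rising as diagnosis
approaches have negative slopes.  The screen runs on the complete case
set and on the stratum of samples drawn more than 12 months before
diagnosis; markers significant only in the far stratum are reported
separately (early trends masked by near-diagnosis heterogeneity).  No
multiplicity correction is applied in this screen, and reports say so.
Raw and log-scale modes are both available; a constant response returns
slope 0 with p = 1.

MTD (months to diagnosis) is floor(days/30.44); the strata are
MTD 1–12 = days < 365, MTD 12–35 = 365 ≤ days < 1065.

## Duplicate QC

Reproducibility is measured on blinded duplicate pairs embedded in the
cohort: per pair and marker, CV = 100·s/m with m the pair mean and
s = |x₁−x₂|/√2 (the sample SD of two observations — the pair-SD
convention, chosen because duplicates come in pairs).  The report gives
the per-marker CV range and mean, and, given a fitted scoring function,
whether both members of every pair receive the same diagnosis.

## The five-step blinded protocol

1. Train candidate panels on an external retrospective case/control set
   (diagnosis-time effect sizes, 343 cases / 227 controls by default).
2. Apply the resulting scoring functions to the first, blinded half of
   the prospective cohort; submit diagnoses; adjudicate against the key.
3. Unblind that half and retrain over the full marker registry.
4. Validate the retrained classifiers on the second, still-blinded half.
5. Unblind everything and train on the entire prospective set.

Halves are split by match group, so controls never separate from their
case; duplicates travel with their source.  The blinding firewall is
structural: a blinded cohort carries no status, days-to-diagnosis or
survival category, and every label-dependent operation raises on it; only
`adjudicate`, which receives the key explicitly, can score blinded
submissions.  Performance is reported per MTD stratum as SN/SP/AUC.
A single-marker reference classifier (the anchor marker at unit weight,
threshold calibrated to the same specificity) is carried through every
step for McNemar / Hanley–McNeil head-to-head comparison.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with recorded
ground truth for parameter-recovery testing.  For subject i and marker j,

    log c_ij = mu_j + case_i * (delta_j + beta_j (t_i - t_bar))
               + sigma_j (rho_j z_i + sqrt(1 - rho_j^2) eps_ij)

— a log-normal marker model (serum marker concentrations span orders of
magnitude and the scoring function works in logs), with case log-shift
delta_j, velocity slope beta_j in log-units per day of time-to-diagnosis
(centred mid-window, so velocity does not move the case mean), and
correlation to a single anchor marker's latent factor z_i.  Days to
diagnosis are uniform on [30, 1065).  Duplicates are re-measurements with
multiplicative noise exp(N(0, s_j)), s_j = √π·CV_j/100 so the expected
pair CV equals a per-marker target drawn from the configured assay range
(default 1.0–7.8%).

Default preset (the study conditions, fixed once): 67 markers; eight
carry case shifts (seven up, prolactin down) with control log-means and
log-SDs set from published healthy-serum levels and shifts d·σ chosen to
reproduce modest prediagnostic AUCs in the 0.52–0.66 range
(d = √2·Φ⁻¹(AUC)); CEA and CA 125 correlate with the CA 19-9 anchor at
r = 0.83 and 0.73; six markers carry velocity slopes −0.0016·σ per day
(a 2–5-fold drift across the 35-month window, detectable at t ≈ 5.6 with
135 cases).  Additional presets: `null` (everything zero, for type-I
calibration), `planted_pair` (two informative markers of 67 at 1.2σ and
1.0σ, for recovery experiments), `retrospective` (unmatched 343/227 with
diagnosis-time effect sizes, for protocol Step 1).

What the generator does **not** emulate: full 67×67 correlation
structure (only single-anchor correlation), assay batch/plate effects,
non-lognormal tails, informative matching failure, or covariate effects
on marker levels (age/sex/race/smoking are carried as matching
covariates only).  Passing tests therefore demonstrate the statistical
machinery is correct and well calibrated under these idealised
conditions; they do not certify performance numbers on real sera.

## Numerical and design choices

* Concentrations ≤ 0 (or below a configurable limit of detection) are
  floored to LOD/2, LOD defaulting to the smallest positive observed
  value per marker, so logarithms are always defined.
* Natural logarithms throughout.
* Cut-point tie-break: among values satisfying the specificity
  constraint, the one maximizing sensitivity is chosen.
* The fast vectorised threshold used inside the Metropolis loop assumes
  tie-free (continuous) scores; the canonical `calibrate_threshold`
  handles ties exactly and supplies every returned threshold.
* Duplicate rows are excluded from all statistics and fitting; they
  exist solely for QC.
* Blind/unblind is an exact inverse: the key table carries status,
  days-to-diagnosis and survival category.
* Cohort half-splitting is by match group (preserves matching); the
  split fraction is configurable (0.5 default; the historical study's
  halves were 56/79 cases).

## Problem sizes used in the shipped tests and acceptance script

The full-scale production run — 67 markers, all 2/3/4-marker panels, 2000
Metropolis iterations and 500-replicate cross-validation per panel — is a
documented long-running job.  The shipped test suite and
`scripts/acceptance.py` exercise the identical code paths at reduced
scale, chosen as the package's own verification budget: exhaustive
C(67,2) = 2211 two-marker searches at 100 Metropolis iterations with 8
objective splits and 50-replicate CV of the winners; recovery experiments
over 20 seeds at the design size n = 135/540; calibration experiments
over 50 seeds.

## Known limitations

* The Metropolis schedule, proposal width and split geometry are
  conventions of this implementation; published descriptions of this
  family of optimizers leave them unspecified, and results at fixed seed
  depend on them.
* Sensitivities at 95% specificity on 135 cases have wide binomial
  error (±4 points); single-seed numbers from the acceptance script
  should be read accordingly.
* The Hanley–McNeil r convention (averaged within-class score
  correlation, no table lookup) can differ from table-based values by a
  few percent of z in extreme-AUC regimes.
* McNemar's χ² and the exact binomial sign test can disagree for
  marginal counts (documented divergence band around p = 0.05); the χ²
  form with the 3.841 cutoff is primary.
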