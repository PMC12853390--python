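# Methods

`hemaqc` implements a sigma-stratified, three-tier dynamic quality-control
(QC) framework for hematology analytes (Hb, WBC, RBC, HCT, PLT): Six Sigma
performance assessment decides *how much* QC an assay needs; an adaptive
moving-average (MA) monitor on patient results and an LSTM deviation
forecaster provide continuous early warning; Westgard multirules on control
materials provide confirmatory verification. This note records the models,
the defaults and their rationale, the numerical choices, and what the
synthetic studies do and do not demonstrate.

## Sigma assessment and matrix correction

For an analyte with total allowable error TEa (percent of target), bias
`Bias% = |lab mean − reference| / reference × 100` against the peer-group
reference value, and imprecision `CV% = SD/mean × 100` (sample SD, n−1,
over a stable period — standard laboratory practice for period statistics):

    σ = (TEa − Bias) / CV

Grades: σ ≥ 6 world-class (`high`), 3 ≤ σ < 6 acceptable (`moderate`),
σ < 3 high-risk (`low`); the bands are right-closed at 3 and 6 exactly.
Negative σ (bias exceeding TEa) is reported with grade `low` and a warning
flag rather than raised as an error — it is actionable QC information.

Because control materials can understate the variability of real
specimens, the patient-sample CV deflates sigma through the matrix
correction factor `F = CV_patient / CV_IQC` and `σ_adjusted = σ / F`.
When a patient CV is supplied, the adjusted sigma overrides the raw sigma
for tier assignment (the case that matters in practice is a borderline
analyte such as PLT being demoted below σ = 3).

**Reporting and rounding.** Values are carried at full precision
internally; reported values round to 2 decimals with IEEE
round-half-even (Python `round`). In the reporting path the corrected
sigma divides by the *rounded* factor — that is how published tables of
this kind are constructed (e.g. 4.65 / 1.07 = 4.35) — while `exact=True`
keeps the algebraic identity `σ/F = (TEa − Bias)/(CV·F)` to 1e−9, which
the property suite asserts.

TEa is stored as either percent-of-target or absolute units with an
explicit mode tag; PLT defaults to an absolute ±10 × 10⁹/L band while the
other analytes carry CLIA '88 percent limits.

## QC plans per tier

* `high` — QC once daily, single 1-2s rule (as the sole configured rule it
  is the only failure criterion and therefore rejects).
* `moderate` — QC per analytical batch, multirule {1-2s, R-4s}.
* `low` — QC every 4 h, dual rule, plus MA monitoring. The dual rule is
  not fixed by convention; this package defaults to {1-3s, 2-2s}
  (one-point gross error plus sustained same-side shift), configurable.

## Westgard engine

Rules operate on signed z-scores against the analyte target/SD. Semantics:
1-2s |z| > 2 (warning inside a cascade); 1-3s |z| > 3; 2-2s two
consecutive same-side beyond 2; 4-1s four consecutive same-side beyond 1;
10x ten consecutive same side of target; R-4s within one run, any pair of
points differing by more than 4 SD. R-4s is deliberately local and
within-run (cross-run application disabled): a violation is reported at
index *i* whenever an earlier same-run point differs from it by > 4, which
makes the engine exactly checkable against an exhaustive brute-force scan
(the acceptance suite runs that equivalence on random sequences).

## MA monitor

The monitor tracks the rolling mean of accepted patient results with
dynamic limits `target ± k·SD_limit`, k_alert = 1.5, k_ooc = 2.5. The
window starts at 100 consecutive samples and adapts each step: 50 when the
real-time CV (current buffer) exceeds the historical CV (trailing horizon,
default 1000 accepted samples, initialised from the calibration baseline),
150 when it does not. No status is emitted until the buffer first reaches
100 samples.

**What SD scales the limits.** This is the one genuinely open design
point, and both options are exposed:

* `sd_mode="ma"` (default): SD_limit is the sampling SD of the MA
  statistic, estimated from a stable baseline as sample-SD/√W and rescaled
  to the *current buffer length* at every step. Limits at ±1.5 SD on a
  100-sample mean then have real power against sub-SD shifts, and the
  false-alarm rate is invariant under window adaptation. (The empirical
  rolling-MA estimator is kept as `sd_mode="ma_empirical"`; it is
  downward-biased on short baselines because the windows overlap.)
* `sd_mode="population"`: limits use the raw analyte SD. On an averaged
  statistic these essentially never fire on stationary data, making the MA
  tier a slow confirmatory layer; this mode is what the lead-time study
  uses (below).

On a window shrink the most recent 50 values are kept; on expansion the
buffer regrows to 150. Escalation: three consecutive alert evaluations, or
one out-of-control breach, suspend testing for investigation. Preprocessing
removes flagged specimens (hemolysis/lipemia/clot) and gross outliers
beyond ±3 SD of the *fixed* analyte target — a rolling reference would let
a genuine shift mask itself.

**False-alarm calibration.** With default settings on stationary streams
whose generator CV equals the historical CV, the mean alert-state rate
across seeded replicates is pinned below 250 per 1000 evaluated samples
(the marginal rate of a ±1.5 SD band is ≈ 13%, and MA autocorrelation
makes per-stream counts cluster widely around it). The suite asserts that
bound.

## LSTM deviation forecaster

A single-layer LSTM (64 units, tanh cell activation, linear head) maps the
last 100 accepted, standardized patient values to the predicted
standardized mean deviation of the next 10 values from target. It is a
compact seeded numpy implementation — forward pass, full backpropagation
through time, Adam (lr 3e−3, gradient-norm clip 5), minibatch MAE loss —
so training is exactly reproducible from the seed.

Training protocol: pairs are split 8:2 (seeded shuffle) into train and
held-out validation; optional k-fold cross-validation (default 5) inside
the training portion reports per-fold MAEs for model selection; the final
model trains on the full training portion with early stopping on the
held-out MAE (default max 200 epochs, patience 10) and restores the best
weights. Inputs are raw accepted values, not MA values: averaging would
discard exactly the short-horizon trend the forecaster is meant to learn.

**Red alert.** With predicted deviation d (analyte units) and TEa in
units, an alert fires when |d| / TEa *strictly* exceeds 0.5 — an exact
50 %-of-TEa prediction does not alert.

## Orchestration and event semantics

`run_monitoring` merges time-ordered patient and QC streams (patient
before QC at equal timestamps). The QC plan gates the tiers. Events:

* `lstm_warning` (forecast every 10 accepted samples by default),
  `ma_alert`, `ma_ooc` on status transitions — all *alerting* events;
* `westgard_violation` on rule rejections — *out-of-control* events.

Confirmation is subsequent: an alerting event is upgraded to a dual
alerting/out-of-control record by the first qualifying Westgard violation
at or after its trigger within the episode horizon (default 24 h).
Verification counts any enabled-rule violation including a 1-2s warning
(configurable to rejections only). In simulation mode a `qc_callback`
draws an immediate verification run at each trigger and, while an episode
remains unresolved, every 20 accepted samples (≈ hourly at the default
sampling rate) — repeat controls during investigation. Lead times are
per-episode differences in hours: first LSTM warning → first MA trigger,
and first MA trigger → first confirmation; episodes without a downstream
event are excluded and counted.

Actions (`recalibration`, `suspend_testing`, …) are recorded labels only;
there are no instrument side effects.

## Synthetic streams

The simulator emulates stationary analyte streams with configurable CV —
normal for Hb/RBC/HCT, log-normal (moment-matched) for the count-type
WBC/PLT — plus injectable step shifts (multiples of SD), linear drifts
(units/sample), CV inflation, gross outliers beyond 3 SD, and
pre-analytical flags, with per-sample ground-truth labels. Defaults chosen
once as the study conditions: PLT target 250 × 10⁹/L, baseline CV 2.8 %
(the internal-QC imprecision of a low-sigma analyte), 20 samples/hour so a
100-sample window spans ~5 h and lead times read naturally in hours. QC
streams draw per-run level values around `target·(1 + bias/100)` and can
inherit the same instrument-level error offsets as the linked patient
stream.

The canonical drift scenario is 800 PLT samples with a +0.15 × 10⁹/L per
sample drift from sample 400 (≈ 0.021 SD/sample, reaching 8.6 SD).
Forecaster training material mixes stationary stretches with up- and
down-drifts of varied slope. The lead-time study runs the MA tier with
`sd_mode="population"`: under MA-statistic limits the MA out-of-control
threshold (≈ 1.75 units) sits far below the LSTM's 50 %-of-TEa threshold
(5 units), so the tight-limit MA would always fire first and the three-tier
ordering (forecast → monitor → verify) is the population-limit regime.
Under those conditions the first red alert precedes the first MA breach in
20/20 seeded replicates with a mean lead of several hours.

**Problem sizes.** The test and acceptance studies use desk-scale sizes
chosen as the package's own defaults: 1000 random streams for the MA
oracle equivalence, 400 random sequences for the Westgard oracle, 25
replicates × 4 shift magnitudes for detection monotonicity, 20 replicates
of the canonical drift for the lead property, 5000 supervised windows for
the at-scale training run, and a 10 000-sample stream with a 1.0 SD step
for the end-to-end smoke.

## Limitations

* The simulator draws i.i.d. values around the target: no diurnal
  case-mix structure, ward/outpatient composition drift, or inter-analyte
  correlation. Passing tests demonstrate the machinery — detection
  ordering, false-alarm control, event bookkeeping — not performance on
  real hospital streams, where patient-mix variation is the dominant
  nuisance for MA-based QC and forecaster retraining on local data is
  required.
* Sensitivity/PPV figures from verification tables use the audit
  convention (confirmed/alerts); they are not confusion-matrix estimates
  of error detection against ground truth (a standard mode is provided
  separately).
* Westgard verification in simulation treats each drawn run as
  instantaneous; reagent-lot investigation, calibration downtime and
  operator response times are outside scope.
* Kappa confidence intervals are asymptotic; no bootstrap.
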