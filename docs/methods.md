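# Methods

`icurisk` develops an inherently interpretable prediction model for 3-day
ICU readmission (or death) after discharge to standard care, end to end:
cohort assembly from unit transfers, time-window featurization of routinely
collected ICU variables, an editable additive risk model fitted by cyclic
gradient boosting, importance-based greedy model-size reduction over
temporal splits, human-in-the-loop inspection/editing, and PR-AUC-first
evaluation. Because real patient-data-management-system extracts cannot be
shipped, the package includes a first-class synthetic cohort generator with
known ground truth; every stage is validated against it.

## The model

The classifier is a generalized additive model on the logit scale,

    logit p(y=1 | x) = β₀ + Σᵢ fᵢ(xᵢ) + Σ_{i<j} f_{ij}(xᵢ, xⱼ),

with each shape function ("risk function") a piecewise-constant lookup
table over quantile bins of one engineered feature (1D) or a small grid
over two features (2D). Fitting is cyclic gradient boosting: each round
visits every feature in fixed (column) order and adds a shrunken,
depth-limited regression-tree fit of the current log-loss gradient on that
feature's bins. Concretely, per feature and round the gradient `g = y − p`
and curvature `h = p(1−p)` are histogrammed over the bins; the finite bins
are greedily partitioned into at most `max_leaves` contiguous segments by
exact best-split search (no sampling — on a pre-binned axis the tree's
split search is exhaustive), and each segment receives a Newton step
`learning_rate · Σg / Σh`. The missing bin is always its own trainable
leaf, so missingness earns a log-odds level of its own (rendered as
"(unknown)") rather than being imputed away.

After fitting, every risk function is centred to mean zero under its
training histogram and the displaced mass is folded into β₀: bin scores
then read as log-odds contributions relative to the average training
patient, and the model is exactly additive — `contributions()` returns a
per-row table whose columns sum (with the intercept) to the logit,
bit-for-bit. This exact additivity is what makes editing well-defined:
deleting a risk function changes each prediction by precisely that row's
contribution from it.

2D risk functions are added on the residuals of the frozen 1D model. Each
candidate pair is pre-binned to at most `max_bins_2d` (default 4) quantile
bins per axis plus the missing bin, and the resulting grid cells are
boosted as categorical leaves — one Newton step per cell. With at most
four bins per axis a depth-limited tree can realise any cell partition, so
the per-cell update is the same estimator without tree bookkeeping.

Uncertainty bands per bin are the SD of the score across `n_bags`
bootstrap refits (multinomial weights), drawn as mean ± 1 SD. They are
descriptive, not inferential.

### Training parameters

| parameter | default | meaning |
|---|---|---|
| `max_bins_1d` | 200 | maximum quantile bins per 1D feature |
| `max_bins_2d` | 4 | maximum bins per axis of a 2D grid |
| `learning_rate` | 0.01 | shrinkage per tree |
| `max_leaves` | 3 | contiguous segments per tree |
| `boosting_rounds` | 5000 | maximum cycles over the features |
| `patience` | 50 | early-stopping patience (cycles) on internal validation log-loss |
| `validation_fraction` | 0.15 | internal validation share (0 disables early stopping) |
| `n_bags` | 8 | bootstrap refits for the confidence band |

"Bin size" is read as a *maximum bin count*; quantile cuts are collapsed
on duplicates, so low-cardinality features get fewer bins. Tests and the
acceptance script use smaller `boosting_rounds`/`max_bins_1d` than the
defaults — with Newton leaf steps the single-feature fit converges to the
empirical log-odds in tens of rounds, and coarser bins make shape-recovery
checks well-posed (equal-mass bins need ≥1% of the training mass for a
stable per-bin comparison).

## Cohort assembly

Transfers with `unit_type == ICU` are merged per patient into ICU stays
when the gap between consecutive transfers is at most `gap_threshold`
(default 1 h — enough to bridge administrative handovers without
swallowing true readmissions; configurable). Overlapping transfers are
rejected, not repaired. Exclusions are applied as a cascade with one
reason per stay, in fixed order: stays ending in death, discharge to an
external ICU/IMC, then stays lacking a full 3-day follow-up window before
the study end. Labelling is positive iff the earliest qualifying event —
admission to any ICU or IMC unit, or death — falls within 3 days of
discharge. The window is closed on the right (an event at exactly
discharge + 72 h counts); simultaneous events resolve ICU > IMC > death.
Planned-procedure readmissions are deliberately not special-cased.

## Featurization

Variables belong to five classes. Time-series variables get a *time
horizon* from their median within-stay sampling interval (≤ 2 h high,
≤ 12 h medium, else low; thresholds configurable — chosen so each lookback
window expects at least two samples). Each horizon fixes three lookback
windows ending at discharge (high: 4/12/24 h; medium: 12 h/24 h/3 d; low:
1/3/7 d), and each window yields median, IQR (linear-interpolation
quantiles), min, max, and OLS slope per day — 15 features per variable.
Flows yield a daily-rate extrapolation (window sum × 24 h / window length)
for 1/3/7-day windows; an empty window is zero flow, since absence of a
record means nothing was collected. Medications yield an administration
indicator and unique-drug count per 1/3/7-day window. Interventions yield
indicators for the 3- and 7-day windows plus, over the full history, the
interval in days since last performed and the last recorded value (never
performed stays missing and lands in the model's unknown bin). Statics
contribute their last value within a tagged interval (patient history /
hospital stay / ICU stay). One manually curated feature — days in hospital
before ICU admission — is derived from the transfer table. Windows are
half-open, right-closed at discharge, and featurization is causal: events
after discharge never influence a feature.

Missing values are propagated explicitly; no imputation anywhere.

## Selection, tuning, evaluation

Temporal splits respect calendar order. The two most recent years are
reserved — the earlier as validation, the latest as hold-out — and each of
the five temporal splits trains on an annually cut-back prefix of the
remaining years with its own seeded random 85/15 train/validation
partition (a year-based validation split would bias importance estimates
for variables only collected in some years). Split SDs are reported as
pseudo-confidence intervals; no distributional claim is made.

1D candidates are ranked by mean importance — mean absolute log-odds
contribution over a split's training rows — across the five temporal
splits (ties break lexicographically). For each size k up to the cap
(80 1D / 20 2D), the model is retrained from scratch with the top-k
candidates and scored by PR-AUC on the full validation split; the best k
wins, smallest on ties. Retraining (rather than freezing earlier
functions) avoids order-dependent residual bias; its cost is bounded by
caching the per-split binning. 2D candidates are all unordered pairs of
the selected 1D features, ranked the same way on residual fits.
Hyper-parameter tuning is exhaustive grid evaluation on the full split's
validation PR-AUC; the published three-step protocol (tune on all
features → approximate the top candidates by a single full fit and
importance cut → retune) is a composition of these operations.

PR-AUC is the primary metric (average-precision estimator — step-wise,
no linear interpolation, which is biased for PR curves; tied scores form
one threshold block). ROC-AUC is Mann–Whitney concordance with half
credit for ties. Precision at recall r is the maximum precision over
thresholds achieving recall ≥ r. The black-box comparator is a
histogram-based gradient-boosted tree ensemble (scikit-learn), optionally
grid-tuned on validation PR-AUC.

## Inspection and editing

Risk functions are rendered as step curves with confidence bands over
aligned training histograms, the missing bin as a separate "(unknown)"
level, and reviewed against a fixed four-problem taxonomy (disparity,
data artifact, contradicts medical knowledge, not interpretable). Every
function receives exactly one decision — include clean, include with
problems, exclude — with free-text justification, reviewer and timestamp;
the exclusion rule is judgment-based, so the ledger documents rather than
automates it. Exclusion is per whole function, never per bin. Removal is
non-destructive, leaves β₀ untouched (an optional flag refits the
intercept only), commutes, and is fully audited in the model's edit log,
which survives serialization.

## The synthetic cohort generator

The generator emulates the raw material of a single-centre retrospective
study with the study conditions fixed up front: 2012–2019 calendar span
(eight years, so five temporal splits plus two reserved years fit), target
prevalence 5.7%, lognormal length of stay with mean ≈ 3.7 days, cause mix
822:31:38 (ICU readmission : IMC readmission : death), per-variable
exponential inter-arrival sampling (≈ 15 min high, 6 h medium, daily low),
Gaussian values with per-stay random means (which is what gives windowed
statistics between-stay signal), and a measurement-shift artifact — PTT
values offset by +15 from 2019-01-01, injected *after* outcomes are drawn
so it corrupts measurements, not risk.

Outcomes follow a known additive model: per-stay engineered features are
computed by the package's own featurizer, passed through configured
piecewise-constant truth terms, and the intercept is solved by 1-D root
finding (Brent) so the mean event probability hits the target prevalence.
The label is drawn first; a consistent readmission or death transfer is
then materialised in the transfer table (readmission delays of 2–72 h so
they never merge back into the index stay; post-discharge deaths appear
as ward transfers ending in death). This keeps the labelling logic
independently testable: merging and labelling the generated transfer
table must reproduce the stored labels exactly, and does.

A second entry point, `sample_feature_matrix`, draws engineered features
directly (standard-normal signal features through piecewise truth shapes
with eight distinct levels — piecewise approximations of smooth risk
curves — plus pure-noise features) for model-level experiments at larger
n where the event layer adds cost without adding coverage. Tests that
exercise merging, labelling and featurization use the full event-level
path at a few hundred to a few thousand stays; model-recovery and parity
properties use the direct sampler at n = 20,000.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: physiologic dynamics and treatment feedback,
informative missingness correlated with severity, inter-variable
correlation structure, documentation artifacts beyond the single planted
shift, and hospital-specific coding. Results on it validate the
*machinery* (labelling, windows, estimator convergence, selection
discipline, edit semantics), not clinical performance.

## Numerical choices and degenerate inputs

- Bins are right-closed; quantile cuts collapse on duplicates and cuts at
  the maximum are dropped so no trailing bin is empty. Constant features
  get a single bin; all-missing features only the missing bin.
- Trend (OLS slope) is undefined for fewer than two points or zero time
  variance → missing. Windows with no observation → all statistics
  missing (flows → zero).
- Early stopping restores the best score tables seen on the internal
  validation fold; `validation_fraction = 0` disables it (used in tests
  that check convergence limits).
- Model JSON serialization round-trips bit-exactly (Python floats print
  shortest-round-trip decimal).
- Single-class labels fail loudly everywhere (fit, metrics, baselines),
  naming the split where applicable.
- Seeds: every stochastic component takes an explicit seed; identical
  seeds give byte-identical generator output and identical fits.

## Problem sizes in tests and the acceptance script

The test suite runs the full event-level pipeline at 500–3,000 patients
and model-level properties at 8,000–20,000 rows; the acceptance script
uses 4,000 patients for the event-level run and 20,000 rows for
model-level properties, with `boosting_rounds ≤ 400` and 24–32 bins.
These sizes were chosen as the smallest at which the checked quantities
are stable (binomial SEs on a ~6% outcome shrink below the tolerances of
interest around these n).

## Known limitations

- The greedy selection retrains per k, which is quadratic in the cap for
  the full published cap of 80; at desk scale this is cheap, at scale one
  would cache per-split binning and parallelise.
- 2D confidence bands are not computed (the published bands are shown for
  1D functions; the editing workflow excluded all 2D functions anyway).
- The inspection taxonomy is recorded, not enforced: nothing stops a
  reviewer from flagging a clean function; the ledger only guarantees
  coverage, uniqueness and decision/problem consistency.
- `evaluate_model` with a fixed hold-out and refit-per-split measures
  training-pool stability, not sampling error of the hold-out estimate.
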