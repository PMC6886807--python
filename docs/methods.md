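# Methods

## Task and data model

The forecasting task is: given 24 consecutive CGM readings at the nominal
5-minute cadence (a 120-minute prediction window), predict the reading 30
minutes (6 steps) after the window's end. A trace is an ordered sequence of
(timestamp, glucose) readings in the sensor's reporting range 40–400 mg/dl;
values outside the range are rejected at I/O, not clamped. Consecutive
readings within 5 min ± 60 s are treated as contiguous; larger deltas are
gaps. The jitter tolerance is configurable per trace because real CGM
clocks drift; 60 s is a conservative default for nominally 5-min data.

Windows are emitted only from fully contiguous 30-reading spans — a gap
anywhere inside the window *or* between window end and target discards the
candidate. This is deliberate: imputing across gaps (Kalman smoothing, last
value carried forward) either uses future information or biases the trace,
so incomplete fragments are simply dropped. Stride is 1 reading, maximizing
the number of examples. Evaluation splits are always chronological
(default last 25% of readings as test, matching a ~6-week/2-week split),
and oversampling is applied to training windows only.

## Glycemic ranges and pseudolabels

Level-1 thresholds: hypoglycemia strictly below 70 mg/dl, hyperglycemia
strictly above 180 mg/dl; the boundary values 70 and 180 are classified
normal (hypo is "< 70", hyper is "> 180"). A window's pseudolabel is the
range of its *target*, not of the window readings. Pseudolabels exist only
to let classification-style oversamplers operate on a regression problem;
regressors never see them.

## Oversampling with target synthesis

All three balancers raise every non-empty minority class to the majority
(in practice normoglycemic) count:

- **random** — duplicate uniformly with replacement;
- **SMOTE** — for each synthetic row, draw a seed example uniformly from
  the class, a partner uniformly from the seed's k nearest same-class
  neighbours (Euclidean distance on the 24 raw mg/dl features), and a
  single λ ~ U[0,1]; emit `x_new = x_i + λ(x_j − x_i)` and
  `y_new = y_i + λ(y_j − y_i)`;
- **ADASYN** — same synthesis, but the number of rows seeded from each
  minority example is proportional to its difficulty r_i = (fraction of
  its k nearest neighbours *in the full dataset* with a different
  pseudolabel), integerized by largest-remainder rounding (ties to lowest
  index) so allocations sum exactly to the deficit; uniform allocation when
  all r_i = 0.

Because each glycemic class is an interval and the target interpolation is
convex, synthetic targets provably keep their parents' pseudolabel; this is
asserted on every synthetic row in tests via recorded provenance (parent
indices + λ). Defaults: k = 5, reduced to class size − 1 for tiny classes;
a singleton class falls back to duplication with a warning. Neighbour pools
are class-restricted for synthesis (both SMOTE and ADASYN) and global for
ADASYN's difficulty — the canonical choices for both algorithms. Distances
are computed on raw features, before standardization or polynomial
expansion, so the interpolation operates on physical mg/dl curves.

## Models

Ten configurations with one train/predict contract. Preprocessing order is
oversample → polynomial expansion (only Lasso and linear SVR) →
standardization (train-fitted means/SDs; zero-variance columns divided
by 1) → learner; `predict` takes raw windows and applies the fitted
preprocessing itself. Expansion last-but-one keeps all 324 degree-2 terms
(24 linear + 24 squares + 276 ordered interactions, no intercept column) on
a comparable scale for L1-type penalties; the alternative ordering
(standardize before expansion) was considered and rejected because the
interpolation and distance computations are defined on raw readings.

The "paper" registry profile pins the published settings: Lasso alpha by
5-fold cross-validation, iteration caps of 100 000 for Lasso/SVR/MLP, 500
trees for random forest and gradient boosting, MLP hidden layers of 5 tanh
units (one layer for `mlp_1`, two for `mlp_2`) trained with ADAM, nu-SVR
for the RBF kernel (no polynomial features), scikit-learn defaults
elsewhere. Two deviations, both documented here as this package's own
choices: scikit-learn has no L1-penalized SVR formulation for regression,
so `linear_svr` is standard epsilon-insensitive LinearSVR (L2 penalty); and
the dummy baseline (constant training-mean predictor) is implemented
natively rather than delegated.

The "fast" profile keeps the same model families with reduced problem
sizes for desk-scale grid runs: iteration caps of 2 000 (SVRs), 200/10
alphas (Lasso CV), 300 epochs at learning rate 0.02 (MLPs — the higher
rate compensates for the shorter schedule on mg/dl-scale targets), 25/50
trees (forest/boosting). Grid-level conclusions (ranking directions,
oversampling effects) are unchanged between profiles; absolute MARD values
differ somewhat.

Benchmark predictions are clamped to the sensor range 40–400 mg/dl before
scoring, as a deployed display would clamp them; this also keeps
relative-error metrics well defined for unconverged learners.

## Metrics

MARD uses the ground truth as denominator. Range-conditioned MARD_C
partitions pairs by the *actual* value's range; an empty subrange is
undefined (None/NaN), never 0 — otherwise a constant normal-range predictor
would look perfect in ranges it never visits. The weighted decomposition
`N·MARD_all = Σ_C N_C·MARD_C` is exact and tested.

Clarke EGA uses the canonical grid inequalities evaluated in precedence
order A, E, C, D, else B (see `metrics.ega_zone` docstring). The precedence
plus the inequalities partition the positive quadrant — verified
exhaustively on the 361 × 361 integer grid against an independently coded
oracle. Zones C and E are computed and reported but excluded from default
model selection: a constant predictor trivially scores 0% there, so they
reward uselessness.

## Benchmark statistics

Combinations are ranked within each patient (rank 1 best, average ranks on
ties; direction-aware — lower is better for all MARD variants and zones
B–E, higher for zone A). The Friedman test uses the tie-corrected
chi-square statistic with k − 1 degrees of freedom on the (k combinations ×
n patients) rank matrix; a fully tied matrix is reported as (0, 1) with a
warning. Its type-I error at α = 0.05 under a 40 × 6 null is calibrated to
5% ± 2.5% in tests. The Nemenyi post hoc compares mean ranks via the
studentized range distribution (q = |R̄_i − R̄_j| / √(k(k+1)/6n), p =
P(Q_{k,∞} ≥ q√2), computed with scipy's exact distribution, which matches
R's `ptukey`); with only ~6 patients it is expectedly underpowered, and a
test asserts that clear mean shifts still fail to reach pairwise
significance at this block count. Paired t-tests drop patients with
undefined values pairwise and report zero-variance differences as p = 1
with a warning. Per-cell sub-seeds are derived by hashing (master seed,
patient, model, oversampler) identities, so any cell can be recomputed in
isolation and results are independent of grid iteration order.

## Synthetic cohort

The generator produces the *statistical shape* of AP-user CGM data, not
physiology: glucose mean-reverts (rate 0.06/min) toward a latent drive =
140 mg/dl baseline + gamma-shaped meal excursions (4/day Poisson, amplitude
U(30, 120) mg/dl, peak ~75 min, ~9 h support) − delayed overcorrection dips
(probability 0.40 per meal, depth U(105, 135) mg/dl, peak ~55 min) +
Gaussian noise (1.3 mg/dl/√min), clipped to 40–400 and rounded to 0.1
mg/dl. Gaps arrive at 1/day with log-uniform durations 15–480 min and
delete readings outright. Kernel shapes and dip depths were calibrated once
by Monte Carlo so that mean range occupancy over seeds lands at ~3% hypo /
~30% hyper — the imbalance regime the oversamplers are designed for — and
then frozen.

What the simulator does *not* emulate: sensor error/drift, insulin and meal
covariates, circadian structure, inter-patient heterogeneity beyond seed
noise. Passing tests therefore demonstrate correctness of the pipeline and
the direction of the oversampling effect under realistic imbalance, not
clinical performance on real patients.

## Problem sizes in the shipped tests and acceptance script

The default simulated record is 56 days (~8 weeks) per patient. The
end-to-end grid tests and `scripts/acceptance.py` run the same six-patient,
240-cell grid on 14-day records with the fast profile — about 2 800
training windows per patient — which preserves every structural property
being checked (cell counts, analytic dummy-model identities, ranking
directions, the oversampling effect on hypoglycemic MARD) at desk scale.
The directional-effect test repeats the mlp_2 × {none, SMOTE, ADASYN}
comparison over 10 master seeds and requires the better synthetic
oversampler to win on hypo-range MARD in at least 7.

## Known limitations

- The linear SVR penalty deviates from an L1-penalized reading (see above).
- k-NN and several learners run at library defaults where the benchmark
  protocol left them unspecified; the registry records everything pinned.
- MARD is undefined for subranges a patient never visits; downstream
  rankings exclude such cells pairwise, which slightly changes the set of
  patients behind different combinations' means when hypoglycemia is rare.
- The Clarke grid boundary convention at bg = 70 follows the canonical
  inequalities; boundary pairs are resolved by the fixed A, E, C, D, B
  precedence.
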