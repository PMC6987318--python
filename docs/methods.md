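# Methods

## Slope of the size–abundance relationship

The unit of analysis is one community sample: the set of taxa counted in one
lake on one date, each contributing a single point (density in cells L⁻¹,
mean cell biovolume in μm³). The SAR slope `b` is the OLS coefficient of
log₁₀ density on log₁₀ biovolume over the taxa *present* (absent taxa are
omitted, not zero-filled; no binning or distribution model). Each taxon is
one point regardless of its density. A fit requires at least three taxa with
at least two distinct biovolumes; samples failing this are logged and
dropped, never imputed.

The model is fit by ordinary least squares. A generalized least-squares
formulation with no specified covariance structure reduces to OLS, so OLS is
the implementation; a weights hook is exposed through the closed-form fit
should a covariance model ever be wanted.

### Subsampling uncertainty

Uncertainty on `b` comes from delete-d jackknife subsampling of the species
pool: `reps = 999` refits, each on `round(0.70 · n)` taxa drawn *without*
replacement. The median of replicate slopes is the point summary
(`b_median`).

The raw 2.5/97.5 percentile interval of replicate slopes is **not** a
calibrated 95% interval: under m-out-of-n subsampling the replicate
dispersion around the full-sample estimate is `se · sqrt(n/m − 1)` (≈ 0.65
se at m = 0.7 n), so the raw interval covers the true slope only ~79–80% of
the time (verified by Monte Carlo at n = 150, noise sd 0.3). The default
`ci_method="calibrated"` therefore rescales the percentile deviations from
the median by `sqrt(m / (n − m))`, the standard subsampling rate correction,
restoring ~94–95% coverage. The uncalibrated interval remains available as
`ci_method="percentile"`. Noise-free (collinear) samples give a zero-width
interval under both methods, and `frac = 1` degenerates to the full-sample
fit.

### Quartile series

Size-class context for the slopes: thresholds are the 25th and 75th
percentiles (linear interpolation, numpy default) of the *distinct* taxon
biovolumes over the whole database, computed once — not per date. Q1/Q4
totals per date sum the densities of taxa strictly below/above these
thresholds; taxa exactly at a threshold belong to the middle classes. The
Q4/Q1 ratio is 0 when no large taxon is present and undefined (NaN) when Q1
is empty.

## Driver features

Ten predictors per lake-date: `T_mean` and `T_CV` (unweighted mean and
sample-sd/mean over the available depths; CV needs ≥ 2 depths and a positive
mean), `P_PO4_mean` (depth average with censored values held at the
detection limit), `Phyto_total` and `Zoo_total` (log₁₀ totals; a zero
zooplankton total maps to missing rather than −∞), `Zoo_selectivity`
(raw copepod/daphnid areal-count ratio, no logs; zero denominator → missing),
`Lake_Depth`, `Lake_Volume`, `Time_trend` (days since the lake's first
date) and `Seasonality` (calendar month 1–12, an ordered integer — no cyclic
encoding; December/January adjacency is a documented limitation). Tables are
matched on the exact calendar day by default; a ±k-day nearest-match
tolerance exists but defaults to 0. Missing driver cells stay missing for
the imputation stage; rows without a slope are dropped.

## Regression forest

From-scratch CART regression forest. Trees: at each node the split
minimising total within-child SSE is chosen among `mtry` randomly drawn
predictors, thresholds at midpoints of consecutive distinct values; ties
break toward the lowest variable index and smallest threshold; splitting
stops when children would drop below `min_leaf_size` (default 5) or no
split strictly reduces SSE (tolerance 1e-12, which also keeps constant
responses in a single leaf). No depth limit. Leaves predict their training
mean. Defaults: 999 trees, `mtry = ceil(p/3)` (the regression convention),
n-out-of-n bootstrap per tree. All kernels are numba-compiled; a single
master seed drives bootstrap draws and per-node predictor subsets, so fits
are deterministic and reruns byte-identical.

- **OOB variance explained** = 1 − MSE_OOB / Var(y) (sample variance),
  where each row's OOB prediction averages only trees whose bootstrap
  missed it. Rows never out of bag are excluded with a warning.
- **Permutation importance** (default metric MAE, MSE available): the
  predictor's column is permuted across rows, OOB predictions are
  recomputed, and the importance is the mean increase in OOB error over
  `n_perm = 5` permutations. A constant column cannot change under
  permutation, so its importance is exactly 0.
- **Partial dependence** is the Friedman average-over-data definition: at
  each grid value `g` over the predictor's observed range, the mean
  prediction with that predictor set to `g` for all training rows. The
  band is ± 2 standard errors of the per-row predictions at `g` (ensemble
  dispersion, not a sampling CI). The "average the variable values reaching
  terminal nodes" description sometimes given for forest partial effects is
  nonstandard; the standard definition is implemented deliberately.
- **Interaction surfaces** predict over a 2-D grid of one predictor pair
  with all remaining predictors fixed at their training medians.
- **Proximity** of two rows is the fraction of trees in which they share a
  terminal node.
- **Imputation** (`ProximityImputer`): missing cells start at column
  medians; each of `n_iter = 5` iterations fits a response-aware forest on
  the current completion (300 trees by default) and replaces each missing
  cell by the proximity-weighted average of the column's observed values.
  Columns more than 20% missing are rejected. The per-iteration RMS change
  of imputed cells is reported.
- An autoregressive variant (previous date's slope as an extra predictor)
  is a pipeline flag, off by default.

## Synthetic generator

The generator states a world resembling an eight-lake peri-alpine
monitoring panel and keeps its truth:

- **Lakes**: eight specs spanning the morphometric range (volume 0.148–11.8
  km³, site depth 30–144 m) and the trophic gradient (phosphorus baselines
  12–330 μg L⁻¹ declining at 2–60 μg L⁻¹ decade⁻¹; warming 0.17 °C
  decade⁻¹, matching an ~0.85 °C rise over five decades).
- **Profiles**: surface temperature = 11 + 8·cos(2π(doy−210)/365.25) plus
  the warming trend; depth decay toward a deep-water temperature with an
  e-folding depth that shrinks in summer, so `T_CV` tracks stratification.
  Phosphorus declines linearly, cycles seasonally (winter-mixing high),
  increases slightly with depth, carries lognormal noise, and is censored
  at the 1 μg L⁻¹ detection limit with a flag.
- **Taxa**: one harmonised pool shared across lakes; log₁₀ biovolume
  uniform over [0, 6] (the distribution is a modelling choice — no source
  states it); class labels with cyanobacteria tilted toward small sizes.
- **Communities**: per date, each taxon present with probability 0.6
  (Bernoulli), log₁₀ density = a + b·log₁₀ V + N(0, 0.3). The slope is
  `b = f(drivers) + N(0, 0.04)` with
  `f = −0.745 + 0.050·L(T) + 0.045·L(Zoo) − 0.050·L(P) − 0.045·L(Phyto) +
  0.035·L(T)·(1−L(P))` — logistic ramps centred at 10 °C, 5.2 log₁₀
  grazers m⁻², 100 μg L⁻¹ and 6.3 log₁₀ cells L⁻¹ — giving b in roughly
  [−0.84, −0.60] (clipped to [−1.5, −0.3]); the flattest response sits at
  high temperature and low phosphorus by construction. The intercept is
  chosen so the realised total density equals the generated `Phyto_total`
  driver exactly. Driver values are computed through the same preprocess
  functions the analysis uses, so a missingness-free round trip reproduces
  the truth table to machine precision, and the truth-minus-f discrepancy
  is exactly the recorded slope noise.
- **Zooplankton**: the four families with summer peaks and lognormal noise;
  **decoys**: two pure-noise columns are always recorded for
  importance-ranking recovery tests; **missingness**: a configurable
  fraction (≤ 0.2) of profile and zooplankton cells blanked at random —
  never community counts.
- `make_driver_table(n, r2)` samples the four true drivers independently
  over realistic ranges, adds the two decoys, and scales Gaussian noise so
  the generating R² is exactly `r2` — the controlled bench for forest
  skill, importance-ranking and effect-shape experiments.

What a green recovery test does *not* establish: the generator has no
taxonomic turnover, no colony-size biology, no zero-inflation beyond
Bernoulli absence, independent dates (no autocorrelated noise), and drivers
that are conditionally independent given season and trend — real
monitoring data are harsher on all counts.

## Numerical and design notes

- Subsampling replicates are drawn by vectorised partial argsort of uniform
  draws; per-sample seeds derive from one master seed in sorted
  (lake, date) order, per-lake generator streams from fixed seed offsets —
  all reruns byte-identical, all derived seeds < 2³¹.
- Monthly sampling snaps `interval_days` in [28, 31] to calendar months
  (mid-month sampling day), so a 30-year run has exactly 360 dates.
- The tree-grower's SSE is computed by prefix sums; the test oracle
  recomputes it directly per candidate split. Exact tie agreement between
  the two is not guaranteed in principle but is not observed to differ on
  continuous data.
- Pipeline stage failures abort with the stage name; dropped dates are
  logged and counted in the manifest.
- Known limitations: no GLS covariance structures; month is ordinal;
  permutation importance permutes whole columns (not within-tree OOB sets);
  no variable-importance p-values; single-threaded tree growth.
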