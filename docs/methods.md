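# Methods

This note records the modeling choices, defaults and known limitations of
the package, in the order the pipeline runs.

## Synthetic landscapes

Covariate layers are Gaussian random fields obtained by convolution
smoothing of white noise (`scipy.ndimage.gaussian_filter`, sigma =
`autocorrelation_range` in cells), standardized to zero mean and unit
variance. Lag-1 spatial autocorrelation is monotone in the range parameter,
which is the only property downstream code relies on. One categorical layer
(four quantile-binned classes of an independent smooth field) is always
present so that the one-hot paths of every algorithm are exercised.

Each virtual species responds to `n_drivers` (default 3) randomly chosen
continuous layers with effect sizes drawn from `beta_range` (default
|β| ∈ [1.5, 2.5], signs random); the logistic intercept is calibrated so the
fraction of cells with P > 0.5 falls in `prevalence_range` (default
[0.3, 0.5]). Realized occurrence is a Bernoulli(P) draw stored with the
truth, so detection experiments have a concrete occupancy to detect.

Abundance is zero wherever occupancy is below `occupancy_floor` (default
0.3) — a hard threshold chosen to reproduce the zero-heavy character of real
percent-cover data — and otherwise

    A_s = clip(amax_s · (P_s − floor)/(1 − floor), 0, 100) · max(0, 1 + Σ_j M_sj P_j)

with `amax_s` ~ U(20, 60) ha/km² and M a sparse signed interaction matrix
(default: 20 % of ordered pairs interact, coefficients up to 0.6 in
magnitude, 70 % negative to bias toward competition). With M = 0, abundance
is monotone in own occupancy by construction.

Tree-cover truth comes from a fine-scale (default 50 m) binary woodland
mask: within each 1-km cell the woodland count matches a smooth target
fraction, with fine cells chosen by a smoothed noise key so woodland clumps.
Woodland-tree cover C_W is the woodland fraction times a smooth canopy
density (0.6–0.9); outside-woodland cover C_O is a small smooth field scaled
by the nonwooded fraction; C_A = C_W + C_O; edge cover C_E is computed by
the same `compute_edge_cover` routine the harmonization module exposes.
Units: cover layers are fractions in [0, 1]; abundance is ha/km², numerically
equal to percent cover.

Survey effort is parameterized per tetrad (2 × 2 block of 1-km cells):
surveyed with probability `p_surveyed`, visit count `min_surveys +
Poisson(extra)`, per-visit species totals Normal(70, 12) with an
`undersurveyed_fraction` of tetrads logging only 10–49 species, detection
probability 0.9 by default. The detection probability implicit in real atlas
data is unknown; here it is an explicit free parameter, not a claim about
any survey scheme. Abundance samplers draw (species, cell) pairs uniformly;
patch-dialect draws are restricted to cells where the within-patch
percentage is representable (woodland present, percentage ≤ 100), and both
dialects invert exactly under zero noise — the recoverability tests depend
on that.

What the generator does **not** emulate: real spatial sampling bias
(recorder effort correlates with population density in real atlases),
non-Gaussian covariate marginals, temporal trends across the survey window,
and any resemblance to actual geography. Passing recovery tests therefore
demonstrates correctness of the machinery under the stated statistical
assumptions, not expected skill on real data.

## Occurrence preparation

Calendar window endpoints (default 1950–2014) are inclusive. Records coarser
than tetrad precision are dropped; finer ones are re-keyed to their tetrad.
A tetrad is well-surveyed when it has ≥ `min_surveys` (2) in-window surveys
with ≥ `min_species` (50) species each; weaker extra surveys are ignored
rather than disqualifying — the criterion asks for enough strong surveys,
and a third poor visit adds no evidence of absence. Presences are kept even
in tetrads failing the effort bar (a record is evidence regardless of
effort); only absences require it. Rows that are presence-only tetrads carry
NaN for unrecorded species and are dropped per species in stage 1.

## Covariate pruning

Greedy elimination ordered by descending |r|: the most collinear violating
pair is resolved first by removing its lower-priority member (priority rank
1 = most important; ranks are user configuration, standing in for domain
knowledge about which variables matter). The rule is strictly "higher than"
the threshold; comparisons carry a 1e-9 tolerance so a pair sitting exactly
on the boundary is not decided by floating-point noise. Constant layers are
excluded from the correlation computation with a warning but retained.
Pearson r is computed over cells finite in both layers. The output is
idempotent and provably threshold-satisfying (both are asserted in tests).

## Stage-1 ensemble

Splits are unstratified random 70/30 (train = round(0.7·n)); with fewer than
10 rows the split refuses. Within the pipeline a split is redrawn (up to 20
times, deterministically) if either part is single-class, since ROC and TSS
are undefined there. Repeat seeds derive from (base seed, species index,
repeat index) so every member is reproducible in isolation.

Algorithms are realized with scikit-learn: GLM = near-unpenalized logistic
regression; GAM = cubic spline basis (5 knots) + logistic regression; CTA =
a single depth-limited decision tree (max depth 8, min leaf 10); GBM = 100
gradient-boosted trees of depth 3; RF = 500 bagged trees; the MaxEnt-style
member is an L2-penalized logistic regression on linear + quadratic +
pairwise-product features — with presence–absence input the presence-only
background machinery of true MaxEnt is unnecessary, and the expanded-feature
penalized logistic captures the equivalent response flexibility. All
hyperparameters are config-overridable. Nonsignificant covariates are never
removed.

TSS is maximized over thresholds {0} ∪ {midpoints of sorted unique scores}
∪ {1} with "score ≥ threshold ⇒ predicted present" and the smallest
maximizing threshold reported. AUC is rank-based pair counting with half
credit for ties.

Member selection: sorted by ROC, the smallest top group whose worst member
beats the best remaining model by ≥ `gap` (default 0.05) in *both* ROC and
TSS is the leading group; "a step higher" is qualitative in origin, and 0.05
is this package's reading of it. Otherwise the top 20 by ROC are taken, ties
at the cut included. The published workflow then screened members by visual
inspection of response curves; this package replaces that manual step with
an automated consensus rule — members whose mean absolute deviation from the
cellwise-median map exceeds 0.25 are rejected, with a floor of two survivors
— while response-curve export (`sdm.response_curves`) is retained for manual
inspection. Survivors are refitted on 100 % of the rows for the final map
(selection scores still come from the 70/30 runs), and the ensemble is the
ROC-proportional weighted mean, weights normalized to sum to one. The
weighted mean is convex, so ensemble maps stay in [0, 1] cellwise between
the member extremes.

## Harmonization

Both conversions are exact closed forms: patch percentage × woodland
fraction, and linear % × linear fraction + nonlinear % × (1 − fraction).
Outputs are clipped to [0, 100] to guard float overshoot. Duplicate
(species, cell) records are kept as independent training rows — how real
duplicates were reconciled is unstated, and independent rows are the least
presumptive choice. Edge cover uses an exact Euclidean distance transform,
cell-center to cell-center, on the fine mask (resolution must not exceed the
50-m edge distance; 10 m is typical, the synthetic truth uses 50 m); all-
woodland and no-woodland masks yield zero edge by definition rather than
erroring.

## Stage-2 abundance forest

Feature order is fixed: focal P̂ first, remaining species in sorted name
order, then C_A, C_W, C_O, C_E (n_species + 4 columns). Forest defaults: 500
trees, a third of covariates per split, seeded. Predictions are clipped at
zero, and tree averaging keeps them ≤ the observed maximum. The fold rule is
k = 10 when nonzero ≥ 50, else floor(nonzero/5) when nonzero ≥ `min_nonzero`,
else refusal; `min_nonzero` defaults to 30, splitting the interval between
the smallest count that was modeled in practice (42) and the largest that
was refused (27). Cross-validation folds are unstratified random with the
seed recorded in the report. R² (1 − SSE/SST on pooled held-out predictions,
possibly negative) always travels with a caveat flag: under heavy zero
inflation R² depends on the response's spread and punishes the forest's
slightly-above-zero predictions at true zeros, so RMSE/MAE are the headline
metrics. `zero_cutoff` (coercing small predictions to exact zero) defaults
to off; choosing it is a judgment about the map's intended use.

## Orchestration and determinism

Stages communicate only via files (CSV tables, multi-page float32 TIFF
rasters with JSON grid sidecars and CSV layer manifests), so each stage is
independently testable. The run manifest logs seeds and record counts at
every filter (records in → tetrad level → well-surveyed → PA rows), making
data loss auditable. Every random draw descends from the configured seed;
rerunning any stage reproduces its outputs bit for bit.

## Problem sizes used in validation

The test suite validates recovery on an 80 × 80-km landscape (1,600 tetrads,
5 species, 3 strong drivers, detection 0.9, 6 algorithms × 5 repeats,
3,000 + 3,000 abundance records at noise SD 2 ha/km²) and bookkeeping on a
20 × 20-km landscape at the full 25-species × 6-algorithm × 15-repeat
configuration with reduced tree counts. These sizes are the package's
validation conditions; the pipeline itself has no scale assumptions beyond
memory.

## Known limitations

Tetrad-level training rows are matched to 1-km covariates at the tetrad
center rather than averaged over member cells. The consensus screen is a
proxy for expert plausibility review and can in principle reject a lone
correct member when the committee is collectively wrong. No spatial
cross-validation is offered, so reported CV skill is optimistic under
residual spatial autocorrelation. Pseudo-absence generation, imperfect-
detection occupancy corrections, uncertainty maps and projection to novel
conditions are out of scope.
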