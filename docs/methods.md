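# Methods

This note documents the models, estimators and numerical choices behind
`shoalnet`, what the synthetic-data generator does and does not emulate,
and the design decisions made where the methodology was genuinely open.

## Trajectory handling

Input is the output format of identity-preserving trackers: one row per
video frame, one (x, y) pair per fish, missing detections as NA. The
canonical dialect is CSV with header `frame,x1,y1,...,x8,y8`, one file per
group-trial; fish identities come from the metadata table, and a
calibration factor (cm per coordinate unit) plus the frame rate are
required configuration because recording setups differ. Coordinates are
stored with the origin at the arena center.

All collective metrics use **complete frames only** — the group centroid
and the full pairwise distance matrix need all eight individuals. Frames
failing this are dropped; a missing fraction above 2% (configurable)
triggers a QC warning because well-tracked videos of this kind lose at
most a couple of percent of frames. Dropped frames leave visible gaps in
the retained frame numbers, and **activity accumulates steps only between
retained frames whose original indices are adjacent**: a dropout gap
contributes zero distance rather than a straight-line bridge, so dropouts
can only deflate activity slightly, never inflate it.

## Collective metrics

- Activity: Σ over adjacent retained frames of the Euclidean step length.
- Cohesion: mean over frames of the distance to the 8-fish centroid.
- Pair interaction time: (# frames with ‖x_i − x_j‖ ≤ t·BL(i,j)) / fps,
  default threshold t = 1 body length. **BL(i,j) is the mean of the two
  fish's standard lengths** — symmetric and uses the measured sizes; the
  focal-fish and group-mean alternatives are selectable. Distances are
  between tracker centers of mass, and the comparison is ≤.
- Strength: row sum of the group-trial weight matrix; conserved exactly
  against the pair table (Σ_i s_i = 2 Σ_{i<j} w_ij).

## Weighted clustering

Proximity networks of 8 fish in a 1.2 m arena are almost always
topologically complete (every pair interacts at least one frame), and any
clustering coefficient that reduces to the binary transitivity on complete
graphs is then identically 1. The Barrat coefficient
C_i = (W A²)_ii / (s_i(k_i−1)) has exactly this property, so the default
is the Onnela form C_i = ((Ŵ^{1/3})³)_ii / (k_i(k_i−1)), Ŵ = W/max W,
which keeps discriminating weight structure on complete topologies and is
invariant to rescaling W. The Clemente–Grassi strength-based coefficient
reduces algebraically to Barrat's on undirected graphs and is provided
under its own name for cross-checks. Nodes with fewer than two positive
edges have no defined triangle fraction; their clustering is reported as 0
and they are flagged (`degenerate_nodes`), never silently dropped. No edge
thresholding is applied: any positive interaction time is an edge.

## Allometric size adjustment

M_adj = M_o (S̄L/SL_o)^b with b the common within-population slope of
**log₁₀ trait on log₁₀ standard length** from the additive ANCOVA
log₁₀M ~ log₁₀SL + population. Fitting on the log scale is what makes the
power-law back-transform internally consistent (the standard
Reist/common-slope procedure); the slope is fitted per trait, pooled
across ecotypes, and S̄L is the grand mean over all measured fish, not a
per-population mean. After adjustment the residual log-log slope is ~0 by
construction, which the tests verify on data with known slopes.

## Mixed models and Type III Wald tests

All Gaussian mixed models are random-intercept models fitted by REML with
a dedicated variance-components engine (`shoalnet/_lmm.py`). The REML
criterion is profiled over the fixed effects and the residual variance and
optimized over log variance ratios; the linear algebra runs on q×q
random-effect cross-products via the Woodbury identity (q = total random
levels, ≤ ~250 here), so a fit costs ~1 ms for one component and ~40 ms
for three. That speed is the point: the resampling procedures below need
10³–10⁴ refits. statsmodels' MixedLM fits the same models and is used as
an independent cross-check in the test-suite (agreement to ≈4 decimals on
variance components; on the crossed 3-component design statsmodels' default
optimizer can stall at a worse REML criterion and agrees only after
switching it to Powell).

Model structure, per response:

| response | fixed | random |
|---|---|---|
| behavior PC scores | ecotype | population, family, group |
| behavior PC scores | population | family, group |
| morphology PC scores | ecotype | population, family |
| morphology PC scores | population | family |
| latency (quasi-Poisson) | ecotype | population, family |
| latency (quasi-Poisson) | population | family |

Morphology models carry no group term because morphology is measured on
individuals outside the group assay. Fixed factors use sum-to-zero coding,
a precondition for meaningful Type III tests; the reported statistic is
the Wald chi-square b'V⁻¹b over the factor's coefficients (df = levels−1).
**Known property:** with only 8 populations / 30 groups the chi-square
reference is an approximation — slightly conservative under a complete
null (≈3% rejection at nominal 5%; lme4 + car::Anova shows the same size
on identical simulations) and anti-conservative (≈8%) when substantial
clustering variance is present, because the effective denominator df are
~6–22 rather than infinite. This is a property of the Wald-chi-square
procedure itself, reproduced by the reference implementation, and is left
as-is rather than substituting an F test.

Post-hoc contrasts compare estimated marginal means of the fixed factor
with the Tukey (studentized-range) adjustment, using residual df as the
denominator-df approximation, and summarize separations with a compact
letter display (insert-and-absorb algorithm).

## Quasi-Poisson GLMM (latency to emerge)

Latency is integer seconds with a hard ceiling: fish that never emerged
within 10 min are scored 600 s and treated as observed values, not as
censored. The model is a log-link GLMM with Var(y) = φ·μ, fitted by
penalized quasi-likelihood: iterate (i) working response
z = η + (y−μ)/μ and weights w = μ, (ii) weighted variance-components REML
on z, (iii) update η = Xβ + Zû from the BLUPs, to a 1e-6 sup-norm
tolerance on η. The dispersion φ is the residual variance of the weighted
working model, equivalent to a Pearson χ²/df moment estimator; on
simulated Poisson data it sits at ≈1, and the fixed-effect estimates agree
with MASS::glmmPQL to ~0.01 on the log scale (tested via Rscript when R is
available).

## Adjusted repeatability

R = σ²_ID / (σ²_ID + σ²_res) from the LMM with the (transformed) behavior
as response, population fixed, fish ID random — the intraclass correlation
net of population differences. Transforms follow the distributional shape
of each metric: log for activity, square root for cohesion, strength and
pairwise interaction time, none for clustering (already approximately
normal). Pair-level repeatability uses the pair identity as the grouping
factor.

Uncertainty and significance:

- **95% CI** — parametric bootstrap: simulate from the fitted model
  (fixed effects + Gaussian random effects + residual), refit, take the
  2.5/97.5 percentiles of R (default 1000 iterations; the engine makes
  10⁴ feasible).
- **p_boot** — parametric bootstrap under the no-individual-variance null
  (same total variance, none between individuals), p = (1 + #{R* ≥ R̂}) /
  (n+1).
- **p_perm** — permute fish identities across observations *within
  population* (preserving the adjusted fixed structure) and compare the
  one-way ANOVA F-ratio of the fixed-effect-adjusted residuals. The F
  statistic, not R̂ itself, is the permutation statistic: REML truncates
  R̂ at zero, so under the null about half of the observed and permuted
  values tie at the boundary and an R̂-based p-value piles up at 1 (it is
  valid but very conservative). The F-ratio is continuous and monotone in
  the ICC, giving a uniform null p-value distribution (verified by KS test
  in the acceptance suite) with the same power against positive
  repeatability.

Calibration, verified in the acceptance suite at the study design
(240 fish × 2 trials, variance ratio 0.5): mean R̂ unbiased to <±0.03 over
200 replicates; bootstrap CI coverage 95%±3% at 1000 iterations.

## PCA and correlations

PCA is on the correlation matrix by default (center + unit scale): the
behaviors live on incommensurate scales (cm, seconds, dimensionless), so
covariance PCA would be dominated by whichever variable has the largest
units. Components are ordered by decreasing variance; the sign of each
component is fixed by making its largest-magnitude loading positive (PC
signs are otherwise arbitrary, so any comparison across software is up to
a global flip per component). Scores feed the mixed models; variance
explained is reported over all components and sums to 1. Spearman
correlations use scipy's rank correlation with a bootstrap percentile 95%
CI (the CI method is not standardized in the field; bootstrap makes the
fewest assumptions).

## Synthetic data generator

The generator emulates the study *design*, not fish biomechanics:

- **Design**: 8 lake populations, 4 per ecotype, with the uneven
  family/group layout of the real study (2–4 families and 2–7 groups per
  population; 30 groups, 240 fish); two trials per group; 20-min trials in
  a 1.2 m circular arena; ≤2% frame dropout (default rate 1%).
- **Traits**: each fish carries latent sociability (centroid attraction,
  cm/s per frame) and speed (cm/s) built hierarchically: ecotype shift +
  population deviate + family deviate + fish deviate. Defaults: speed
  5 ± (0.8 pop, 0.3 family, 1.0 fish, 0.7 trial) cm/s; sociability
  0.5 ± (0.15, 0.05, 0.12, 0.08). Ecotype shifts default to 0 for both
  behavior traits — population-level but not ecotype-level divergence —
  while morphology carries a benthic body-depth shift (+0.04 log₁₀ ≈ +10%)
  and latency a benthic/limnetic mean ratio of 150/250 s, the pattern of
  parallel morphology/boldness divergence without behavioral parallelism
  this kind of study probes.
- **Movement**: v ← P·v + s·û_centroid + c·speed·ξ per frame, positions
  advance by v/fps and reflect specularly off the wall; persistence
  P = 0.8 and noise scale c = √((1−P²)/2), chosen so a lone fish's RMS
  speed equals its speed trait. Trial-level trait deviates (redrawn each
  trial) plus trajectory stochasticity generate the within-individual
  variance; persistent traits generate repeatability. The kernel is
  deliberately minimal — attraction, persistence, noise, wall — enough to
  induce the variance structure the statistics consume and cheap enough to
  run thousands of times. It has no alignment/repulsion zones, no
  body-size-dependent kinematics and no predator or habitat features, so
  passing recovery tests demonstrates estimator correctness, not realism
  of fish locomotion.
- **Morphology**: log₁₀trait = baseline + b·(log₁₀SL − log₁₀S̄L) + pop
  deviate + ecotype shift + N(0, 0.02); per-trait slopes 0.9–1.2. 159 of
  the fish are "measured", excluding the two smallest populations,
  mirroring incomplete measurement coverage.
- **Latency**: negative-binomial seconds (size 3; Poisson if size is None)
  around the log-scale ecotype means with population/family deviates,
  hard-truncated at 600.

Everything is deterministic given the config and seed (single PCG64
stream per sub-generator, offset from the config seed).

## Problem sizes

Default simulation fps is 30; the test-suite and the acceptance script run
the full 30-group design at 5 fps (tests also shorten trials to 2 min),
which preserves every design count and the variance structure while
keeping a full pipeline run in seconds. The acceptance script uses 500
bootstrap/permutation iterations per behavior, 200 replicates for
estimator-bias calibration, 150 for permutation-uniformity and CI checks,
and 400 null replicates for Wald-test size; the paper-scale 10 000
iterations are a config change (`n_boot`, `n_perm`).

## Known limitations

- The Wald chi-square calibration issue above: with so few populations,
  ecotype inferences lean on ~6 effective denominator df; p-values near
  0.05 should be read with that in mind.
- PQL is a first-order approximation; for strongly overdispersed,
  near-ceiling latency distributions the dispersion estimate absorbs some
  ceiling-truncation effects.
- The emulated morphology PCA has no built-in cross-trait correlation
  beyond shared allometry, so its variance-explained spread is flatter
  than in real morphometric data.
- Bootstrap CIs use percentile bounds; R̂ can fall marginally outside the
  interval in boundary cases (quantile granularity).
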