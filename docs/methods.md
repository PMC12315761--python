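# Methods

This package implements a multivariate analysis chain linking vertex-wise
cortical morphometry to executive-function outcomes in a two-site
case-control cohort (cases: adolescents and young adults who underwent
cardiopulmonary-bypass surgery for a complex congenital heart defect;
controls: age- and sex-matched healthy peers). The chain is: control
matching → descriptive statistics → multi-site harmonization → orthogonal
projective non-negative matrix factorization (OPNMF) of the stacked
cortical features → behavioural partial least squares correlation (bPLS)
with resampling inference → exploratory clinical correlations. Because the
real cohort is only available under a data-sharing agreement, the package
ships a synthetic-cohort generator with planted ground truth; every stage
is exercised and validated against that ground truth.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
cortical anatomy. Geometry is a two-hemisphere rectangular grid with
4-neighbour adjacency (default 25 × 40 per hemisphere, 2,000 vertices); the
first grid column of each hemisphere is flagged "midline" and masked, the
analogue of excluding unreliable midline vertices on real surfaces (81,924
→ 77,122 at full resolution). Contiguity is the only topological property
the stability analyses rely on, so a grid suffices.

The feature model is additive and parts-based, the regime a non-negative
factorization is designed for:

    X_m = W H_m + site effects + noise,       m ∈ {CT, SA, GI}

* `W` (vertices × k, default k = 6): spatially contiguous, pairwise
  disjoint patches grown by seeded breadth-first region growing that tile
  the unmasked surface; loadings uniform on [0.5, 1.5].
* `H_m = s_m · clip(1 + 0.2·u + 0.15·volz, 0.05, ∞)`: non-negative subject
  weights around metric-scale baselines s_CT = 3 mm, s_SA = 12 mm²,
  s_GI = 2.5, with ~20% coefficient of variation. `u` (k × n, standard
  normal) are the latent component scores; `volz` is standardized total
  grey-matter volume, so volume residualization has real work to do.
* Latent scores carry the group signal (components 1–3 shifted by 0.6,
  −0.45, 0.35 SD in cases) plus small age and sex effects, so brain
  structure, demographics and behaviour are coupled through a common cause,
  as the analysis assumes.
* Behaviour: 12 executive-function scales on the T-score convention,
  `T = 50 + 10·(C u + b·(group − ½) + e)`, with the coupling matrix `C`
  tying the working-memory-flavoured scales to component 1 (0.30) and the
  regulation scales to component 2 (−0.20), group effects of 0.55 SD on 8
  of 12 scales (cases worse) and 0.25 SD on the rest, and the noise scale
  chosen per scale so each column has unit total variance (sample mean ≈
  50, SD ≈ 10). Effect sizes for the brain-behaviour coupling are not
  published for the real cohort; these defaults are one fixed, plausible
  operating point, configurable but not calibrated to any reported result.
* Site effects, second site only: additive shift (0.05 of each metric
  scale), variance inflation (×1.3), and a rank-1 shared-factor
  perturbation that raises between-vertex correlations — precisely the
  mean/variance/covariance triple the harmonization stage claims to remove.
* Case-only clinical variables (age at first surgery, aortic cross-clamp
  time ~ N(72.7, 31.4) minutes) with ~12% missing completely at random,
  mirroring the partial clinical availability typical of surgical
  registries.

With noise and site effects switched off the features equal `W H_m`
exactly, which gives downstream recovery tests an exact target. What the
generator does **not** emulate: real surface topology and geodesic
distances, spatially correlated measurement noise, non-Gaussian behaviour
distributions, site-by-group confounding (sites are balanced by design),
and any dependence of missingness on disease severity. Passing tests
therefore demonstrate correctness of the machinery under the model's own
assumptions, not robustness to their violation.

## Matching and descriptive statistics

Controls are matched 1:1 to cases by greedy nearest neighbour on raw-scale
Euclidean distance over (age, sex), cases in table order, ties to the first
occurrence — deterministic and idempotent. Abnormality flags use the
clinical convention T ≥ 65 (inclusive). Contingency tables are tested by
Fisher's exact test (two-sided, minimum-likelihood convention) when any
expected count is below 5 and by Pearson's χ² without continuity correction
otherwise; both branches can be forced. Continuous outcomes use an ANCOVA
F-test for the group term (full vs reduced least-squares fit, equivalent to
Type III for a single binary factor) with age, sex and maternal education
as covariates; an automatic gate checks Shapiro–Wilk normality of the
residuals at α = 0.05 and falls back to a log-transformed ANCOVA (positive
outcomes) or a Mann–Whitney U test, recording the branch taken.

## Harmonization

Location-scale harmonization follows the classic per-row empirical-Bayes
model: rows are standardized against a pooled intercept + covariate fit,
per-batch per-row means and variances are shrunk across rows under a
normal / inverse-gamma prior (hyperparameters by method of moments, coupled
posteriors by fixed-point iteration), and covariate effects (age, sex,
group) are restored afterwards. One deliberate numerical choice: batch
variance estimates use the population (1/n) convention so they are
commensurate with the pooled variance; two identical batches then get scale
factors of exactly 1 and a single batch is exactly a no-op.

The covariance stage stacks CT, SA, GI and the volume scalar vertically,
takes principal axes of the location-scale-adjusted residuals, and applies
the same location-scale correction (without shrinkage) to the component
scores spanning `pc_fraction` (default 0.95) of the residual variance
before reconstruction. This removes batch effects expressed in the
*dominant* covariance structure — e.g. a shared scanner factor — and is, by
construction, insensitive to covariance perturbations confined to a few
rows, which are statistically indistinguishable from covariance sampling
noise at realistic n. Total grey-matter volume is harmonized inside the
same stack (one extra row) so the residualization stage sees a
batch-corrected volume; whether the original analyses harmonized volume
jointly or separately is not documented, and this is the simpler choice.

## Factorization input

Midline vertices are dropped; each (vertex, metric) row is residualized on
harmonized total volume by per-row OLS with intercept; rows are z-scored
*within each metric block* (the metrics live on different scales, so
cross-metric z-scoring would let one metric dominate); the single
matrix-wide minimum z-score is subtracted so min(V) = 0 exactly.
Zero-variance rows are set to zero before shifting — a constant feature
carries no covariance information and must not produce a division by zero.

## OPNMF

The factorization minimizes ‖V − W WᵀV‖²_F over W ≥ 0 (projective form:
H = WᵀV), by the Yang–Oja multiplicative update

    W ← W ⊙ (V(VᵀW)) ⊘ (W((WᵀV)(VᵀW)) + ε),    ε = 1e-16,

with NNDSVD initialization, a 1e-16 entry floor, and products arranged so
the vertices × vertices Gram matrix is never formed (memory O(mk + nk);
~1e5-vertex surfaces are tractable). Convergence is declared when the
relative change of the objective between checks (every 10 iterations) falls
below 1e-5; defaults max_iter = 100,000, tol = 1e-5. Output W has unit-norm
columns and H = WᵀV; winner-take-all labels take each row's argmax, ties to
the lowest index, all-zero rows a sentinel −1.

Two numerical decisions matter here. First, the update is **not** rescaled
inside the loop: per-iteration column normalization changes the update's
implicit scaling dynamics and demonstrably traps it in a severe local
minimum on clean parts data (relative error 0.49 where ~0 is attainable);
normalization is applied to the monitored copy and the final output only.
Second, NNDSVD's structural zeros are filled with 1e-6 × the mean positive
initial entry (multiplicative updates cannot leave an exact zero); making
the fill relative to W's own scale rather than V's keeps the whole fit
exactly equivariant under V → cV.

Two honest limitations, both verified empirically. (1) Off-part leakage
entries decay like O(1/t), so on noiseless parts data the *unsquared*
relative Frobenius error plateaus around 1e-4 at feasible iteration counts
even though winner-take-all labels are exact from a few hundred iterations;
near-zero reconstruction error should be read on the squared (objective)
scale. (2) Fitted error is not monotone in k: past the true rank, and on
featureless data generally, the orthogonality pressure can *raise* the
reached local optimum's error. Rank selection therefore treats "error rises
with more components" as "no further gain", not as a violation.

## Rank selection

For each candidate k the subjects are split into random halves (default 10
splits), each half re-prepared *independently* (residualization and
z-scoring within the half, so no leakage) and factorized, and the two
half-sample W matrices compared after optimal one-to-one Hungarian matching
on cosine similarity. The selected rank is the smallest k whose mean
similarity reaches the stability floor (default 0.8) while the error gain
from adding one more component is below 1% of the initial error; if no k
qualifies the smallest grid value is returned with a `no_elbow` flag. The
floors are exposed configuration: the underlying criterion ("high spatial
stability and low reconstruction error with minimal complexity") is
qualitative, and these defaults are the package's operationalization.

## Behavioural PLS

Both blocks are column-wise z-scored, so the cross-block matrix
R = YᵀX/(n−1) is the behaviour × brain correlation matrix; its SVD
R = U S Vᵀ yields the latent variables. Covariance explained per LV is
s²ᵢ/Σs² (fractions are additive across LVs by construction); subject
expressions are x = XV, y = YU. Sign convention: each LV's behaviour
salience is oriented so its largest-magnitude entry is positive —
determinism across runs and platforms, nothing more.

Inference:

* **Permutation** (default 10,000): rows of Y permuted; add-one p per
  singular value, without any alignment of the permuted solutions
  (standard practice for singular-value significance).
* **Bootstrap** (default 10,000): subjects resampled with replacement,
  blocks re-standardized, SVD refitted, and each resample's singular
  vectors aligned to the original by optimal order/sign matching
  (Hungarian assignment on the stacked behaviour + brain similarity, one
  assignment for both sides). A free orthogonal (Procrustes) rotation was
  evaluated and rejected: it lets noise LVs rotate into the leading LV and
  shrinks the bootstrap SD of null saliences to roughly half their true
  sampling SD (measured 0.066–0.100 vs a true 0.142 at n = 150), which
  inflates the false "contributing" rate several-fold. With matched
  alignment the bootstrap SD reproduces the sampling SD (0.144 vs 0.142)
  and the CI-excludes-zero flags calibrate. Bootstrap ratio = original
  salience / bootstrap SD; CI = 2.5/97.5 percentiles; degenerate resamples
  (constant column) are redrawn and counted.
* **Split-half** (default 200 splits): per split, each half's singular
  vectors are order/sign-aligned to the full-sample solution and the
  per-LV correlation between the halves' brain vectors (left) and
  behaviour vectors (right) is averaged over splits; the same statistic is
  recomputed under row permutations of Y (same splits, default 500 draws)
  for an add-one p per side per LV. The exact split-half statistic used
  with the real cohort is not documented; this cross-half correlation
  against a permuted null is the package's documented choice.

Subjects with any missing behaviour value are excluded listwise and
reported. The behaviour block enters as T-scores (the "continuous scores"
phrasing is ambiguous; T-scores are the norm-referenced scale).

## Clinical associations

Within cases only: average-rank Spearman ρ between LV scores and continuous
clinical variables, t-approximation p (an exact permutation p is available
for very small n), pairwise deletion of missing values. Categorical
clinical variables are excluded (sparse cells), and no multiplicity
correction is applied to these exploratory tests.

## Pipeline and problem sizes

`run_pipeline` executes the stages in study order with one master seed
fanned out per stage (`numpy` SeedSequence); for a fixed config + seed the
result bundle is bit-identical across runs. The default synthetic scale
(2,000 vertices, 120 subjects, k = 6) exercises every stage in seconds to
minutes on one core; the test suite and the acceptance script use reduced
replicate counts (e.g. 3–5 stability splits, hundreds rather than thousands
of resamples) chosen as the smallest sizes at which the monitored
quantities are stable, and each test states the sizes it uses.

## Known limitations

* The grid geometry has no notion of geodesic distance or folding, so
  spatial claims are limited to contiguity and disjointness.
* Parametric empirical Bayes only (normal / inverse-gamma priors); more
  than two batches is supported but only the two-site case is exercised.
* The bPLS block is a correlation PLS; regression PLS, sparse PLS and
  multi-group variants are out of scope.
* Calibration statements (permutation rejection rates, bootstrap flag
  rates) are Monte-Carlo estimates under the generator's assumptions;
  they carry the usual binomial noise at the replicate counts used.
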