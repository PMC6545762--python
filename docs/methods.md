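# Methods

This note records the statistical model behind `ensemblefs`, the choices
made where the design was genuinely open, and what the synthetic experiments
do and do not demonstrate.

## Cohort model

The generator emulates a pediatric cohort (n = 726 by default, age
10.0 ± 0.67 y) in which obesity-related variation is carried by two latent,
standard-normal adiposity factors: visceral `V` and total
`T = ρV + √(1−ρ²)·T′`, correlated at ρ (default 0.5). Anthropometrics:

    waist = 64 + 1.5·sex + 1.2·(age−10) + a_w·V + ε_w
    bmi   = 17.5 + 0.3·sex + 0.5·(age−10) + a_b·T + c·lean + ε_b

with `lean` an independent lean-mass factor — BMI deliberately cannot
distinguish fat from muscle, which is the scientific contrast between the
two obesity definitions. Informative biomarkers are linear in the latent
factors plus Gaussian noise; the default loadings give CRP and insulin
positive, and adiponectin negative, loadings on total adiposity together
with same-signed visceral components (visceral fat is the metabolically
active compartment), while leptin loads on the visceral factor only. The
remaining thirteen analytes are standard-normal noise. Fitness is modelled
as heart-rate elevation after exercise, increasing with total adiposity,
and is binarized at the median. All units on the biomarker side are
irrelevant after z-scoring; anthropometric constants are plausible for
ten-year-olds but are configuration, not estimates of the real cohort.

Default loadings were chosen so that (i) each informative biomarker's
correlation with its driving latent factor sits in the 0.55–0.65 band
plausible for salivary analytes, (ii) the four informative markers have
near-equal association with the waist outcome so no single marker's
relative score crushes the rest below the 20% selection cutoff, and
(iii) leptin's association with BMI-defined obesity flows only through ρ,
keeping its conditional contribution for that outcome near zero. Waist
noise is modest (the waist–visceral correlation is ≈ 0.92): because the
outcome is a 95th-percentile tail with only ~41 cases, noise on the
outcome side of the chain — not marker noise — is what limits how reliably
the analysis can recover all planted markers at this sample size.

Outcomes are flagged within sex × whole-year-age groups at the empirical
95th percentile (linear-interpolation quantile; "at or above" inclusive),
so prevalence is ≈ 5% per group and ties at the cutoff are all flagged.

### Influence screening

The original analysis excluded subjects with extreme measurements for
their undue influence on an initial regression. Two statistics are
offered. The default is the hat-matrix leverage of the additive design
(a monotone function of the covariate Mahalanobis distance) with threshold
0.5: a clean cohort's maximum leverage is ≈ 0.06 while a single 50-SD
assay value lifts its subject above 0.75, so the screen is sharp and
outcome-independent. Cook's distance from the additive logistic fit
(threshold 4/n) is available as `statistic="cooks"`, with a caveat: with a
~5% outcome the 4/n flag set is dominated by ordinary cases — the IRLS
weight of a saturated, far-out control vanishes, so the classic diagnostic
is blind to exactly the extreme-measurement subjects the screen targets.
Because the synthetic generator produces no extreme assay values, default
runs exclude nobody; the screen earns its keep on real, heavy-tailed data.

## Learners

* **Lasso** — L1-penalized logistic regression over a 20-point λ grid
  spanning four decades below the null-model λ_max; λ by 10-fold
  cross-validated mean binomial deviance; importance |β| at that λ
  (standardized features make magnitudes comparable; sign is direction,
  not importance); AUC = mean fold AUC at the chosen λ.
* **MARS** — forward addition of reflected hinge pairs at quantile-spaced
  candidate knots (30 per variable by default), additive by default
  (`max_degree=1`, GCV penalty 2 per knot; 3 with interactions), backward
  pruning to the minimum-GCV subset, binary outcomes fitted by least
  squares on 0/1 with scores thresholded only for ROC. Importance is the
  GCV reduction at each forward step, credited to the entering variable
  and kept only for variables still present after pruning. The restriction
  is per variable rather than per term: the backward pass may swap an
  early hinge pair for a numerically equivalent later copy on the same
  variable, and a per-term rule would then silently delete the credit.
  Candidate evaluation is exact (projection off an orthonormal basis of
  the current model), not heuristic.
* **Random forest** — 500 trees, mtry = ⌊√p⌋, unlimited depth, Gini
  splitting. Importance is the classic per-tree out-of-bag permutation
  scheme: error on the tree's OOB subjects after minus before permuting
  one variable within the OOB set, averaged over trees; negatives are
  floored at zero before rescaling so relative scores stay in [0, 100].
  The model AUC is computed from OOB predicted class fractions.
* **Boosted trees** — gradient boosting of depth-3 regression trees on the
  binomial deviance, shrinkage 0.1, subsample 0.5; ensemble size by
  10-fold cross-validated AUC over staged predictions (evaluated every 5
  trees); importance is the cumulative squared-error split improvement on
  each variable over trees 1..size.

Common layer: raw importances are rescaled to a top score of 100;
selection at ≥ 20 (boundary inclusive); ranks use the average-rank tie
convention so all zero-importance variables share one rank, giving every
variable a rank under every learner.

## Aggregation and vote

Weights are the learners' model AUCs normalized to sum to one; the
aggregated rank is the weighted mean of per-learner ranks (the weighted
*average* is used: an unnormalized weighted sum would not be a rank).
Majority = at least 3 of 4 selections. Permuting the learners, or scaling
all AUCs by a constant, provably changes nothing.

## Evaluation

Linear-kernel SVM (cost 1) on the already-standardized consensus columns.
Each of B = 100 bootstrap replicates trains on an n-out-of-n resample and
scores only the subjects not drawn — out-of-replicate scoring avoids the
optimism of resubstitution, which the source tooling leaves unspecified.
Replicate ROC curves are interpolated onto a fixed 101-point FPR grid and
averaged vertically; the AUC point estimate is the mean replicate AUC and
the 95% CI the 2.5/97.5 percentiles of the replicate AUC distribution.
Single-class replicates are redrawn (capped at 10·B).

## Clustering

Proximity = fraction of all trees (not OOB-restricted; a flag could narrow
this) in which two subjects share a terminal node. Classical (Torgerson)
MDS treats 1 − proximity as squared dissimilarity: double-center,
eigendecompose, scale the top eigenvectors by √eigenvalue; requested
dimensions beyond the matrix rank are zero-padded with a warning. Label
separation is the mean silhouette of the 2-D embedding under the obesity
labels, defined as 0 when all points coincide.

## Replicated experiments and their scope

`ensemblefs.experiments` wraps the full pipeline in multi-seed loops:

* **Planted recovery** — 20 fresh cohorts; in each, both outcomes are
  analysed end-to-end (preprocess, influence screen, four learners,
  aggregation, vote). Recovery means every planted informative marker
  appears in the consensus with at most one null biomarker among the
  winners. The primary recovery statistic is computed over the union of
  the waist- and BMI-outcome consensus sets, because the planted set spans
  both outcome channels by construction — leptin is reachable only through
  the waist outcome, while the total-adiposity markers may surface through
  either; the waist-only rate is reported alongside. The leptin
  discrimination statistic is per outcome by definition: leptin in the
  waist consensus and absent from the BMI consensus.
* **Null calibration** — outcome labels permuted; learner CV AUCs must
  average in [0.4, 0.6] and the bootstrap CI of the consensus-subset AUC
  must cover 0.5 in ≥ 90% of seeds.

Replicated runs use scaled learner settings (500 trees, boosting capped at
200 trees, 20 candidate knots) — sizes at which single-run results are
indistinguishable from the full defaults on these cohorts — and the null
calibration uses n = 400 cohorts.

What passing these experiments shows: the pipeline's machinery — each
importance scheme, the weighting, the vote — recovers a known planted
signal structure and does not hallucinate signal under the null. What it
does not show: anything about assay noise floors, plate effects, missing
data, non-Gaussian biomarker distributions, or the real cohort's effect
sizes; the published AUCs are not reproducible without the original data,
and no attempt is made to match them.

## Numerical notes

* All randomness flows from explicit seeds; child seeds are spawned via
  `numpy.random.SeedSequence` and kept below 2³¹.
* Z-scoring uses the population SD and is exactly idempotent; a constant
  biomarker column is rejected by name (tolerance 1e-12 relative).
* Fitness binarization: strictly-greater-than-median → 1 (tie convention).
* The MARS forward pass declines candidates whose orthogonalized norm
  falls below 1e-10·n, guarding against collinear hinge pairs; the
  backward pass keeps pruning on GCV ties, preferring smaller models.
* Proximity matrices are validated (symmetry, unit diagonal, [0, 1]);
  MDS eigenvalues may be slightly negative (non-Euclidean proximities) and
  are clipped at zero for coordinates while the full spectrum is reported.

## Known limitations

* MARS importance is intrinsically front-loaded: the first variable to
  enter absorbs the bulk of the GCV drop, so MARS typically anoints one or
  two variables and abstains on the rest; the consensus design absorbs
  this (three votes suffice).
* With ≈ 41 cases (5% of 726), per-seed consensus membership of any single
  correlated marker is stochastic; the recovery experiments quantify
  exactly this.
* The lasso path solver treats the deviance-minimizing λ as flat near its
  minimum; ties resolve to the larger penalty by grid order.
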