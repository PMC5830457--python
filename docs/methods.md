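# Methods

## Problem and data model

The package compares classifiers that combine a four-biomarker panel —
three urine DNA markers (TP53 249T mutation level, methylated RASSF1A,
methylated GSTP1) and serum AFP in ng/mL — into a single probability of
hepatocellular carcinoma, on a case–control cohort of HCC patients
versus cirrhosis/hepatitis controls. A cohort table holds one row per
subject: disease group, the four non-negative marker levels, and
optional demographics (age, gender, HBV, HCV) with explicit
missingness. The binary modeling label is HCC versus pooled controls.
Models use complete biomarker rows only; demographic analyses use
pairwise-complete cases.

## Classifiers

**Logistic regression.** Binomial GLM fitted by iteratively reweighted
least squares, convergence when the largest coefficient change falls
below 1e-8 or after 25 iterations. Complete or quasi-complete
separation is detected (vanishing working weights or exploding
coefficients) and handled by warning and returning the last stable
iterate, so downstream pipelines keep finite scores. Standard errors
come from the inverse Fisher information at the final iterate; a test
cross-checks coefficients and standard errors against an independent
GLM implementation.

**Classification tree (CART).** Gini impurity splits with the
conventional recursive-partitioning controls: a node needs at least 20
subjects to split and leaves keep at least 7. The fully grown tree's
cost-complexity pruning path supplies the candidate complexity values;
each candidate's misclassification error is estimated by stratified
internal 10-fold cross-validation (the "xerror"), and the tree is
pruned at the error-minimizing value, ties resolved toward the larger
penalty (the smaller tree). A single-class training set degenerates to
one leaf rather than an error. Tree growth itself is delegated to
scikit-learn; the selection logic is the package's. A pruned tree emits
at most one distinct probability per leaf — this matters for operating
points, see below.

**Random forest.** Breiman-style bagging: each of 500 trees (default)
is grown unpruned (minimum leaf 1) on an n-out-of-n bootstrap, with 2
of the 4 features drawn as candidates at every split (mtry = 2, the
integer nearest the √p conventions for a four-feature panel; exposed as
a parameter). Out-of-bag membership is recorded per tree; its mean
fraction is ≈ (1 − 1/n)ⁿ ≈ 0.368. The forest probability is the
unweighted mean of tree leaf probabilities. This is a bagged-Gini
forest, not a conditional-inference forest: the permutation-test split
machinery is a heavy dependency with marginal effect on a four-feature
panel, and an independent R implementation remains available for
cross-checks. The discrepancy is absorbed by the tolerance any
cross-validated comparison carries at this cohort size.

**Fixed Sequential (FS).** Subjects with serum AFP at or above the
20 ng/mL screening threshold are assigned probability exactly 1 (the
boundary counts as positive, consistent with the score ≥ cutoff rule
used everywhere); a logistic regression on all four markers, trained on
the AFP-negative training subjects only, scores the rest. With the AFP
cutoff at +∞, FS reduces exactly to plain LR — kept as a tested
identity.

**Two-Step (TS).** The first split replaces AFP with a learned one: a
logistic regression over the panel, thresholded at the cutoff achieving
a 95% specificity floor on its own training scores (no nested holdout —
the cross-validation results show no overfitting signal that would
justify one, and the cutoff is re-learned inside every fold anyway).
First-split positives get probability 1; a forest trained on the
step-1-negative training subjects scores the rest. Training the second
stage on the step-1 negatives only mirrors FS's construction; training
on all subjects is available as a flag. Folds in which a second-stage
training subset is empty or single-class raise a degenerate-split
error, which the harness logs and records as a missing fold entry.

## ROC and dynamic operating points

Scores are compared with the rule *positive iff score ≥ cutoff*. The
ROC curve is the empirical step function over a threshold grid of the
unique scores plus a +∞ sentinel; trapezoidal area over this curve
equals the tie-corrected Mann–Whitney statistic exactly (tested against
the O(n²) pairwise oracle, ties included). Operating points are chosen
at achieved values only — no interpolation: given a specificity floor,
the selector returns the smallest cutoff whose specificity meets the
floor (equivalently maximal sensitivity), and symmetrically for
sensitivity floors. The sentinel guarantees feasibility of any
specificity floor; when a scorer places a point mass among the
negatives (a pruned tree scoring 40% of controls at its higher leaf
value, say), the only feasible cutoff can be the sentinel and the
achieved sensitivity collapses to 0 — the interpolation-free choice is
what makes this deployment-relevant failure visible.

## Cross-validation harness

Folds are stratified: within each class, subjects are shuffled and
dealt round-robin into k = 10 folds, so per-class fold counts differ by
at most one. Each iteration trains all five models on every nine-fold
building set, selects the dynamic cutoffs on building scores
(specificity floors 85/90/95%, sensitivity floors 90/95/99%), applies
them unchanged to the held-out fold, and averages metrics over the ten
folds (pooling held-out predictions before scoring is available as an
option; averaging matches the per-fold cutoff application and is the
default). Iteration i of an experiment uses base_seed + i for its folds
and derives fixed-offset streams per stochastic model, so experiments
are bit-reproducible. Across iterations each metric is summarized by
mean, percentile 95% CI (2.5th/97.5th, linear interpolation —
distribution-free and adequate for the tight intervals these metrics
produce), median, min and max.

## Synthetic cohort

The generator emulates the structure the analysis assumes: 137 HCC, 207
cirrhosis and 224 hepatitis subjects by default; each marker
zero-inflated lognormal per class (zero with probability
1 − detect_prob, else exp(Normal(log_mean, log_sd))); age, gender, HBV
and HCV drawn per class with a 7% missingness mask; markers independent
given class (the real joint dependence is unknown and deliberately not
invented). A single global seed expands into fixed per-marker
substreams, so regenerating one marker never perturbs another.

The default parameters were solved against the closed-form AUC of the
zero-inflated binormal mixture (see `closed_form_auc`), not fitted to
any data: serum AFP (log-mean 0.674/2.926, log-sd 1.0/1.635, always
detected) simultaneously satisfies three published anchors — AUC 0.880,
and specificity 0.990 with sensitivity 0.483 at the 20 ng/mL threshold;
the urine markers hit closed-form AUCs of 0.56 (TP53 249T, detect
probabilities 0.25/0.35), 0.64 (mGSTP1, 0.40/0.55) and 0.70 (mRASSF1A,
0.45/0.65), spanning the published univariate range. Demographic
parameters follow the published study-population table (age 55.3 ± 10.7
vs 61.3 ± 11.4 years; 71% vs 78% male; HBV 78% vs 58%; HCV 31% vs 33%).

What passing tests on this cohort do **not** show: real urine marker
panels have inter-marker correlation, assay floors and batch structure
that independence-given-class cannot mimic, so multivariate model
rankings measured here are properties of the synthetic conditions, not
estimates for any real population. The univariate anchors, by
construction, do transfer. One internal tension of the published
univariate summary is worth noting: the rank-sum statistic is a
monotone function of the empirical AUC, so at 137 vs 431 subjects a
marker with AUC 0.56 cannot produce a rank-sum p below 0.0001; the
generator is calibrated to the printed AUCs and its weakest marker
accordingly tests significant at the 0.05, not the 0.0001, level.

## Numerical conventions

- Chi-square tests on 2×2 demographic tables apply the Yates continuity
  correction (the R default under which the published study-population
  p-values — 0.1315 for gender, 0.0604 for HCV — reproduce exactly);
  the uncorrected statistic is available and tested against the
  Σ(O−E)²/E formula.
- The t-test for age is Welch's (unequal variances).
- Wilcoxon rank-sum: exact enumeration for untied samples with m+n ≤ 20,
  otherwise the normal approximation with midranks, tie correction and
  continuity correction.
- Point-biserial correlations use ln(x + 1) so zero (not-detected)
  marker levels are admissible; the offset is a parameter.
- Quartiles and percentile CIs use linear interpolation (type 7);
  box-plot whiskers are Tukey 1.5·IQR fences.
- All stochastic fits take explicit seeds; there is no hidden global
  random state.

## Problem sizes and limitations

The repeated-CV demonstration in `scripts/acceptance.py` runs 25
iterations of 10-fold CV with 500-tree forests on the 568-subject
synthetic cohort — the package's demonstration scale; the harness
itself has no iteration limit and the full 1,000-iteration experiment
is a single parameter. Known limitations: no regularized logistic
variants, no class weighting, no marker–marker dependence in the
generator, no confidence bands on ROC curves, and the forest is bagged
Gini rather than conditional-inference (a strategy hook on the tree
builder is the intended extension point).
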