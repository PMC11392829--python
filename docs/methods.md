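# Methods

This note documents the models and procedures implemented in `consig`,
the assumptions behind them, the defaults that matter and the places
where the design was genuinely open.

## Consensus signature model

The input is a set of per-cohort DEG tables (gene, log₂ fold change,
adjusted p). The pooled universe — every gene appearing in at least one
table — defines the AML-related genes (ARGs). Stability is quantified
per gene by two statistics:

**GMCS (gene mean consistency score).** We define GMCS as pairwise
co-detection consistency: over all unordered cohort pairs in which the
gene appears in at least one member, the fraction in which it appears in
both. Under the *all-testable* assumption (every gene measurable in
every cohort) this has the closed form `(k−1)/(2D−k−1)` for occurrence
`k` out of `D` cohorts. The definition is a reconstruction: the original
description of the score ("calculated using permutations") is not public,
so we fixed the simplest definition that has the documented qualitative
behaviour — bounded in [0, 1], zero for singletons, one for universal
genes, strictly increasing in occurrence — and an exact brute-force
oracle (explicit pair enumeration, verified for all `k ≤ D ≤ 10`). A
Monte-Carlo estimator over random cohort pairs is exposed
(`gmcs_montecarlo`) and converges to the closed form; it exists to
validate the reconstruction, not for production use.

The all-testable assumption is a documented limitation: per-cohort
tested-gene lists are generally unpublished, so genes missing from a
platform are indistinguishable from genes tested and not called.

**CV.** The coefficient of variation (sample sd / mean, ddof = 1) of
|log₂FC| across detecting cohorts. Absolute values are used so genes
consistently up- and consistently down-regulated are treated
symmetrically; CV is undefined (flagged, excluded from threshold-scan
means) for singletons and zero-mean effects.

**Selection.** Genes with occurrence ≥ t form the signature; the default
t = 6 follows the convention of requiring recurrence in at least six
cohorts out of 26. Members are ordered by descending occurrence, then
lexicographically, so outputs diff cleanly.

**Dataset scores.** RS = |DEG ∩ signature| (integer, quantity-oriented);
DGSE = overlap proportion plus the exact hypergeometric upper tail
P[X ≥ overlap] with parameters (universe, |signature|, |DEG|)
(quality-oriented). The universe defaults to the per-collection
tested-gene count when known, else |union of DEG sets ∪ signature|.

## Cox machinery

The fitter maximises the Efron-corrected partial log-likelihood by
Newton–Raphson with step-halving (the penalized log-likelihood never
decreases between iterations). Efron's correction was chosen over
Breslow as the more accurate standard default; on tie-free data the two
coincide and a fully vectorized path is used. Convergence: max |score|
< 1e-8, cap 50 iterations. An optional ridge term `λ‖β‖²/2` supports
penalized fits. Monotone likelihood (separation) is detected as
|β̂| > 15 after fitting and flagged rather than reported as a converged
estimate. Standard errors come from the inverse observed information;
Wald p-values are two-sided normal.

The univariate screen fits one single-gene model per candidate and keeps
Wald p < α (default 0.05), skipping constant or absent genes with a
logged warning. Forward stepwise selection starts from the empty model
and adds the candidate minimizing AIC (−2ℓ + 2p) until no addition
lowers it, breaking ties lexicographically. AIC entry is deliberately
liberal — a pure-noise candidate clears the 2-point penalty with
probability P[χ²₁ > 2] ≈ 0.16 — so selected models typically carry a
marginal covariate or two beside the true signal; a stricter
likelihood-ratio `p_to_enter` rule is available behind a flag for users
who prefer sparsity over sensitivity. Backward elimination is provided
symmetrically.

Risk scores are the linear predictor βᵀx. Stratification splits at the
training median; samples exactly at the cutoff go to the high-risk group
(≥ rule) so validation-set application is deterministic, and the
training cutoff is carried to validation cohorts by default (recomputing
per cohort is possible by passing no cutoff). The two-group log-rank
test uses the hypergeometric variance with a χ²₁ p-value; Kaplan–Meier
is the standard product-limit estimator. Harrell's C-index counts a pair
as usable when the strictly shorter follow-up had an event, concordant
when that sample also has the higher score, with ½ credit for score
ties; it is checked against an O(n²) double-loop oracle.

## Model-selection framework

A learner is a screen→fit composition. Native fits: full Cox, ridge Cox,
lasso Cox (iteratively reweighted cyclic coordinate descent; λ grid
log-spaced from the all-zero λ_max down to 1% of it, chosen by seeded
inner 5-fold CV on held-out C-index, selected support refitted
unpenalized), and forward/backward stepwise. The registry accepts
externally supplied learners with the same signature, so richer
ensembles (random survival forests, boosting, partial least squares)
can be plugged in without changing the evaluation code; they are not
re-implemented here.

Each learner is fitted once on the training cohort and evaluated by
C-index on every validation cohort; learners are ranked by mean
validation C-index with ties broken by fewer genes, then name. LOOCV on
the training cohort scores each sample with a model fitted without it
and pools the n out-of-fold predictors before computing a single C-index
(per-fold C-indexes are undefined for single left-out samples). Fold
failures are recorded and tolerated up to 20%.

Fixed published signatures (gene lists with coefficients) are compared
via `compare_models`: genes missing from a cohort contribute zero to the
linear predictor (logged); a model missing more than half its genes in a
cohort gets NA there.

## Consensus NMF subtyping

Factorization is multiplicative-update minimization of relative
Frobenius error (KL divergence behind a flag), uniform random
initialization scaled to the data, cap 500 iterations or relative
improvement < 1e-6 over a 10-iteration window; the update never
increases the error. Consensus clustering draws repeated random 80%
sample subsets, assigns each sample to its argmax metagene, and records
co-assignment frequency normalized by co-subsampling frequency; the
diagonal is 1 and never-co-subsampled pairs are flagged.

**Rank selection.** The number of subtypes is read off the consensus
CDFs. The default criterion is the dispersion coefficient
`mean(4(c − ½)²)` over off-diagonal entries — maximal exactly when the
CDF has all its mass at {0, 1}, i.e. when cluster membership is
perfectly reproducible across subsamples ("most cohesive clusters");
ties go to the smallest rank. Two alternatives ship behind a flag: the
cophenetic correlation of the consensus tree, and a delta-area elbow on
the CDF area (`∫F = 1 − mean`). The elbow variant is not the default
for a structural reason: increasing the rank past the truth splits an
existing cluster, which moves a fixed fraction of consensus mass toward
zero and inflates the CDF area by ~0.2 relative on balanced two-block
data *regardless of how unstable the split is*, so an area-gain
threshold systematically over-estimates the rank where a cohesion
measure does not. On planted two-block data the dispersion criterion
recovers rank 2 in 5/5 seeds (score 1.0 vs ≤ 0.75 for higher ranks).

Subtype labels come from cutting an average-linkage tree on
(1 − consensus) at the chosen rank; labels are arbitrary integers and
should be compared as partitions.

## Drug triage

Per-target competition ranks (ties share the minimum rank, so float
noise cannot demote a compound) by ascending affinity. A compound is
prioritized when it meets the affinity cutoff (default −5.0 kcal/mol,
*inclusive*) and ranks within the top n (default 30) on **every**
target; a quorum mode ("at least q targets") is available since
"consistently" also admits that reading.

## Cell-origin classifier

A gradient-boosted tree ensemble (binary logistic objective) on
signature-gene expression only, with the reference hyperparameters:
depth 6, learning rate 0.01, column subsampling 0.5, 1000 rounds,
single-threaded histogram trees for determinism. Cells are called
AML-derived when predicted probability strictly exceeds 0.5 (a
probability of exactly 0.5 is a non-AML call). AUC is the tie-aware
Mann–Whitney estimator. Feature importances aggregate gain, cover and
split frequency per gene over all trees (the per-tree averages reported
by the booster are rescaled by split counts to totals); ranking is by
total gain with cover and frequency as tie-breaks. The boosted-tree
learner itself is treated as a pluggable contract and provided by
xgboost rather than re-implemented.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their configuration including the
seed.

* **DEG collections** — 26 cohorts, a 200-gene planted core detected
  independently per cohort with probability 0.85 (consistent regulation
  sign, |log₂FC| ~ |N(2.0, 0.4)|), 5000 background genes at probability
  0.05 (random sign per cohort); adjusted p uniform on (0, 0.05). These
  rates make the ≥6-of-26 rule cleanly separating:
  P[Bin(26, 0.85) ≥ 6] ≈ 1 while P[Bin(26, 0.05) ≥ 6] ≈ 0.002, giving
  ~99% sensitivity and >90% precision for the planted core.
* **Survival cohorts** — i.i.d. standard-normal expression; event times
  exponential with rate `2e-3 · exp(Σ βg xg)` per day (median survival
  near one year at baseline, an untreated-AML overall-survival scale),
  censoring an independent exponential clock at 1e-3/day (about two
  thirds of samples observe the event). Planted log-hazard coefficients
  attach to named genes.
* **Two-block expression** for subtyping — half the genes mean-shifted
  in one sample block, half in the other, exponentiated to positivity.
* **Cell mixtures** — both classes standard normal; the AML class
  mean-shifted by `shift` on every signature gene.
* **Docking tables** — background affinities uniform on (−4.9, −1.0),
  one planted compound uniform on (−9.0, −6.0) on every target, so the
  planted binder is the unique compound passing −5.0 by construction.

None of this mimics platform-specific noise, batch effects, probe
collapse, library-size artefacts, correlated co-expression modules or
real AML biology. Passing tests therefore demonstrate that the
*algorithms* behave as specified on data with the assumed structure —
recurrence detection, hazard recovery, block recovery, rank selection,
boundary handling — not that the biological findings of any particular
cohort would replicate.

## Problem sizes and reproducibility

The demonstration pipeline uses: the DEG defaults above; a training
cohort of n = 120 with three planted hazard genes (β = 0.8, −0.8, 0.6)
among the signature genes and two validation cohorts of n = 100;
consensus NMF on 100 samples × 60 signature genes, ranks 2–4, 30
subsamples; a 200-compound × 7-target docking table; and 300 cells per
class with a 70/30 train/held-out split. One global seed fans out as
seed + stage index; manifests record per-file SHA-256 checksums and a
rerun with the same configuration is byte-identical. The heavier
calibration experiments in the test suite use 200 replicates (screen
calibration), 20 replicates (hazard recovery and coverage) and 5 seeds
(signature recovery, rank selection, null classifier).

## Known limitations

* GMCS/CV are reconstructions of incompletely published statistics; the
  all-testable assumption overstates occurrence for platform-limited
  genes.
* The stepwise entry rule is AIC by design; users wanting
  noise-free selected sets should use `p_to_enter` (see above).
* Consensus clustering over-reports stability on any fixed noise
  realization; rank selection is only trustworthy when candidate ranks
  differ clearly in dispersion.
* The lasso path uses a full gradient refresh per coordinate update —
  exact but not optimized for large gene panels.
* No proportional-hazards diagnostics, time-dependent covariates or
  clinical-covariate adjustment.
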