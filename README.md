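# consig

Consensus transcriptomic signatures and downstream analysis for acute
myeloid leukaemia (AML).

Transcriptomic studies of AML disagree with each other to a striking
degree: most differentially expressed genes (DEGs) reported by any one
cohort never replicate in another. `consig` implements a meta-analytic
pipeline for researchers who want to extract the *reproducible* part of
that signal and carry it through to clinically oriented endpoints:

1. **Consensus signature discovery** — pool per-cohort DEG lists, score
   every gene's cross-cohort stability, and keep the genes that recur.
2. **Dataset relevance scoring** — quantify how strongly any one cohort
   reflects the consensus (RS / DGSE scores).
3. **Survival risk modelling** — native Cox proportional-hazards
   machinery: univariate prognostic screening, forward-stepwise model
   selection, median-split risk stratification, Kaplan–Meier / log-rank
   comparison and Harrell's C-index benchmarking across validation
   cohorts, with a leave-one-out cross-validation (LOOCV) framework for
   comparing screen→fit learner combinations.
4. **Consensus-NMF subtyping** — repeated non-negative matrix
   factorization on subsamples; the consensus matrix CDF selects the
   number of transcriptomic subtypes.
5. **Drug triage from docking scores** — compounds that bind every model
   target at ≤ −5.0 kcal/mol and rank in the per-target top 30 are
   prioritized.
6. **Single-cell origin classification** — a gradient-boosted tree model
   on signature-gene expression calls whether a cell derives from an AML
   patient (probability > 0.5), evaluated by AUC with gain/cover/frequency
   feature rankings.

Public AML cohorts are not redistributable here, so the package ships a
first-class `synthetic_data` module whose seeded generators reproduce the
statistical structure each stage assumes (a planted recurrent-gene core, a
hazard-linked survival cohort, two-block expression, a planted pan-target
binder, shifted cell mixtures). Every pipeline property is demonstrated
and tested against those planted truths.

## The statistics at the core

For a gene detected as a DEG in `k` of `D` cohorts, the **gene mean
consistency score** is the fraction of cohort pairs that could have
co-detected it in which both actually did; with all genes testable in all
cohorts this is

```
GMCS(k, D) = (k − 1) / (2D − k − 1)
```

(0 for singletons, 1 for genes found everywhere, strictly increasing in
`k`). Effect-size stability is the coefficient of variation of
|log₂ fold change| across detecting cohorts. Genes with occurrence
`k ≥ t` (default `t = 6`) form the consensus signature.

A cohort with DEG set `G` is scored against signature `S` by
`RS = |G ∩ S|` (quantity) and `DGSE = |G ∩ S| / |G|` with an exact
hypergeometric upper-tail enrichment p-value (quality).

Risk models maximise the Cox partial likelihood (Efron tie correction) by
Newton–Raphson with step-halving; the linear predictor `βᵀx` is split at
the training median, and models are compared by Harrell's C-index
`(concordant + ½·tied) / usable pairs` on held-out cohorts.

## Worked example

```
$ consig demo --seed 1 --out demo/
signature: ok {'n_args': 3916, 'n_signature': 214, 'core_sensitivity': 1.0, 'core_precision': 0.9346}
scoring: ok {'mean_rs': 173.88, 'mean_dgse_prop': 0.412}
risk: ok {'n_screened': 12, 'winner': 'StepCox[backward]', 'n_selected': 4,
          'mean_validation_cindex': 0.786, 'train_logrank_p': 3.82e-14}
subtyping: ok {'chosen_rank': 2, ...}
drugs: ok {'prioritized': ['SOLASONINE']}
cells: ok {'train_auc': 1.0, 'test_auc': 1.0}
```

Reading the numbers: 26 synthetic cohorts produced a 3916-gene pooled
universe; the ≥6-occurrence rule kept 214 genes, recovering all 200
planted recurrent genes (sensitivity 1.0) with 93% precision. The
univariate Cox screen kept 12 prognostic candidates, stepwise selection
retained 4, and the winning model separated high- from low-risk patients
decisively (log-rank p ≈ 4e-14) with mean validation C-index 0.79.
Consensus NMF chose 2 subtypes, matching the planted two-block structure;
the planted pan-target binder was the only prioritized compound; and the
cell-origin classifier separated AML-derived from normal cells perfectly
on the shifted mixture. Reruns with the same seed are byte-identical.

The same stages are importable directly (`consig.consensus_signature`,
`consig.survival_risk`, …) and individually exposed on the command line
(`consig signature`, `consig risk train/apply`, `consig subtype`,
`consig drugs`, `consig synth …`).

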