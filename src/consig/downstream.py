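"""Docking-score drug prioritization and signature-based cell-origin calling.

Drug triage follows two conjunctive rules over a compound x target affinity
table: a compound must bind every target at -5.0 kcal/mol or lower
(inclusive) and must rank within the top 30 by affinity on every target.
Rank ties share the minimum (competition) rank so float noise cannot demote
a compound.  A quorum mode relaxes the all-targets conjunction to "at least
q targets".

Cell-origin classification trains a gradient-boosted tree ensemble
(binary logistic objective) on signature-gene expression, calling a cell
AML-derived when its predicted probability strictly exceeds 0.5, and is
evaluated by the tie-aware Mann-Whitney AUC.  Feature importances are
ranked by total gain, with cover and split frequency as tie-breakers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_model import DockingScoreTable, GeneSet, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "DrugPriorityReport",
    "ClassifierConfig",
    "ClassificationReport",
    "prioritize_drugs",
    "train_cell_classifier",
    "predict_cell_origin",
    "auc",
    "feature_importance",
]


@dataclass
class DrugPriorityReport:
    affinity_cutoff: float
    top_n: int
    table: pd.DataFrame  # per compound: min/max affinity, worst rank, flags
    prioritized: list[str]


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the boosted-tree cell-origin model."""

    max_depth: int = 6
    learning_rate: float = 0.01
    colsample: float = 0.5
    n_rounds: int = 1000
    prob_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValidationError("probability threshold must lie in (0, 1)")


@dataclass
class ClassificationReport:
    probabilities: np.ndarray
    calls: np.ndarray  # 1 = AML origin
    auc: float | None
    importances: pd.DataFrame | None = None


def prioritize_drugs(
    table: DockingScoreTable,
    cutoff: float = -5.0,
    top_n: int = 30,
    quorum: int | None = None,
) -> DrugPriorityReport:
    """Select compounds passing the affinity cutoff and top-n rank per target.

    ``quorum=None`` (default) requires both conditions on *every* target;
    ``quorum=q`` requires them on at least q targets.  The -5.0 kcal/mol
    boundary is inclusive ("or lower").
    """
    aff = table.affinity
    if aff.shape[0] < 1 or aff.shape[1] < 1:
        raise ValidationError("docking table must have >= 1 compound and target")
    need = aff.shape[1] if quorum is None else int(quorum)
    if not (1 <= need <= aff.shape[1]):
        raise ValidationError(f"quorum {need} outside [1, {aff.shape[1]}]")

    passes = aff.to_numpy() <= cutoff
    # competition ranks per target, ascending affinity (strongest first)
    ranks = np.column_stack(
        [rankdata(aff.iloc[:, j].to_numpy(), method="min") for j in range(aff.shape[1])]
    )
    in_top = ranks <= top_n
    ok_targets = (passes & in_top).sum(axis=1)
    prioritized_mask = ok_targets >= need

    report = pd.DataFrame(
        {
            "best_affinity": aff.min(axis=1),
            "worst_affinity": aff.max(axis=1),
            "worst_rank": ranks.max(axis=1),
            "n_targets_pass_cutoff": passes.sum(axis=1),
            "n_targets_in_top": in_top.sum(axis=1),
            "n_targets_ok": ok_targets,
            "prioritized": prioritized_mask,
        },
        index=aff.index,
    )
    prioritized = sorted(aff.index[prioritized_mask])
    log.info(
        "drug triage: %d/%d compounds pass cutoff %.1f and top-%d on %s targets",
        len(prioritized), aff.shape[0], cutoff, top_n,
        "all" if quorum is None else f">={need}",
    )
    return DrugPriorityReport(
        affinity_cutoff=cutoff, top_n=top_n, table=report, prioritized=prioritized
    )


# ---------------------------------------------------------------------------
# Cell-origin classifier
# ---------------------------------------------------------------------------


def _restrict_to_signature(X: pd.DataFrame, signature: GeneSet) -> pd.DataFrame:
    present = [g for g in sorted(signature.genes) if g in X.columns]
    missing = len(signature) - len(present)
    if missing:
        log.warning("classifier: %d signature genes absent from the matrix", missing)
    if not present:
        raise ValidationError("no signature genes present in the matrix")
    return X[present]


def train_cell_classifier(
    X: pd.DataFrame,
    labels: np.ndarray,
    signature: GeneSet,
    cfg: ClassifierConfig = ClassifierConfig(),
):
    """Train the boosted-tree origin model on signature-gene expression.

    ``X`` is cells x genes; ``labels`` are 1 for AML-derived cells.  Only
    signature genes are used as features; absent ones are dropped with a
    logged count.  Deterministic for a fixed seed.
    """
    import xgboost as xgb

    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValidationError("training labels contain a single class")
    feats = _restrict_to_signature(X, signature)
    model = xgb.XGBClassifier(
        max_depth=cfg.max_depth,
        learning_rate=cfg.learning_rate,
        colsample_bytree=cfg.colsample,
        n_estimators=cfg.n_rounds,
        objective="binary:logistic",
        random_state=cfg.seed,
        tree_method="hist",
        n_jobs=1,
        verbosity=0,
    )
    model.fit(feats.to_numpy(), labels)
    model._consig_features = list(feats.columns)
    return model


def predict_cell_origin(
    model,
    X: pd.DataFrame,
    threshold: float = 0.5,
    labels: np.ndarray | None = None,
) -> ClassificationReport:
    """Per-cell AML-origin probability and the strict > threshold call.

    A probability exactly at the threshold yields a non-AML call.  When true
    labels are supplied the tie-aware AUC is attached.
    """
    feats = [g for g in model._consig_features if g in X.columns]
    if len(feats) < len(model._consig_features):
        raise ValidationError(
            f"matrix missing {len(model._consig_features) - len(feats)} model features"
        )
    probs = model.predict_proba(X[model._consig_features].to_numpy())[:, 1]
    calls = (probs > threshold).astype(int)
    out_auc = auc(labels, probs) if labels is not None else None
    return ClassificationReport(probabilities=probs, calls=calls, auc=out_auc)


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Tie-aware Mann-Whitney AUC: (concordant + 0.5 tied) / (n_pos * n_neg)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = rankdata(scores, method="average")
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def feature_importance(model, top_k: int = 20) -> pd.DataFrame:
    """Top-k features by total gain, ties broken by cover then frequency."""
    booster = model.get_booster()
    names = model._consig_features
    fmap = {f"f{i}": g for i, g in enumerate(names)}
    rows = {}
    for metric in ("gain", "cover", "weight"):
        scores = booster.get_score(importance_type=metric)
        key = "frequency" if metric == "weight" else metric
        # total_gain/total_cover: get_score gain is the average; rescale by weight
        rows[key] = {fmap.get(f, f): v for f, v in scores.items()}
    df = pd.DataFrame(rows).fillna(0.0)
    if "gain" in df and "frequency" in df:
        df["total_gain"] = df["gain"] * df["frequency"]
        df["total_cover"] = df["cover"] * df["frequency"]
    df = df.sort_values(
        by=["total_gain", "total_cover", "frequency"], ascending=False, kind="stable"
    )
    return df.head(top_k)
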