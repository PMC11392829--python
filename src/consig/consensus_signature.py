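"""Cross-cohort gene consistency scoring and consensus-signature selection.

The meta-analysis works on the union of per-cohort DEG lists (the
"AML-related genes", ARGs — occurrence >= 1 is the membership rule) and
quantifies each gene's cross-cohort reproducibility by two statistics:

* **GMCS** (gene mean consistency score): the fraction of unordered cohort
  pairs that could have detected the gene in which both actually did.
  Under the all-testable assumption (every gene testable in every cohort)
  this has the closed form ``(k - 1) / (2 D - k - 1)`` for a gene detected
  in ``k`` of ``D`` cohorts — 0 for singletons, 1 for genes found
  everywhere, strictly increasing in ``k``.
* **CV**: the coefficient of variation (sample sd / mean) of the absolute
  log2 fold change across the cohorts that detected the gene; undefined for
  singletons.

Genes with occurrence above a threshold ``t`` form the consensus signature
(the study's rule is t = 6).  Individual cohorts are then scored against the
signature by RS (overlap count — quantity-oriented) and DGSE (overlap
proportion plus a hypergeometric enrichment p — quality-oriented).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_model import DEGCollection, GeneSet, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "OccurrenceProfile",
    "GeneStabilityStats",
    "SignatureSet",
    "DatasetScore",
    "count_occurrence",
    "compute_gmcs",
    "gmcs_closed_form",
    "gmcs_montecarlo",
    "compute_effect_cv",
    "gene_stability_table",
    "threshold_scan",
    "select_signature",
    "score_dataset_rs",
    "score_dataset_dgse",
    "score_all_datasets",
]


@dataclass
class OccurrenceProfile:
    """Per-gene occurrence counts with supporting cohort ids."""

    occurrence: dict[str, int]
    supporting: dict[str, frozenset[str]]
    n_datasets: int

    def __post_init__(self):
        bad = {g: k for g, k in self.occurrence.items() if not (1 <= k <= self.n_datasets)}
        if bad:
            raise ValidationError(f"occurrence out of [1, D] for {list(bad)[:5]}")


@dataclass(frozen=True)
class GeneStabilityStats:
    gene: str
    occurrence: int
    gmcs: float
    cv: float | None  # None when undefined (k = 1 or zero mean effect)


@dataclass
class SignatureSet:
    """Consensus signature: genes with occurrence >= threshold, with stats."""

    threshold: int
    genes: GeneSet
    stats: list[GeneStabilityStats]

    def __post_init__(self):
        low = [s.gene for s in self.stats if s.occurrence < self.threshold]
        if low:
            raise ValidationError(f"members below threshold: {low[:5]}")


@dataclass(frozen=True)
class DatasetScore:
    dataset_id: str
    rs: int
    dgse_prop: float
    dgse_p: float


def count_occurrence(collection: DEGCollection) -> OccurrenceProfile:
    """Count, per ARG, how many cohorts list it as a DEG."""
    if collection.n_datasets == 0:
        raise ValidationError("empty DEG collection")
    supporting: dict[str, set[str]] = {}
    for did, recs in collection.datasets:
        for r in recs:
            supporting.setdefault(r.gene, set()).add(did)
    return OccurrenceProfile(
        occurrence={g: len(s) for g, s in supporting.items()},
        supporting={g: frozenset(s) for g, s in supporting.items()},
        n_datasets=collection.n_datasets,
    )


def gmcs_closed_form(k: int, d: int) -> float:
    """GMCS for a gene detected in k of d all-testable cohorts: (k-1)/(2d-k-1)."""
    if d < 2:
        raise ValidationError("GMCS needs at least 2 datasets")
    if not (1 <= k <= d):
        raise ValidationError(f"occurrence {k} outside [1, {d}]")
    return (k - 1) / (2 * d - k - 1)


def compute_gmcs(profile: OccurrenceProfile) -> dict[str, float]:
    """Pairwise co-detection consistency for every ARG in the profile."""
    if profile.n_datasets < 2:
        raise ValidationError("GMCS needs at least 2 datasets")
    return {
        g: gmcs_closed_form(k, profile.n_datasets) for g, k in profile.occurrence.items()
    }


def gmcs_montecarlo(
    k: int, d: int, n_subsets: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo GMCS: sample random cohort pairs and estimate the
    co-detection fraction among pairs touching the gene.

    Converges to the exact pairwise value as ``n_subsets`` grows; exposed for
    validating the closed form, not for production use.
    """
    if d < 2:
        raise ValidationError("GMCS needs at least 2 datasets")
    rng = np.random.default_rng(seed)
    detected = np.zeros(d, dtype=bool)
    detected[:k] = True
    hits = relevant = 0
    for _ in range(n_subsets):
        i, j = rng.choice(d, size=2, replace=False)
        a, b = detected[i], detected[j]
        if a or b:
            relevant += 1
            if a and b:
                hits += 1
    return hits / relevant if relevant else 0.0


def compute_effect_cv(collection: DEGCollection, gene: str) -> float | None:
    """CV of |log2FC| across the cohorts detecting ``gene``.

    Returns None (undefined) for singletons or a zero mean effect.  Raises if
    the gene is not an ARG at all.
    """
    effects = [
        abs(r.logfc)
        for _, recs in collection.datasets
        for r in recs
        if r.gene == gene
    ]
    if not effects:
        raise ValidationError(f"{gene!r} is not present in any dataset")
    if len(effects) < 2:
        return None
    arr = np.asarray(effects)
    mean = arr.mean()
    if mean == 0.0:
        return None
    return float(arr.std(ddof=1) / mean)


def gene_stability_table(collection: DEGCollection) -> pd.DataFrame:
    """Occurrence, GMCS and CV for every ARG, as one tidy table.

    Indexed by gene; CV is NaN where undefined.  This is the single pass the
    threshold scan and signature selection both consume.
    """
    profile = count_occurrence(collection)
    gmcs = compute_gmcs(profile)
    # one pass over all tables instead of per-gene rescans
    effects: dict[str, list[float]] = {}
    for _, recs in collection.datasets:
        for r in recs:
            effects.setdefault(r.gene, []).append(abs(r.logfc))
    rows = []
    for g, k in profile.occurrence.items():
        eff = np.asarray(effects[g])
        if k >= 2 and eff.mean() > 0:
            cv = float(eff.std(ddof=1) / eff.mean())
        else:
            cv = math.nan
        rows.append((g, k, gmcs[g], cv))
    df = pd.DataFrame(rows, columns=["gene", "occurrence", "gmcs", "cv"]).set_index("gene")
    return df.sort_values(["occurrence", "gene"], ascending=[False, True], kind="stable")


def threshold_scan(collection: DEGCollection, profile: OccurrenceProfile | None = None) -> pd.DataFrame:
    """Signature size, mean GMCS and mean CV for every threshold t = 1..D.

    Size is non-increasing in t; CV means exclude genes whose CV is
    undefined.  This is the table used to justify the occurrence cutoff.
    """
    stats = gene_stability_table(collection)
    d = collection.n_datasets
    rows = []
    for t in range(1, d + 1):
        sel = stats[stats["occurrence"] >= t]
        rows.append(
            (
                t,
                len(sel),
                sel["gmcs"].mean() if len(sel) else math.nan,
                sel["cv"].mean() if sel["cv"].notna().any() else math.nan,
            )
        )
    return pd.DataFrame(rows, columns=["threshold", "size", "mean_gmcs", "mean_cv"]).set_index(
        "threshold"
    )


def select_signature(
    collection: DEGCollection, threshold: int, name: str = "consensus_signature"
) -> SignatureSet:
    """Genes with occurrence >= threshold, ordered by descending occurrence
    then lexicographically (deterministic for diffing)."""
    profile = count_occurrence(collection)
    if not (1 <= threshold <= profile.n_datasets):
        raise ValidationError(
            f"threshold {threshold} outside [1, {profile.n_datasets}]"
        )
    stats = gene_stability_table(collection)
    sel = stats[stats["occurrence"] >= threshold]
    if sel.empty:
        raise ValidationError(f"no gene reaches occurrence {threshold}")
    members = [
        GeneStabilityStats(
            gene=g,
            occurrence=int(row["occurrence"]),
            gmcs=float(row["gmcs"]),
            cv=None if math.isnan(row["cv"]) else float(row["cv"]),
        )
        for g, row in sel.iterrows()
    ]
    log.info(
        "signature selection: %d of %d ARGs pass occurrence >= %d",
        len(members), len(stats), threshold,
    )
    return SignatureSet(
        threshold=threshold,
        genes=GeneSet(name=name, genes=frozenset(sel.index)),
        stats=members,
    )


def score_dataset_rs(deg_genes: frozenset[str] | set[str], signature: GeneSet) -> int:
    """RS: the number of a cohort's DEGs that belong to the signature."""
    if len(signature) == 0:
        raise ValidationError("empty signature")
    return len(set(deg_genes) & signature.genes)


def score_dataset_dgse(
    deg_genes: frozenset[str] | set[str],
    signature: GeneSet,
    universe: int,
) -> tuple[float, float]:
    """DGSE: overlap proportion plus exact hypergeometric upper-tail p.

    The p-value is P[X >= overlap] for X ~ Hypergeom(universe, |signature|,
    |deg|): the chance of at least the observed overlap when |deg| genes are
    drawn from the universe at random.
    """
    deg_genes = set(deg_genes)
    if not deg_genes:
        raise ValidationError("empty DEG set")
    if universe < len(deg_genes | signature.genes):
        raise ValidationError(
            f"universe {universe} smaller than |deg U signature| = "
            f"{len(deg_genes | signature.genes)}"
        )
    overlap = len(deg_genes & signature.genes)
    prop = overlap / len(deg_genes)
    p = float(hypergeom.sf(overlap - 1, universe, len(signature), len(deg_genes)))
    return prop, min(p, 1.0)


def score_all_datasets(
    collection: DEGCollection,
    signature: GeneSet,
    universe: int | None = None,
) -> list[DatasetScore]:
    """RS and DGSE for every cohort in the collection.

    The hypergeometric universe defaults to |union of all DEG sets together
    with the signature| when the collection does not carry a tested-gene
    count.
    """
    if universe is None:
        universe = collection.universe_size
    if universe is None:
        universe = len(collection.all_genes() | signature.genes)
    out = []
    for did, degs in collection.deg_sets().items():
        prop, p = score_dataset_dgse(degs, signature, universe)
        out.append(
            DatasetScore(
                dataset_id=did,
                rs=score_dataset_rs(degs, signature),
                dgse_prop=prop,
                dgse_p=p,
            )
        )
    return out
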