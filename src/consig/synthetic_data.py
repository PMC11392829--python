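"""Seeded generators emulating the statistical structure of the study inputs.

Every generator is a pure function of its configuration, including the seed:
the same call yields byte-identical objects.  The generators reproduce the
structure each downstream stage assumes — a planted recurrent-gene core over
a large background for the multi-cohort DEG meta-analysis, hazard-linked
genes with exponential censoring for the survival machinery, mean-shifted
two-population single-cell mixtures for the origin classifier, and a planted
pan-target binder for docking triage.  No attempt is made to mimic platform
noise, batch effects or real AML biology beyond this planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import (
    DEGCollection,
    DEGRecord,
    DockingScoreTable,
    GeneSet,
    SurvivalDataset,
    ValidationError,
)

__all__ = [
    "DEGGenConfig",
    "SurvGenConfig",
    "gen_deg_collection",
    "gen_survival_cohort",
    "gen_cell_mixture",
    "gen_docking_tables",
    "gen_block_expression",
    "core_gene_names",
]


def core_gene_names(n_core: int) -> list[str]:
    """Names of the planted recurrent ("core") genes, CORE0001..COREnnnn."""
    return [f"CORE{i + 1:04d}" for i in range(n_core)]


@dataclass(frozen=True)
class DEGGenConfig:
    """Configuration for the multi-cohort DEG-table generator.

    Defaults mirror the meta-analysis setting: 26 cohorts, a planted core of
    200 recurrent genes detected with probability 0.85 per cohort, and 5000
    background genes detected with probability 0.05.  With these rates the
    >=6-of-26 occurrence rule separates core from background almost
    perfectly: P[Bin(26, 0.85) >= 6] ~ 1 while P[Bin(26, 0.05) >= 6] ~ 0.002.
    """

    n_datasets: int = 26
    n_core: int = 200
    n_background: int = 5000
    p_core: float = 0.85
    p_bg: float = 0.05
    logfc_core_mean: float = 2.0
    logfc_core_sd: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_bg < self.p_core <= 1.0):
            raise ValidationError("need 0 <= p_bg < p_core <= 1")
        if self.n_datasets < 1 or self.n_core < 0 or self.n_background < 0:
            raise ValidationError("counts must be non-negative (>=1 dataset)")


@dataclass(frozen=True)
class SurvGenConfig:
    """Configuration for one synthetic survival cohort.

    Event times are exponential with per-sample rate
    ``baseline_rate * exp(sum_g beta_g x_g)``; censoring is an independent
    exponential clock.  ``baseline_rate`` 2e-3/day puts the median survival
    near one year and ``censor_rate`` 1e-3/day leaves roughly two thirds of
    samples with an observed event — a realistic AML overall-survival regime.
    """

    n_samples: int = 200
    n_genes: int = 100
    planted: tuple[tuple[str, float], ...] = ()
    baseline_rate: float = 2e-3
    censor_rate: float = 1e-3
    seed: int = 0
    cohort_id: str = "synthetic"
    gene_names: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.baseline_rate <= 0 or self.censor_rate < 0:
            raise ValidationError("hazard rates must be positive (censor_rate >= 0)")
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValidationError("need >=2 samples and >=1 gene")


def gen_deg_collection(cfg: DEGGenConfig) -> DEGCollection:
    """Generate per-dataset DEG tables with a planted recurrent core.

    Each core gene enters each dataset's table independently with
    probability ``p_core`` and keeps a consistent regulation sign across
    datasets; each background gene enters with probability ``p_bg`` with a
    sign drawn independently per dataset.  Adjusted p-values are uniform on
    (0, 0.05), i.e. every listed gene already passed significance filtering.
    """
    rng = np.random.default_rng(cfg.seed)
    core = core_gene_names(cfg.n_core)
    background = [f"BG{i + 1:05d}" for i in range(cfg.n_background)]
    # consistent per-gene sign for the core (half up, half down, shuffled)
    core_sign = rng.permuted(np.where(np.arange(cfg.n_core) % 2 == 0, 1.0, -1.0))

    datasets: list[tuple[str, list[DEGRecord]]] = []
    for d in range(cfg.n_datasets):
        records: list[DEGRecord] = []
        take_core = rng.random(cfg.n_core) < cfg.p_core
        lfc_core = np.abs(rng.normal(cfg.logfc_core_mean, cfg.logfc_core_sd, cfg.n_core))
        p_core = rng.uniform(0.0, 0.05, cfg.n_core)
        for i in np.flatnonzero(take_core):
            records.append(
                DEGRecord(gene=core[i], logfc=float(core_sign[i] * lfc_core[i]),
                          adj_p=float(p_core[i]))
            )
        take_bg = rng.random(cfg.n_background) < cfg.p_bg
        sign_bg = rng.choice((-1.0, 1.0), cfg.n_background)
        lfc_bg = np.abs(rng.normal(1.5, 0.5, cfg.n_background)) + 1e-6
        p_bg = rng.uniform(0.0, 0.05, cfg.n_background)
        for i in np.flatnonzero(take_bg):
            records.append(
                DEGRecord(gene=background[i], logfc=float(sign_bg[i] * lfc_bg[i]),
                          adj_p=float(p_bg[i]))
            )
        datasets.append((f"AML{d + 1:02d}", records))
    return DEGCollection(
        datasets=datasets, universe_size=cfg.n_core + cfg.n_background
    )


def gen_survival_cohort(cfg: SurvGenConfig) -> SurvivalDataset:
    """Generate a survival cohort with expression-linked exponential hazards.

    Expression is i.i.d. standard normal (log-scale surrogate); event and
    censoring times are competing exponential clocks, the observed time the
    minimum and the event indicator whether the event clock fired first.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.gene_names is not None:
        if len(cfg.gene_names) != cfg.n_genes:
            raise ValidationError("gene_names length must equal n_genes")
        genes = list(cfg.gene_names)
    else:
        genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, _ in cfg.planted:
        if g not in gene_index:
            raise ValidationError(f"planted gene {g!r} not in the cohort gene list")

    X = rng.standard_normal((cfg.n_genes, cfg.n_samples))
    eta = np.zeros(cfg.n_samples)
    for g, beta in cfg.planted:
        eta += beta * X[gene_index[g]]
    rate = cfg.baseline_rate * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censor_rate, cfg.n_samples)
    else:
        t_cens = np.full(cfg.n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)  # guard: positive follow-up invariant

    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    expr = pd.DataFrame(X, index=genes, columns=samples)
    return SurvivalDataset(expression=expr, time=time, event=event, cohort_id=cfg.cohort_id)


def gen_cell_mixture(
    n_per_class: int,
    signature: GeneSet,
    shift: float,
    seed: int,
    n_background_genes: int = 300,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-population single-cell mixture shifted on the signature genes.

    Returns a cells x genes matrix and binary labels (1 = AML-derived).
    Both classes are standard normal on background genes; the AML class is
    mean-shifted by ``shift`` on every signature gene, so the classes are
    separable on the signature mean for large shifts and indistinguishable
    at shift zero.
    """
    rng = np.random.default_rng(seed)
    sig_genes = sorted(signature.genes)
    genes = sig_genes + [f"NB{i + 1:05d}" for i in range(n_background_genes)]
    n_cells = 2 * n_per_class
    X = rng.standard_normal((n_cells, len(genes)))
    labels = np.repeat([0, 1], n_per_class)
    X[labels == 1, : len(sig_genes)] += shift
    cells = [f"cell{i + 1:05d}" for i in range(n_cells)]
    return pd.DataFrame(X, index=cells, columns=genes), labels


def gen_docking_tables(
    n_compounds: int, n_targets: int, planted_id: str, seed: int
) -> DockingScoreTable:
    """Docking table with one planted pan-target strong binder.

    Background affinities are uniform on (-4.9, -1.0) — never passing a
    -5.0 kcal/mol cutoff — while the planted compound draws uniform
    (-9.0, -6.0) on every target.
    """
    if n_compounds < 1 or n_targets < 1:
        raise ValidationError("need >=1 compound and >=1 target")
    rng = np.random.default_rng(seed)
    compounds = [f"CPD{i + 1:04d}" for i in range(n_compounds)] + [planted_id]
    targets = [f"T{j + 1}" for j in range(n_targets)]
    aff = rng.uniform(-4.9, -1.0, (n_compounds, n_targets))
    planted = rng.uniform(-9.0, -6.0, (1, n_targets))
    table = pd.DataFrame(np.vstack([aff, planted]), index=compounds, columns=targets)
    return DockingScoreTable(affinity=table)


def gen_block_expression(
    genes: list[str],
    n_per_block: tuple[int, int],
    shift: float,
    seed: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Non-negative genes x samples matrix with two planted sample blocks.

    Block 2 is mean-shifted on the first half of the gene list and block 1 on
    the second half; exponentiation makes every entry positive, so the matrix
    is directly factorizable by NMF.  Returns (matrix, true block labels).
    """
    rng = np.random.default_rng(seed)
    n1, n2 = n_per_block
    n = n1 + n2
    X = rng.standard_normal((len(genes), n))
    half = len(genes) // 2
    labels = np.repeat([0, 1], [n1, n2])
    X[:half, labels == 1] += shift
    X[half:, labels == 0] += shift
    V = np.exp(0.5 * X)
    samples = [f"S{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(V, index=genes, columns=samples), labels
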