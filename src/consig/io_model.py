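"""Domain types and readers/writers for every format the pipeline touches.

All tabular interchange is plain text: tab-separated tables with a mandatory
header row and '.' decimal separator, CSV or MatrixMarket for expression
matrices, GMT for gene sets and JSON for reports.  Gene identifiers are
opaque, case-sensitive strings; no alias mapping is attempted.  Expression is
assumed to arrive already normalised and log-scaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import issparse

log = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "DEGRecord",
    "DEGCollection",
    "SurvivalDataset",
    "GeneSet",
    "DockingScoreTable",
    "read_deg_table",
    "write_deg_table",
    "read_deg_collection",
    "write_deg_collection",
    "read_survival_dataset",
    "write_survival_dataset",
    "read_gmt",
    "write_gmt",
    "read_docking_table",
    "write_docking_table",
]


class ValidationError(ValueError):
    """An input violates a domain invariant (range, duplication, shape)."""


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DEGRecord:
    """One differentially expressed gene: symbol, log2 fold change, adjusted p.

    ``direction`` is derived from the sign of ``logfc`` ("up" for positive,
    "down" for negative); a zero log fold change is rejected since such a gene
    is by definition not differentially expressed.
    """

    gene: str
    logfc: float
    adj_p: float

    def __post_init__(self):
        if not self.gene:
            raise ValidationError("gene symbol must be non-empty")
        if not np.isfinite(self.logfc) or self.logfc == 0.0:
            raise ValidationError(
                f"logfc must be finite and non-zero, got {self.logfc!r} for {self.gene}"
            )
        if not (0.0 <= self.adj_p <= 1.0):
            raise ValidationError(
                f"adj_p must lie in [0, 1], got {self.adj_p!r} for {self.gene}"
            )

    @property
    def direction(self) -> str:
        return "up" if self.logfc > 0 else "down"


@dataclass
class DEGCollection:
    """Ordered set of per-dataset DEG tables; the union defines the ARG universe.

    ``universe_size`` optionally records the number of genes tested per
    dataset (used as the hypergeometric universe when scoring datasets).
    """

    datasets: list[tuple[str, list[DEGRecord]]]
    universe_size: int | None = None

    def __post_init__(self):
        ids = [d for d, _ in self.datasets]
        if len(ids) != len(set(ids)):
            raise ValidationError("dataset ids must be unique")
        for did, records in self.datasets:
            genes = [r.gene for r in records]
            if len(genes) != len(set(genes)):
                dupes = sorted({g for g in genes if genes.count(g) > 1})
                raise ValidationError(f"duplicate genes in {did}: {dupes[:5]}")

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    def deg_sets(self) -> dict[str, frozenset[str]]:
        """Per-dataset DEG symbol sets, in collection order."""
        return {did: frozenset(r.gene for r in recs) for did, recs in self.datasets}

    def all_genes(self) -> frozenset[str]:
        """The ARG universe: every gene appearing in at least one table."""
        out: set[str] = set()
        for _, recs in self.datasets:
            out.update(r.gene for r in recs)
        return frozenset(out)


@dataclass
class SurvivalDataset:
    """Expression matrix (genes x samples) with per-sample follow-up.

    ``time`` is follow-up in days (> 0); ``event`` is 1 for an observed event
    and 0 for censoring.  Columns of ``expression`` align with ``time`` and
    ``event``.
    """

    expression: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    cohort_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = self.expression.shape[1]
        if len(self.time) != n or len(self.event) != n:
            raise ValidationError(
                f"expression has {n} samples but time/event have "
                f"{len(self.time)}/{len(self.event)}"
            )
        if np.any(self.time <= 0):
            raise ValidationError("follow-up times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicators must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    def covariate_matrix(self, genes: list[str]) -> np.ndarray:
        """Samples x covariates design matrix for the requested genes."""
        missing = [g for g in genes if g not in self.expression.index]
        if missing:
            raise ValidationError(f"genes absent from cohort {self.cohort_id}: {missing[:5]}")
        return self.expression.loc[genes].to_numpy(dtype=float).T


@dataclass
class GeneSet:
    """A named set of gene symbols (GMT semantics)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        if not self.genes:
            raise ValidationError(f"gene set {self.name} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class DockingScoreTable:
    """Compound x target binding-affinity matrix in kcal/mol (lower = stronger)."""

    affinity: pd.DataFrame  # rows: compounds, columns: targets

    def __post_init__(self):
        if self.affinity.index.duplicated().any():
            raise ValidationError("duplicate compound ids in docking table")
        if self.affinity.columns.duplicated().any():
            raise ValidationError("duplicate target ids in docking table")
        vals = self.affinity.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("docking affinities must be finite")

    @property
    def compounds(self) -> list[str]:
        return list(self.affinity.index)

    @property
    def targets(self) -> list[str]:
        return list(self.affinity.columns)


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

_DEG_COLUMNS = ["gene", "logfc", "adj_p"]


def read_deg_table(path: str | Path, dataset_id: str) -> tuple[str, list[DEGRecord]]:
    """Read one per-dataset DEG table (TSV with header gene/logfc/adj_p)."""
    path = Path(path)
    records: list[DEGRecord] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != _DEG_COLUMNS:
            raise ParseError(f"expected header {_DEG_COLUMNS}, got {header[:3]}", line=1)
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"expected 3 columns, got {len(parts)}", line=lineno)
            gene = parts[0]
            try:
                logfc, adj_p = float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ParseError(f"non-numeric value: {exc}", line=lineno) from exc
            if gene in seen:
                raise ValidationError(f"duplicate gene {gene!r} in {dataset_id}")
            seen.add(gene)
            records.append(DEGRecord(gene=gene, logfc=logfc, adj_p=adj_p))
    return dataset_id, records


def write_deg_table(path: str | Path, records: list[DEGRecord]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_DEG_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.logfc!r}\t{r.adj_p!r}\n")  # repr: lossless floats


def read_deg_collection(directory: str | Path, universe_size: int | None = None) -> DEGCollection:
    """Read every ``*.deg.tsv`` file in a directory as one collection.

    The file stem before ``.deg.tsv`` is the dataset id; files are taken in
    sorted order so the collection is deterministic.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.deg.tsv"))
    if not paths:
        raise ValidationError(f"no *.deg.tsv files under {directory}")
    datasets = [read_deg_table(p, p.name[: -len(".deg.tsv")]) for p in paths]
    return DEGCollection(datasets=datasets, universe_size=universe_size)


def write_deg_collection(directory: str | Path, collection: DEGCollection) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for did, records in collection.datasets:
        write_deg_table(directory / f"{did}.deg.tsv", records)


# ---------------------------------------------------------------------------
# Survival datasets
# ---------------------------------------------------------------------------


def read_survival_dataset(
    expr_path: str | Path,
    clinical_path: str | Path,
    cohort_id: str = "",
) -> SurvivalDataset:
    """Read expression (CSV genes x samples, or MatrixMarket + sidecars) plus
    a clinical TSV with columns sample/time/event.

    Samples are aligned on the id intersection in clinical-table order;
    non-overlapping samples on either side are dropped and counted in the log.
    """
    expr_path = Path(expr_path)
    if expr_path.suffix == ".mtx":
        mat = mmread(expr_path)
        if issparse(mat):
            mat = mat.toarray()
        genes = (expr_path.with_suffix(".genes.txt")).read_text().split()
        samples = (expr_path.with_suffix(".samples.txt")).read_text().split()
        expr = pd.DataFrame(np.asarray(mat), index=genes, columns=samples)
    else:
        expr = pd.read_csv(expr_path, index_col=0)

    clinical = pd.read_csv(clinical_path, sep="\t", dtype={"sample": str})
    for col in ("sample", "time", "event"):
        if col not in clinical.columns:
            raise ParseError(f"clinical table missing column {col!r}", line=1)
    if clinical["sample"].duplicated().any():
        raise ValidationError("duplicate sample ids in clinical table")
    if (clinical["time"] <= 0).any():
        raise ValidationError("clinical table contains non-positive follow-up times")
    if not clinical["event"].isin([0, 1]).all():
        bad = sorted(set(clinical["event"]) - {0, 1})
        raise ValidationError(f"event column contains values other than 0/1: {bad}")

    expr_samples = set(expr.columns)
    keep = clinical[clinical["sample"].isin(expr_samples)]
    dropped_clin = len(clinical) - len(keep)
    dropped_expr = len(expr_samples) - len(keep)
    if len(keep) == 0:
        raise ValidationError("no overlapping samples between expression and clinical tables")
    if dropped_clin or dropped_expr:
        log.info(
            "sample alignment for %s: dropped %d clinical-only, %d expression-only",
            cohort_id or expr_path.name, dropped_clin, dropped_expr,
        )
    order = list(keep["sample"])
    return SurvivalDataset(
        expression=expr[order],
        time=keep["time"].to_numpy(dtype=float),
        event=keep["event"].to_numpy(dtype=int),
        cohort_id=cohort_id,
    )


def write_survival_dataset(
    expr_path: str | Path,
    clinical_path: str | Path,
    ds: SurvivalDataset,
    matrix_market: bool = False,
) -> None:
    expr_path = Path(expr_path)
    if matrix_market:
        mmwrite(expr_path, ds.expression.to_numpy())
        expr_path.with_suffix(".genes.txt").write_text("\n".join(ds.genes) + "\n")
        expr_path.with_suffix(".samples.txt").write_text("\n".join(ds.samples) + "\n")
    else:
        ds.expression.to_csv(expr_path)
    clin = pd.DataFrame({"sample": ds.samples, "time": ds.time, "event": ds.event})
    clin.to_csv(clinical_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: list[GeneSet] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError("GMT line needs name, description and >=1 gene", line=lineno)
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ParseError(f"gene set {name!r} is empty", line=lineno)
            if len(genes) != len(set(genes)):
                log.warning("GMT set %s line %d: duplicate genes deduplicated", name, lineno)
            sets.append(GeneSet(name=name, genes=frozenset(genes)))
    return sets


def write_gmt(path: str | Path, sets: list[GeneSet], description: str = "na") -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Docking tables
# ---------------------------------------------------------------------------


def read_docking_table(path: str | Path) -> DockingScoreTable:
    """TSV matrix: first column compound ids, remaining columns one per target."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric affinity in docking table: {exc}") from exc
    return DockingScoreTable(affinity=df)


def write_docking_table(path: str | Path, table: DockingScoreTable) -> None:
    out = table.affinity.copy()
    out.index.name = "compound"
    out.to_csv(path, sep="\t")
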