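"""Per-cell RBP-target engagement scores and per-cluster summaries.

The score for a cell is the ratio of its summed normalized unspliced counts
over a set of target genes to its normalized RBP count.  Both terms are
normalized by the same per-cell total, so the score reduces to
``sum(unspliced targets) / rbp_count`` and is invariant to library size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXCLUDED = float("nan")


@dataclass
class CellCounts:
    """Paired spliced/unspliced gene x cell integer count matrices.

    Both matrices share gene and cell orderings; ``cluster_labels`` gives a
    cluster index per cell.
    """

    spliced: np.ndarray
    unspliced: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cluster_labels: np.ndarray

    def __post_init__(self) -> None:
        self.spliced = np.asarray(self.spliced)
        self.unspliced = np.asarray(self.unspliced)
        self.cluster_labels = np.asarray(self.cluster_labels)
        if self.spliced.shape != self.unspliced.shape:
            raise ValueError(
                f"spliced {self.spliced.shape} and unspliced "
                f"{self.unspliced.shape} shapes differ"
            )
        n_genes, n_cells = self.spliced.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match matrix columns")
        if len(self.cluster_labels) != n_cells:
            raise ValueError("cluster_labels length does not match cells")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        if (self.spliced < 0).any() or (self.unspliced < 0).any():
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_cells(self) -> int:
        return self.spliced.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not present") from None


@dataclass
class TargetSet:
    """An RBP gene and the set of its target gene identifiers."""

    rbp_gene_id: str
    target_gene_ids: set[str] = field(default_factory=set)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.target_gene_ids = set(self.target_gene_ids)
        if not self.target_gene_ids:
            raise ValueError("target set is empty")
        if self.rbp_gene_id in self.target_gene_ids:
            raise ValueError("rbp_gene_id must not be among its own targets")


@dataclass
class EngagementResult:
    per_cell: pd.DataFrame  # cell_id, cluster, score, excluded
    per_cluster: pd.DataFrame  # cluster, n_cells_used, n_excluded, median_score, ci_low, ci_high


def _prepare(counts: CellCounts, targets: TargetSet, total: str, rbp_counts: str):
    """Resolve gene indices and per-cell vectors used by the score."""
    if targets.rbp_gene_id not in counts.gene_ids:
        raise KeyError(f"RBP gene {targets.rbp_gene_id!r} absent from counts")
    present = [g for g in targets.target_gene_ids if g in set(counts.gene_ids)]
    dropped = len(targets.target_gene_ids) - len(present)
    if not present:
        raise KeyError("no target genes present in the count matrix")
    if dropped:
        logger.warning("dropped %d target genes absent from counts", dropped)
    pos = {g: i for i, g in enumerate(counts.gene_ids)}
    t_idx = np.array([pos[g] for g in present], dtype=int)
    r_idx = pos[targets.rbp_gene_id]

    if total == "spliced":
        n_c = counts.spliced.sum(axis=0).astype(float)
    elif total == "spliced+unspliced":
        n_c = (counts.spliced.sum(axis=0) + counts.unspliced.sum(axis=0)).astype(float)
    else:
        raise ValueError(f"unknown total mode {total!r}")

    if rbp_counts == "spliced":
        r_c = counts.spliced[r_idx].astype(float)
    elif rbp_counts == "spliced+unspliced":
        r_c = (counts.spliced[r_idx] + counts.unspliced[r_idx]).astype(float)
    else:
        raise ValueError(f"unknown rbp_counts mode {rbp_counts!r}")

    u_c = counts.unspliced[t_idx].sum(axis=0).astype(float)
    return u_c, r_c, n_c


def compute_cell_engagement_score(
    counts: CellCounts,
    targets: TargetSet,
    cell: int,
    *,
    total: str = "spliced+unspliced",
    rbp_counts: str = "spliced",
    pseudocount: float = 0.0,
) -> float:
    """Engagement score of a single cell, or NaN when the RBP count is zero.

    score = (sum_{g in targets} u_{g,c} / N_c) / (r_c / N_c)

    with N_c the cell's total read count.  ``pseudocount`` (default off) is
    added to r_c instead of excluding zero-RBP cells.
    """
    u_c, r_c, n_c = _prepare(counts, targets, total, rbp_counts)
    if n_c[cell] <= 0:
        raise ValueError(f"cell {cell} has zero total counts")
    r = r_c[cell] + pseudocount
    if r == 0:
        return EXCLUDED
    return (u_c[cell] / n_c[cell]) / (r / n_c[cell])


def score_all_cells(
    counts: CellCounts,
    targets: TargetSet,
    *,
    total: str = "spliced+unspliced",
    rbp_counts: str = "spliced",
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Score every cell; returns the ``per_cell`` table (order-preserving)."""
    u_c, r_c, n_c = _prepare(counts, targets, total, rbp_counts)
    if (n_c <= 0).any():
        bad = int((n_c <= 0).sum())
        raise ValueError(f"{bad} cells have zero total counts")
    r = r_c + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(r > 0, (u_c / n_c) / np.where(r > 0, r / n_c, 1.0), np.nan)
    return pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "cluster": counts.cluster_labels,
            "score": scores,
            "excluded": r == 0,
        }
    )


def bootstrap_median_ci(
    values: np.ndarray, n_boot: int, rng: np.random.Generator, level: float = 95.0
) -> tuple[float, float]:
    """Percentile-bootstrap CI of the median (seeded, resample with replacement)."""
    values = np.asarray(values, dtype=float)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    medians = np.median(values[idx], axis=1)
    half = (100.0 - level) / 2.0
    lo, hi = np.percentile(medians, [half, 100.0 - half])
    return float(lo), float(hi)


def summarize_by_cluster(
    per_cell: pd.DataFrame,
    *,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median engagement score per cluster with a 95% bootstrap CI.

    Excluded cells (zero RBP count) do not enter the summaries; clusters in
    which every cell is excluded get a null summary and a warning.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if len(per_cell) == 0:
        raise ValueError("empty per-cell table")
    rng = np.random.default_rng(seed)
    rows = []
    for cluster in sorted(per_cell["cluster"].unique()):
        sub = per_cell[per_cell["cluster"] == cluster]
        used = sub[~sub["excluded"]]["score"].to_numpy(dtype=float)
        n_excl = int(sub["excluded"].sum())
        if len(used) == 0:
            logger.warning("cluster %s: all %d cells excluded", cluster, n_excl)
            rows.append((cluster, 0, n_excl, np.nan, np.nan, np.nan))
            continue
        med = float(np.median(used))
        lo, hi = bootstrap_median_ci(used, n_boot, rng)
        rows.append((cluster, len(used), n_excl, med, lo, hi))
    return pd.DataFrame(
        rows,
        columns=["cluster", "n_cells_used", "n_excluded", "median_score", "ci_low", "ci_high"],
    )


def rank_clusters(per_cluster: pd.DataFrame) -> list:
    """Clusters sorted by median score descending; ties by cluster index ascending."""
    if len(per_cluster) == 0:
        raise ValueError("empty per-cluster table")
    df = per_cluster.dropna(subset=["median_score"])
    ordered = df.sort_values(
        ["median_score", "cluster"], ascending=[False, True], kind="mergesort"
    )
    meds = ordered["median_score"].to_numpy()
    if len(meds) != len(set(meds.tolist())):
        logger.info("tied medians broken by ascending cluster index")
    return ordered["cluster"].tolist()


def score_and_summarize(
    counts: CellCounts,
    targets: TargetSet,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    total: str = "spliced+unspliced",
    rbp_counts: str = "spliced",
    pseudocount: float = 0.0,
) -> EngagementResult:
    per_cell = score_all_cells(
        counts, targets, total=total, rbp_counts=rbp_counts, pseudocount=pseudocount
    )
    per_cluster = summarize_by_cluster(per_cell, n_boot=n_boot, seed=seed)
    return EngagementResult(per_cell=per_cell, per_cluster=per_cluster)
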