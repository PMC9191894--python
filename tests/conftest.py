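"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
plain loops, per-base counters and exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from rbp_engage.annotation import CATEGORIES, NONCODING, GeneModel, GenomeAnnotation
from rbp_engage.engagement import CellCounts, TargetSet


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_counts() -> CellCounts:
    """3 genes x 4 cells; gene order: RBP, two targets."""
    spliced = np.array(
        [[4, 5, 0, 8],
         [1, 0, 2, 3],
         [2, 1, 0, 5]]
    )
    unspliced = np.array(
        [[0, 1, 0, 2],
         [2, 5, 1, 0],
         [3, 0, 0, 4]]
    )
    return CellCounts(
        spliced=spliced,
        unspliced=unspliced,
        gene_ids=["RBP", "g1", "g2"],
        cell_ids=[f"c{i}" for i in range(4)],
        cluster_labels=np.array([0, 0, 1, 1]),
    )


@pytest.fixture
def toy_targets() -> TargetSet:
    return TargetSet(rbp_gene_id="RBP", target_gene_ids={"g1", "g2"})


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two genes on chr1 (one per strand) plus one on chr2.

    geneA (+): 0..3000, exons [0,1200) and [2200,3000), CDS 200..2800
      -> 5'UTR [0,200), 3'UTR [2800,3000), intron [1200,2200) (1000 nt:
         proximal 500 each side, no distal at the default window).
    geneB (-): 4000..9000, exons [4000,5500) and [7500,9000), CDS 4300..8600
      -> 3'UTR [4000,4300), 5'UTR [8600,9000), intron [5500,7500)
         (2000 nt: 500 proximal each side, 1000 distal).
    """
    return GenomeAnnotation(
        genes=[
            GeneModel("geneA", "chr1", "+", 0, 3000, [(0, 1200), (2200, 3000)], 200, 2800),
            GeneModel("geneB", "chr1", "-", 4000, 9000, [(4000, 5500), (7500, 9000)], 4300, 8600),
            GeneModel("geneC", "chr2", "+", 100, 2100, [(100, 2100)], 300, 1900),
        ]
    )


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def naive_engagement_scores(
    counts: CellCounts, targets: TargetSet, total: str = "spliced+unspliced"
) -> list[float]:
    """Straight-line per-cell reimplementation of the score formula."""
    out = []
    target_rows = [i for i, g in enumerate(counts.gene_ids) if g in targets.target_gene_ids]
    rbp_row = counts.gene_ids.index(targets.rbp_gene_id)
    for c in range(counts.n_cells):
        n_c = 0.0
        for g in range(counts.n_genes):
            n_c += counts.spliced[g, c]
            if total == "spliced+unspliced":
                n_c += counts.unspliced[g, c]
        u = 0.0
        for g in target_rows:
            u += counts.unspliced[g, c]
        r = float(counts.spliced[rbp_row, c])
        if r == 0:
            out.append(float("nan"))
        else:
            out.append((u / n_c) / (r / n_c))
    return out


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational enumeration over the margins."""
    n1, n2 = a + b, c + d
    ncol = a + c
    M = n1 + n2

    def pmf(k: int) -> Fraction:
        return Fraction(comb(n1, k) * comb(n2, ncol - k), comb(M, ncol))

    p_obs = pmf(a)
    gamma = Fraction(10**7 + 1, 10**7)  # guard against ties lost to rounding
    total = Fraction(0)
    for k in range(max(0, ncol - n2), min(ncol, n1) + 1):
        p = pmf(k)
        if p <= p_obs * gamma:
            total += p
    return float(min(total, Fraction(1)))


def hypergeom_tail_enumeration(k: int, size_a: int, size_b: int, n: int) -> float:
    """Exact upper-tail P(X >= k) by rational summation (small universes)."""
    total = Fraction(0)
    for x in range(k, min(size_a, size_b) + 1):
        total += Fraction(comb(size_a, x) * comb(n - size_a, size_b - x), comb(n, size_b))
    return float(total)


def brute_force_reldist(query: pd.DataFrame, reference: pd.DataFrame):
    """All-pairs scan version of the relative-distance statistic."""
    dists, skipped = [], 0
    for chrom in query["chrom"].unique():
        q = query[query["chrom"] == chrom]
        r = reference[reference["chrom"] == chrom]
        rmid = sorted((r["start"] + r["end"]) / 2.0)
        for _, row in q.iterrows():
            x = (row["start"] + row["end"]) / 2.0
            if len(rmid) < 2 or x < rmid[0] or x > rmid[-1]:
                skipped += 1
                continue
            best = None
            for left, right in zip(rmid, rmid[1:]):
                if left <= x <= right:
                    d = 0.0 if right == left else min(x - left, right - x) / (right - left)
                    best = d if best is None else min(best, d)
            dists.append(best)
    return np.asarray(dists), skipped


def per_base_feature_totals(
    chrom: str, start: int, end: int, strand: str,
    annotation: GenomeAnnotation, proximal_window: int = 500,
) -> dict[str, int]:
    """Per-base membership counter over every same-strand gene segment."""
    totals = dict.fromkeys(CATEGORIES, 0)
    for pos in range(start, end):
        for g in annotation.genes_on(chrom):
            if g.strand != strand:
                continue
            for cat, segs in g.feature_segments(proximal_window).items():
                for s, e in segs:
                    if s <= pos < e:
                        totals[cat] += 1
    return totals


def brute_force_assign(chrom, start, end, strand, annotation, proximal_window=500) -> str:
    totals = per_base_feature_totals(chrom, start, end, strand, annotation, proximal_window)
    if sum(totals.values()) == 0:
        return NONCODING
    best = max(totals.values())
    for cat in CATEGORIES:  # priority order
        if totals[cat] == best:
            return cat
    raise AssertionError("unreachable")


def per_base_metagene(intervals: pd.DataFrame, annotation: GenomeAnnotation, n_bins: int):
    """Per-base brute-force histogram: each covered base contributes its
    1-nt-wide unit-coordinate interval, split across bins."""
    prof = np.zeros(n_bins)
    for g in annotation.genes:
        L = g.length
        sub = intervals[intervals["chrom"] == g.chrom]
        if "strand" in intervals.columns:
            sub = sub[sub["strand"] == g.strand]
        for _, r in sub.iterrows():
            for pos in range(max(int(r["start"]), g.tx_start), min(int(r["end"]), g.tx_end)):
                if g.strand == "+":
                    u0, u1 = (pos - g.tx_start) / L, (pos + 1 - g.tx_start) / L
                else:
                    u0, u1 = (g.tx_end - pos - 1) / L, (g.tx_end - pos) / L
                for i in range(n_bins):
                    seg = min(u1, (i + 1) / n_bins) - max(u0, i / n_bins)
                    if seg > 0:
                        prof[i] += seg / (u1 - u0)
    if prof.sum() > 0:
        prof /= prof.sum()
    return prof
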