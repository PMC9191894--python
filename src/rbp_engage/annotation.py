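"""Gene models and interval statistics.

Covers peak-to-feature assignment, feature distributions, metagene
percentile profiles, the relative-distance colocalization statistic,
splicing-event matching between datasets, and the hypergeometric gene-set
overlap test.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

# feature categories; order doubles as the tie-break priority
CATEGORIES = ["3UTR", "5UTR", "CDS", "proximal_intron", "distal_intron"]
NONCODING = "noncoding/other"

DEFAULT_PROXIMAL_WINDOW = 500


@dataclass
class GeneModel:
    """One stranded gene model with exon blocks and a CDS extent."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (self.tx_start < self.tx_end):
            raise ValueError("tx_start must be < tx_end")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError("CDS must lie within the transcript")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError("exon blocks overlap")
        for s, e in exons:
            if s >= e or s < self.tx_start or e > self.tx_end:
                raise ValueError("exon block outside transcript")
        self.exons = exons

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    def intron_segments(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return out

    def _exonic_clip(self, lo: int, hi: int) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            a, b = max(s, lo), min(e, hi)
            if a < b:
                out.append((a, b))
        return out

    def cds_segments(self) -> list[tuple[int, int]]:
        return self._exonic_clip(self.cds_start, self.cds_end)

    def utr5_segments(self) -> list[tuple[int, int]]:
        if self.strand == "+":
            return self._exonic_clip(self.tx_start, self.cds_start)
        return self._exonic_clip(self.cds_end, self.tx_end)

    def utr3_segments(self) -> list[tuple[int, int]]:
        if self.strand == "+":
            return self._exonic_clip(self.cds_end, self.tx_end)
        return self._exonic_clip(self.tx_start, self.cds_start)

    def feature_segments(self, proximal_window: int = DEFAULT_PROXIMAL_WINDOW):
        """Map category -> list of (start, end) genomic segments.

        Intronic positions within ``proximal_window`` nt of either flanking
        exon boundary are proximal intron; the remainder is distal.
        """
        prox, dist = [], []
        for s, e in self.intron_segments():
            if e - s <= 2 * proximal_window:
                prox.append((s, e))
            else:
                prox.append((s, s + proximal_window))
                prox.append((e - proximal_window, e))
                dist.append((s + proximal_window, e - proximal_window))
        return {
            "3UTR": self.utr3_segments(),
            "5UTR": self.utr5_segments(),
            "CDS": self.cds_segments(),
            "proximal_intron": prox,
            "distal_intron": dist,
        }


@dataclass
class GenomeAnnotation:
    """A collection of gene models, indexed by chromosome."""

    genes: list[GeneModel]
    _by_chrom: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_ids in annotation")
        self._by_chrom = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)

    def __len__(self) -> int:
        return len(self.genes)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    def overlapping_genes(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[str]:
        """gene_ids whose transcript extent overlaps [start, end) by >=1 nt."""
        out = []
        for g in self.genes_on(chrom):
            if strand is not None and g.strand != strand:
                continue
            if max(start, g.tx_start) < min(end, g.tx_end):
                out.append(g.gene_id)
        return out


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def assign_peak_feature(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    annotation: GenomeAnnotation,
    *,
    proximal_window: int = DEFAULT_PROXIMAL_WINDOW,
) -> str:
    """Feature category of an interval: maximal overlap across same-strand
    gene segments; ties broken by 3UTR > 5UTR > CDS > proximal > distal
    intron; no gene overlap gives 'noncoding/other'."""
    if start >= end:
        raise ValueError("malformed interval (start >= end)")
    totals = dict.fromkeys(CATEGORIES, 0)
    for g in annotation.genes_on(chrom):
        if g.strand != strand:
            continue
        for cat, segs in g.feature_segments(proximal_window).items():
            for s, e in segs:
                totals[cat] += _overlap(start, end, s, e)
    if sum(totals.values()) == 0:
        return NONCODING
    return max(CATEGORIES, key=lambda c: (totals[c], -CATEGORIES.index(c)))


def feature_distribution(
    intervals: pd.DataFrame,
    annotation: GenomeAnnotation,
    *,
    proximal_window: int = DEFAULT_PROXIMAL_WINDOW,
) -> pd.DataFrame:
    """Counts and fractions of intervals per feature category.

    ``intervals`` needs chrom/start/end/strand columns.
    """
    if len(intervals) == 0:
        raise ValueError("no intervals")
    cats = [
        assign_peak_feature(
            r["chrom"], int(r["start"]), int(r["end"]), r["strand"], annotation,
            proximal_window=proximal_window,
        )
        for _, r in intervals.iterrows()
    ]
    order = CATEGORIES + [NONCODING]
    counts = pd.Series(cats).value_counts().reindex(order, fill_value=0)
    return pd.DataFrame(
        {"category": order, "count": counts.to_numpy(),
         "fraction": counts.to_numpy() / len(intervals)}
    )


def _spread_uniform(u0: float, u1: float, weight: float, out: np.ndarray) -> None:
    """Deposit ``weight`` uniformly over [u0, u1) across the bins of ``out``."""
    n = len(out)
    if u1 <= u0:
        return
    lo = max(0, int(np.floor(u0 * n)))
    hi = min(n - 1, int(np.ceil(u1 * n)) - 1)
    dens = weight / (u1 - u0)
    for i in range(lo, hi + 1):
        seg = min(u1, (i + 1) / n) - max(u0, i / n)
        if seg > 0:
            out[i] += dens * seg


def metagene_profile(
    intervals: pd.DataFrame,
    annotation: GenomeAnnotation,
    n_bins: int = 100,
    *,
    stranded: bool = True,
) -> np.ndarray:
    """Normalized per-bin coverage of intervals over gene bodies.

    Each gene body maps to [0, 1] from 5' to 3' (minus-strand genes are
    flipped); an interval's overlap with a gene is apportioned to bins by
    fractional base overlap.  The returned profile sums to 1.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    prof = np.zeros(n_bins)
    for g in annotation.genes:
        if g.length == 0:
            raise ValueError(f"zero-length gene {g.gene_id}")
        sub = intervals[intervals["chrom"] == g.chrom]
        if stranded and "strand" in intervals.columns:
            sub = sub[sub["strand"] == g.strand]
        for _, r in sub.iterrows():
            a = max(int(r["start"]), g.tx_start)
            b = min(int(r["end"]), g.tx_end)
            if a >= b:
                continue
            if g.strand == "+":
                u0 = (a - g.tx_start) / g.length
                u1 = (b - g.tx_start) / g.length
            else:
                u0 = (g.tx_end - b) / g.length
                u1 = (g.tx_end - a) / g.length
            _spread_uniform(u0, u1, float(b - a), prof)
    total = prof.sum()
    if total > 0:
        prof = prof / total
    return prof


def relative_distance(
    query: pd.DataFrame, reference: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame, int]:
    """Relative distance of query interval midpoints to the two flanking
    reference midpoints, per chromosome (bedtools-reldist style).

    For a query midpoint x with flanking reference midpoints L <= x <= R:
    d = min(x - L, R - x) / (R - L), in [0, 0.5].  Queries outside the
    reference midpoint span on their chromosome are skipped and counted.

    Returns (distances, histogram with 0.01-wide bins, n_skipped).
    """
    if len(reference) == 0:
        raise ValueError("empty reference")
    dists: list[float] = []
    skipped = 0
    for chrom, qsub in query.groupby("chrom"):
        ref = reference[reference["chrom"] == chrom]
        rmid = np.sort((ref["start"].to_numpy() + ref["end"].to_numpy()) / 2.0)
        qmid = (qsub["start"].to_numpy() + qsub["end"].to_numpy()) / 2.0
        if len(rmid) < 2:
            skipped += len(qmid)
            continue
        inside = (qmid >= rmid[0]) & (qmid <= rmid[-1])
        skipped += int((~inside).sum())
        for x in qmid[inside]:
            j = np.searchsorted(rmid, x, side="right")
            j = min(max(j, 1), len(rmid) - 1)
            left, right = rmid[j - 1], rmid[j]
            if right == left:
                dists.append(0.0)
            else:
                dists.append(float(min(x - left, right - x) / (right - left)))
    d = np.asarray(dists)
    edges = np.round(np.arange(0, 0.51 + 1e-9, 0.01), 10)
    counts, _ = np.histogram(d, bins=edges)
    # fold the d == 0.5 boundary into the last true bin
    hist = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    hist = hist[hist["bin_low"] < 0.5].copy()
    hist.loc[hist.index[-1], "count"] += int((d == 0.5).sum()) if len(d) else 0
    hist["fraction"] = hist["count"] / max(len(d), 1)
    return d, hist.reset_index(drop=True), skipped


@dataclass
class SplicingEventSet:
    """Differential-splicing intron events (consumed, never computed)."""

    events: pd.DataFrame  # chrom, strand, intron_start, intron_end, cluster_id, dPSI, fdr

    def __post_init__(self) -> None:
        need = ["chrom", "strand", "intron_start", "intron_end"]
        missing = [c for c in need if c not in self.events.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        ev = self.events
        if (ev["intron_start"] >= ev["intron_end"]).any():
            raise ValueError("intron_start must be < intron_end")
        if "fdr" in ev.columns and ((ev["fdr"] < 0) | (ev["fdr"] > 1)).any():
            raise ValueError("fdr outside [0, 1]")
        if "dPSI" in ev.columns and (ev["dPSI"].abs() > 1).any():
            raise ValueError("dPSI outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.events)


def match_splicing_events(
    set_a: SplicingEventSet | pd.DataFrame,
    set_b: SplicingEventSet | pd.DataFrame,
    tolerance: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Greedy 1:1 matching of splicing events across two datasets.

    Events match when chrom and strand agree and both intron boundaries
    agree within ``tolerance`` nt.  Candidate pairs are consumed in order of
    increasing total boundary distance (ties by indices), so the matching is
    deterministic.  Returns (matched-pairs table, Jaccard index).
    """
    a = set_a.events if isinstance(set_a, SplicingEventSet) else set_a
    b = set_b.events if isinstance(set_b, SplicingEventSet) else set_b
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both event sets must be non-empty")
    cand = []
    for ia, ra in a.reset_index(drop=True).iterrows():
        for ib, rb in b.reset_index(drop=True).iterrows():
            if ra["chrom"] != rb["chrom"] or ra["strand"] != rb["strand"]:
                continue
            ds = abs(int(ra["intron_start"]) - int(rb["intron_start"]))
            de = abs(int(ra["intron_end"]) - int(rb["intron_end"]))
            if ds <= tolerance and de <= tolerance:
                cand.append((ds + de, ia, ib))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for dist, ia, ib in cand:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ia, ib, dist))
    matched = pd.DataFrame(pairs, columns=["index_a", "index_b", "boundary_distance"])
    jaccard = len(pairs) / (len(a) + len(b) - len(pairs))
    return matched, float(jaccard)


def hypergeometric_overlap(k: int, size_a: int, size_b: int, universe_n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(universe_n, size_a, size_b).

    Computed by log-space summation of the pmf over the upper tail.
    """
    if size_a > universe_n or size_b > universe_n:
        raise ValueError("set sizes exceed the universe")
    if k > min(size_a, size_b):
        raise ValueError("overlap exceeds the smaller set")
    if k < 0:
        raise ValueError("negative overlap")
    if k == 0:
        return 1.0
    ks = np.arange(k, min(size_a, size_b) + 1)
    logp = stats.hypergeom.logpmf(ks, universe_n, size_a, size_b)
    return float(min(1.0, np.exp(logsumexp(logp))))
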