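"""Synthetic inputs with planted ground truth.

Three generators cover every input family the pipeline consumes:

* :func:`simulate_cell_counts` — paired spliced/unspliced gene x cell count
  matrices with cluster labels, a planted RBP expression profile and target
  genes whose unspliced (pre-mRNA) abundance peaks in a chosen cluster.
* :func:`simulate_eclip` — toy gene models, tiled candidate peak windows and
  Poisson IP/input read counts with planted enriched sites.
* :func:`simulate_apa` — per-gene, per-replicate proximal/distal 3'UTR
  isoform abundances with planted shortened/lengthened genes.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation, assign_peak_feature
from .apa import LENGTHENED, SHORTENED, UNCHANGED
from .eclip import PeakSet
from .engagement import CellCounts

logger = logging.getLogger(__name__)


def _check_nonneg_finite(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all() or (arr < 0).any():
        raise ValueError(f"{name} must be finite and nonnegative")
    return arr


def negative_binomial_counts(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """NB counts parameterized by mean and size; Poisson in the size->inf limit.

    Zero means give zero counts exactly.
    """
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if np.isinf(dispersion):
        out[pos] = rng.poisson(mean[pos])
    else:
        r = dispersion
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the single-cell count simulator.

    Clusters are ordered along a pseudo-differentiation axis; the RBP's
    spliced counts follow ``rbp_profile`` per cluster, and target genes'
    unspliced counts follow ``target_unspliced_profile``, which must peak at
    ``target_peak_cluster``.
    """

    n_clusters: int = 4
    cells_per_cluster: int = 50
    n_genes: int = 60
    rbp_profile: tuple[float, ...] = (10.0, 10.0, 10.0, 10.0)
    target_peak_cluster: int = 2
    n_targets: int = 10
    target_unspliced_profile: tuple[float, ...] = (1.0, 1.0, 10.0, 1.0)
    background_mean: float = 2.0
    nb_dispersion: float = 10.0
    libsize_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if not (0 <= self.target_peak_cluster < self.n_clusters):
            raise ValueError("target_peak_cluster out of range")
        if self.cells_per_cluster < 1 or self.n_targets < 1:
            raise ValueError("cells_per_cluster and n_targets must be >= 1")
        if self.n_genes < self.n_targets + 1:
            raise ValueError("n_genes must cover the RBP gene and all targets")
        rbp = _check_nonneg_finite("rbp_profile", self.rbp_profile)
        tgt = _check_nonneg_finite("target_unspliced_profile", self.target_unspliced_profile)
        _check_nonneg_finite("background_mean", [self.background_mean])
        if len(rbp) != self.n_clusters or len(tgt) != self.n_clusters:
            raise ValueError("profiles must have one entry per cluster")
        if tgt[self.target_peak_cluster] < tgt.max():
            raise ValueError("target_unspliced_profile must peak at target_peak_cluster")
        if not (self.nb_dispersion > 0):
            raise ValueError("nb_dispersion must be > 0")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rbp_profile"] = list(self.rbp_profile)
        d["target_unspliced_profile"] = list(self.target_unspliced_profile)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("rbp_profile", "target_unspliced_profile"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimTruth:
    """Planted ground truth of a single-cell simulation."""

    rbp_gene_id: str
    target_gene_ids: list[str]
    target_peak_cluster: int
    expected_cluster_scores: list[float]

    def __post_init__(self) -> None:
        if self.rbp_gene_id in self.target_gene_ids:
            raise ValueError("targets must exclude the RBP gene")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


def simulate_cell_counts(config: SimConfig) -> tuple[CellCounts, SimTruth]:
    """Draw spliced/unspliced count matrices around cluster-specific means.

    Counts are negative binomial around per-cluster means scaled by a
    per-cell log-normal library factor that multiplies both matrices, so the
    engagement score's per-cell normalization can be exercised.
    """
    K = config.n_clusters
    n_cells = K * config.cells_per_cluster
    rng = np.random.default_rng(config.seed)

    rbp_gene = "RBP1"
    targets = [f"TGT{i:04d}" for i in range(config.n_targets)]
    n_bg = config.n_genes - config.n_targets - 1
    background = [f"BG{i:04d}" for i in range(n_bg)]
    gene_ids = [rbp_gene] + targets + background
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    clusters = np.repeat(np.arange(K), config.cells_per_cluster)

    lib = (
        rng.lognormal(mean=0.0, sigma=config.libsize_sigma, size=n_cells)
        if config.libsize_sigma > 0
        else np.ones(n_cells)
    )

    rbp_mu = np.asarray(config.rbp_profile)[clusters]
    tgt_mu = np.asarray(config.target_unspliced_profile)[clusters]

    spliced_mean = np.full((config.n_genes, n_cells), config.background_mean)
    spliced_mean[0] = rbp_mu
    unspliced_mean = np.full((config.n_genes, n_cells), config.background_mean)
    unspliced_mean[1 : 1 + config.n_targets] = tgt_mu

    spliced = negative_binomial_counts(spliced_mean * lib, config.nb_dispersion, rng)
    unspliced = negative_binomial_counts(unspliced_mean * lib, config.nb_dispersion, rng)

    counts = CellCounts(
        spliced=spliced,
        unspliced=unspliced,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cluster_labels=clusters,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.where(
            np.asarray(config.rbp_profile) > 0,
            config.n_targets
            * np.asarray(config.target_unspliced_profile)
            / np.asarray(config.rbp_profile),
            np.nan,
        )
    truth = SimTruth(
        rbp_gene_id=rbp_gene,
        target_gene_ids=targets,
        target_peak_cluster=config.target_peak_cluster,
        expected_cluster_scores=[float(x) for x in expected],
    )
    return counts, truth


# ---------------------------------------------------------------------------
# eCLIP peaks
# ---------------------------------------------------------------------------

@dataclass
class EclipSimConfig:
    """Parameters of the eCLIP peak simulator.

    ``feature_fractions`` allots each gene's length to (5'UTR, CDS exons,
    introns, 3'UTR) and must sum to 1.  True binding sites are placed among
    candidate windows with weights given by ``feature_bias`` on the window's
    feature category; IP reads at true sites are Poisson with rate
    ``background_rate * enrichment_lambda``.
    """

    n_genes: int = 40
    gene_length_range: tuple[int, int] = (2000, 6000)
    feature_fractions: tuple[float, float, float, float] = (0.1, 0.4, 0.3, 0.2)
    n_true_sites: int = 40
    enrichment_lambda: float = 8.0
    background_rate: float = 20.0
    feature_bias: dict[str, float] = field(
        default_factory=lambda: {"3UTR": 4.0, "proximal_intron": 4.0}
    )
    n_bound_genes: int | None = None
    window_size: int = 50
    intergenic_gap: int = 500
    library_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = _check_nonneg_finite("feature_fractions", self.feature_fractions)
        if len(fr) != 4 or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("feature_fractions must be 4 proportions summing to 1")
        if self.n_true_sites > 0 and not self.enrichment_lambda > 1:
            raise ValueError("enrichment_lambda must be > 1")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        lo, hi = self.gene_length_range
        if lo < 10 * self.window_size or hi < lo:
            raise ValueError("gene_length_range too small for the window size")
        if self.window_size < 1 or self.n_genes < 1:
            raise ValueError("window_size and n_genes must be >= 1")
        if self.library_scale < 1:
            raise ValueError("library_scale must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gene_length_range"] = list(self.gene_length_range)
        d["feature_fractions"] = list(self.feature_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EclipSimConfig":
        d = dict(d)
        for key in ("gene_length_range", "feature_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _build_gene(gene_id: str, chrom: str, strand: str, start: int, length: int,
                fractions: tuple[float, float, float, float]) -> GeneModel:
    """One two-exon gene: UTRs at the ends, a single intron inside the CDS."""
    f5, fcds, fint, f3 = fractions
    l5 = max(1, int(round(f5 * length)))
    l3 = max(1, int(round(f3 * length)))
    li = max(1, int(round(fint * length)))
    lcds = length - l5 - l3 - li
    if lcds < 2:
        raise ValueError("gene too short for the requested fractions")
    end = start + length
    # genomic left-to-right: [left UTR][CDS half][intron][CDS half][right UTR]
    left = l5 if strand == "+" else l3
    right = l3 if strand == "+" else l5
    c1 = lcds // 2
    exon1 = (start, start + left + c1)
    exon2 = (start + left + c1 + li, end)
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=end,
        exons=[exon1, exon2],
        cds_start=start + left,
        cds_end=end - right,
    )


def simulate_eclip(
    config: EclipSimConfig,
    *,
    gene_ids: list[str] | None = None,
    bound_gene_ids: list[str] | None = None,
) -> tuple[GenomeAnnotation, PeakSet, pd.DataFrame]:
    """Toy gene models, tiled candidate windows, Poisson IP/input counts.

    ``gene_ids`` overrides the default G#### naming; ``bound_gene_ids``
    (or ``config.n_bound_genes``) restricts true sites to those genes, with
    at least one site per bound gene when counts allow.  Returns the
    annotation, an un-annotated PeakSet and a truth table of planted sites
    (peak_id, gene_id, category).
    """
    rng = np.random.default_rng(config.seed)
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    if len(gene_ids) != config.n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    lo, hi = config.gene_length_range
    genes = []
    pos = 0
    for i, gid in enumerate(gene_ids):
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if i % 2 == 0 else "-"
        genes.append(_build_gene(gid, "chr1", strand, pos, length, config.feature_fractions))
        pos += length + config.intergenic_gap
    annotation = GenomeAnnotation(genes=genes)

    rows = []
    for g in annotation.genes:
        n_win = (g.tx_end - g.tx_start) // config.window_size
        for j in range(n_win):
            s = g.tx_start + j * config.window_size
            rows.append((g.chrom, s, s + config.window_size, g.strand, g.gene_id))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])
    windows.insert(0, "peak_id", [f"peak_{i:06d}" for i in range(len(windows))])
    categories = np.array(
        [
            assign_peak_feature(r["chrom"], r["start"], r["end"], r["strand"], annotation)
            for _, r in windows.iterrows()
        ]
    )

    if bound_gene_ids is None and config.n_bound_genes is not None:
        bound_gene_ids = list(
            rng.choice(gene_ids, size=config.n_bound_genes, replace=False)
        )

    weights = np.array([config.feature_bias.get(c, 1.0) for c in categories], dtype=float)
    is_true = np.zeros(len(windows), dtype=bool)
    if config.n_true_sites > 0:
        eligible = np.ones(len(windows), dtype=bool)
        if bound_gene_ids is not None:
            eligible = windows["gene_id"].isin(bound_gene_ids).to_numpy()
            # guarantee coverage: one weighted draw inside each bound gene first
            for gid in bound_gene_ids:
                idx = np.flatnonzero((windows["gene_id"] == gid).to_numpy() & ~is_true)
                if len(idx) == 0 or is_true.sum() >= config.n_true_sites:
                    break
                w = weights[idx] / weights[idx].sum()
                is_true[rng.choice(idx, p=w)] = True
        remaining = config.n_true_sites - int(is_true.sum())
        pool = np.flatnonzero(eligible & ~is_true)
        if remaining > len(pool):
            raise ValueError("n_true_sites exceeds the eligible candidate windows")
        if remaining > 0:
            w = weights[pool] / weights[pool].sum()
            chosen = rng.choice(pool, size=remaining, replace=False, p=w)
            is_true[chosen] = True

    rate_ip = np.where(
        is_true, config.background_rate * config.enrichment_lambda, config.background_rate
    )
    ip = rng.poisson(rate_ip)
    inp = rng.poisson(np.full(len(windows), config.background_rate))

    ip_total = int(round(max(ip.sum(), 1) * config.library_scale))
    input_total = int(round(max(inp.sum(), 1) * config.library_scale))
    peaks = windows[["peak_id", "chrom", "start", "end", "strand"]].copy()
    peaks["ip_reads"] = ip
    peaks["input_reads"] = inp
    peakset = PeakSet(peaks=peaks, ip_total=ip_total, input_total=input_total)

    truth = windows.loc[is_true, ["peak_id", "gene_id"]].copy()
    truth["category"] = categories[is_true]
    return annotation, peakset, truth.reset_index(drop=True)


# ---------------------------------------------------------------------------
# APA tables
# ---------------------------------------------------------------------------

@dataclass
class ApaSimConfig:
    """Parameters of the 3'UTR isoform abundance simulator."""

    n_genes: int = 200
    n_replicates: int = 3
    frac_shortened: float = 0.15
    frac_lengthened: float = 0.15
    ppau_shift: float = 30.0
    abundance_noise_cv: float = 0.1
    wt_ppau: float = 40.0
    total_abundance: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_shortened <= 1 and 0 <= self.frac_lengthened <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_shortened + self.frac_lengthened > 1:
            raise ValueError("class fractions must sum to <= 1")
        if self.ppau_shift < 0:
            raise ValueError("ppau_shift must be >= 0")
        if not (0 <= self.wt_ppau <= 100):
            raise ValueError("wt_ppau must lie in [0, 100]")
        if self.abundance_noise_cv < 0:
            raise ValueError("abundance_noise_cv must be >= 0")
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ApaSimConfig":
        return cls(**d)


def simulate_apa(config: ApaSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-isoform abundance table plus per-gene truth classes.

    Planted shortened genes have KO PPAU = WT + shift; lengthened genes the
    negative shift (clipped to [0, 100] with a log message); the remainder
    are unshifted.  Noise multiplies isoform abundances log-normally with
    the configured coefficient of variation.
    """
    rng = np.random.default_rng(config.seed)
    n_short = int(round(config.frac_shortened * config.n_genes))
    n_long = int(round(config.frac_lengthened * config.n_genes))
    classes = np.array(
        [SHORTENED] * n_short
        + [LENGTHENED] * n_long
        + [UNCHANGED] * (config.n_genes - n_short - n_long)
    )
    rng.shuffle(classes)
    gene_ids = [f"APA{i:04d}" for i in range(config.n_genes)]

    ko_ppau = np.full(config.n_genes, config.wt_ppau)
    ko_ppau[classes == SHORTENED] += config.ppau_shift
    ko_ppau[classes == LENGTHENED] -= config.ppau_shift
    clipped = (ko_ppau < 0) | (ko_ppau > 100)
    if clipped.any():
        logger.warning("clipping %d KO PPAU values to [0, 100]", int(clipped.sum()))
        ko_ppau = np.clip(ko_ppau, 0.0, 100.0)

    cv = config.abundance_noise_cv
    sigma = np.sqrt(np.log1p(cv**2))

    def noise(size):
        if cv == 0:
            return np.ones(size)
        return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)

    rows = []
    for cond, ppau_vec in (("WT", np.full(config.n_genes, config.wt_ppau)), ("KO", ko_ppau)):
        for rep in range(1, config.n_replicates + 1):
            eps = noise((config.n_genes, 2))
            prox = config.total_abundance * ppau_vec / 100.0 * eps[:, 0]
            dist = config.total_abundance * (1 - ppau_vec / 100.0) * eps[:, 1]
            for i, gid in enumerate(gene_ids):
                rows.append((gid, cond, f"rep{rep}", f"{gid}_P", True, prox[i]))
                rows.append((gid, cond, f"rep{rep}", f"{gid}_D", False, dist[i]))
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "condition", "replicate_id", "isoform_id", "is_proximal", "abundance"],
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "true_class": classes,
         "wt_ppau": config.wt_ppau, "ko_ppau": ko_ppau}
    )
    return table, truth
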