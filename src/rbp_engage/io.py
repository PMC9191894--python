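"""Plain-text readers and writers for the pipeline's file formats.

Matrices go to Matrix Market with TSV sidecars (genes / barcodes /
clusters), gene models to BED12, peaks to BED6 plus a counts TSV with a
JSON totals sidecar.  All TSV outputs carry ``#``-prefixed header lines
naming the producing version and parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from . import __version__
from .annotation import GeneModel, GenomeAnnotation
from .eclip import PeakSet
from .engagement import CellCounts, TargetSet


def _header_lines(params: dict | None) -> str:
    lines = [f"# rbp-engage v{__version__}"]
    for k, v in (params or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- CellCounts -------------------------------------------------------------

def write_cell_counts(counts: CellCounts, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, mat in (("spliced", counts.spliced), ("unspliced", counts.unspliced)):
        mmwrite(outdir / f"{name}.mtx", sparse.csr_matrix(mat))
    (outdir / "genes.tsv").write_text("\n".join(counts.gene_ids) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(counts.cell_ids) + "\n")
    with open(outdir / "clusters.tsv", "w") as fh:
        for cid, cl in zip(counts.cell_ids, counts.cluster_labels):
            fh.write(f"{cid}\t{cl}\n")


def read_cell_counts(outdir: str | Path) -> CellCounts:
    outdir = Path(outdir)
    spliced = np.asarray(mmread(outdir / "spliced.mtx").todense()).astype(np.int64)
    unspliced = np.asarray(mmread(outdir / "unspliced.mtx").todense()).astype(np.int64)
    gene_ids = (outdir / "genes.tsv").read_text().splitlines()
    cell_ids = (outdir / "barcodes.tsv").read_text().splitlines()
    clusters = pd.read_csv(
        outdir / "clusters.tsv", sep="\t", header=None, names=["cell_id", "cluster"]
    )
    return CellCounts(
        spliced=spliced,
        unspliced=unspliced,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cluster_labels=clusters["cluster"].to_numpy(),
    )


# -- TargetSet --------------------------------------------------------------

def write_target_set(targets: TargetSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"rbp_gene_id\t{targets.rbp_gene_id}\n")
        for g in sorted(targets.target_gene_ids):
            fh.write(f"target\t{g}\n")


def read_target_set(path: str | Path, provenance: str = "") -> TargetSet:
    rbp = None
    targets: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, value = line.split("\t")
        if key == "rbp_gene_id":
            rbp = value
        elif key == "target":
            targets.add(value)
        else:
            raise ValueError(f"unexpected row key {key!r} in target set file")
    if rbp is None:
        raise ValueError("target set file lacks the rbp_gene_id header line")
    return TargetSet(rbp_gene_id=rbp, target_gene_ids=targets, provenance=provenance)


# -- gene models (BED12) ----------------------------------------------------

def write_bed12(annotation: GenomeAnnotation, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in annotation.genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.tx_start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
                        g.cds_start, g.cds_end, 0, len(g.exons), sizes, starts,
                    )
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> GenomeAnnotation:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        tx_start = int(f[1])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [(tx_start + st, tx_start + st + sz) for st, sz in zip(starts, sizes)]
        genes.append(
            GeneModel(
                gene_id=f[3], chrom=f[0], strand=f[5],
                tx_start=tx_start, tx_end=int(f[2]),
                exons=exons, cds_start=int(f[6]), cds_end=int(f[7]),
            )
        )
    return GenomeAnnotation(genes=genes)


# -- peaks (BED6 + counts TSV + totals JSON) --------------------------------

def write_peakset(peakset: PeakSet, outdir: str | Path, prefix: str = "peaks") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{prefix}.bed", "w") as fh:
        for _, r in peakset.peaks.iterrows():
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['peak_id']}\t0\t{r['strand']}\n"
            )
    counts = peakset.peaks[["peak_id", "ip_reads", "input_reads"]]
    write_tsv(counts, outdir / f"{prefix}_counts.tsv")
    with open(outdir / f"{prefix}_totals.json", "w") as fh:
        json.dump({"ip_total": peakset.ip_total, "input_total": peakset.input_total}, fh)


def read_peakset(
    bed_path: str | Path, counts_path: str | Path, totals_path: str | Path
) -> PeakSet:
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start", "end", "peak_id", "score", "strand"], comment="#",
    )
    counts = read_tsv(counts_path)
    totals = json.loads(Path(totals_path).read_text())
    peaks = bed.drop(columns=["score"]).merge(counts, on="peak_id", how="inner")
    if len(peaks) != len(bed):
        raise ValueError("peak BED and counts TSV do not agree on peak_ids")
    peaks = peaks[["peak_id", "chrom", "start", "end", "strand", "ip_reads", "input_reads"]]
    return PeakSet(
        peaks=peaks, ip_total=int(totals["ip_total"]), input_total=int(totals["input_total"])
    )


# -- generic BED6 intervals -------------------------------------------------

def read_bed6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"], comment="#",
    )


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            name = r.get("name", ".")
            score = r.get("score", 0)
            strand = r.get("strand", ".")
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{name}\t{score}\t{strand}\n")


def convert_coordinates(df: pd.DataFrame, from_one_based_closed: bool) -> pd.DataFrame:
    """Convert 1-based closed intervals to 0-based half-open (or back)."""
    out = df.copy()
    if from_one_based_closed:
        out["start"] = out["start"] - 1
    else:
        out["start"] = out["start"] + 1
    return out
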