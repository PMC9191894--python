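"""End-to-end orchestration: simulate -> eclip-filter -> targets -> score ->
annotate -> apa, with a reproducibility manifest.

A single global seed is fanned out deterministically to per-stage streams,
so a partial re-run of any stage with the same config reproduces its output
bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .annotation import feature_distribution, metagene_profile
from .apa import ppau_analysis
from .eclip import call_significant, derive_target_set
from .engagement import rank_clusters, score_all_cells, summarize_by_cluster
from .simulate import (
    ApaSimConfig,
    EclipSimConfig,
    SimConfig,
    simulate_apa,
    simulate_cell_counts,
    simulate_eclip,
)

logger = logging.getLogger(__name__)

STAGES = ["simulate_cells", "simulate_eclip", "simulate_apa",
          "eclip_filter", "score", "annotate", "apa"]


@dataclass
class RunConfig:
    """Whole-pipeline configuration; JSON-round-trippable, unknown keys rejected."""

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    outdir: str = "rbp_engage_run"
    log_level: str = "INFO"
    alpha: float = 1e-8
    n_boot: int = 1000
    n_bins: int = 100
    proximal_window: int = 500
    tolerance: int = 0
    total_mode: str = "spliced+unspliced"
    rbp_counts_mode: str = "spliced"
    pseudocount: float = 0.0
    cells_sim: dict = field(default_factory=dict)
    eclip_sim: dict = field(default_factory=dict)
    apa_sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**data)


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0])
        for name, child in zip(STAGES, children)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    Stage outputs land under ``outdir``; the manifest (also written to
    ``manifest.json``) records parameters, per-stage seeds and the sha256 of
    every output file.  Identical config and seed give identical outputs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    requested = [s for s in STAGES if s in config.stages]  # dependency order

    if "simulate_cells" in requested:
        cfg = SimConfig.from_dict({**config.cells_sim, "seed": seeds["simulate_cells"]})
        counts, truth = simulate_cell_counts(cfg)
        io.write_cell_counts(counts, out / "cells")
        (out / "cells" / "truth.json").write_text(truth.to_json())

    cell_truth = None
    truth_path = out / "cells" / "truth.json"
    if truth_path.exists():
        from .simulate import SimTruth

        cell_truth = SimTruth.from_json(truth_path.read_text())

    if "simulate_eclip" in requested:
        cfg = EclipSimConfig.from_dict({**config.eclip_sim, "seed": seeds["simulate_eclip"]})
        gene_ids = None
        bound = None
        if cell_truth is not None:
            # name eCLIP genes after the cell-simulation gene pool so that the
            # derived target set feeds the scoring stage
            bound = list(cell_truth.target_gene_ids)
            n_extra = cfg.n_genes - len(bound)
            if n_extra < 1:
                raise ValueError("eclip n_genes must exceed the planted target count")
            gene_ids = bound + [cell_truth.rbp_gene_id] + [
                f"BG{i:04d}" for i in range(n_extra - 1)
            ]
        annotation, peakset, site_truth = simulate_eclip(
            cfg, gene_ids=gene_ids, bound_gene_ids=bound
        )
        io.write_bed12(annotation, out / "eclip" / "genes.bed")
        io.write_peakset(peakset, out / "eclip")
        io.write_tsv(site_truth, out / "eclip" / "truth_sites.tsv")

    if "simulate_apa" in requested:
        cfg = ApaSimConfig.from_dict({**config.apa_sim, "seed": seeds["simulate_apa"]})
        table, truth = simulate_apa(cfg)
        io.write_tsv(table, out / "apa" / "apa_table.tsv")
        io.write_tsv(truth, out / "apa" / "truth_classes.tsv")

    if "eclip_filter" in requested:
        eclip_dir = out / "eclip"
        if not (eclip_dir / "peaks.bed").exists():
            raise FileNotFoundError(
                "eclip_filter requires peaks.bed/peaks_counts.tsv/peaks_totals.json "
                f"under {eclip_dir}"
            )
        peakset = io.read_peakset(
            eclip_dir / "peaks.bed", eclip_dir / "peaks_counts.tsv",
            eclip_dir / "peaks_totals.json",
        )
        annotated = call_significant(peakset, alpha=config.alpha)
        io.write_tsv(annotated.peaks, eclip_dir / "peaks_annotated.tsv",
                     params={"alpha": config.alpha})
        annotation = io.read_bed12(eclip_dir / "genes.bed")
        rbp = cell_truth.rbp_gene_id if cell_truth is not None else "RBP1"
        targets = derive_target_set(annotated, annotation, rbp)
        io.write_target_set(targets, out / "targets.tsv")

    if "score" in requested:
        if not (out / "cells" / "spliced.mtx").exists():
            raise FileNotFoundError(f"score requires cell counts under {out / 'cells'}")
        if not (out / "targets.tsv").exists():
            raise FileNotFoundError(f"score requires the target set at {out / 'targets.tsv'}")
        counts = io.read_cell_counts(out / "cells")
        targets = io.read_target_set(out / "targets.tsv")
        per_cell = score_all_cells(
            counts, targets, total=config.total_mode,
            rbp_counts=config.rbp_counts_mode, pseudocount=config.pseudocount,
        )
        per_cluster = summarize_by_cluster(
            per_cell, n_boot=config.n_boot, seed=seeds["score"]
        )
        ranking = rank_clusters(per_cluster)
        io.write_tsv(per_cell, out / "score_per_cell.tsv",
                     params={"total": config.total_mode, "rbp_counts": config.rbp_counts_mode})
        io.write_tsv(per_cluster, out / "score_per_cluster.tsv",
                     params={"n_boot": config.n_boot, "seed": seeds["score"]})
        io.write_tsv(
            pd.DataFrame({"rank": range(1, len(ranking) + 1), "cluster": ranking}),
            out / "cluster_ranking.tsv",
        )

    if "annotate" in requested:
        eclip_dir = out / "eclip"
        if not (eclip_dir / "peaks_annotated.tsv").exists():
            raise FileNotFoundError("annotate requires eclip_filter output")
        peaks = io.read_tsv(eclip_dir / "peaks_annotated.tsv")
        sig = peaks[peaks["significant"]]
        annotation = io.read_bed12(eclip_dir / "genes.bed")
        use = sig if len(sig) else peaks
        dist = feature_distribution(use, annotation, proximal_window=config.proximal_window)
        io.write_tsv(dist, out / "feature_distribution.tsv",
                     params={"proximal_window": config.proximal_window})
        prof = metagene_profile(use, annotation, n_bins=config.n_bins)
        io.write_tsv(
            pd.DataFrame({"bin": range(config.n_bins), "coverage": prof}),
            out / "metagene_profile.tsv", params={"n_bins": config.n_bins},
        )

    if "apa" in requested:
        apa_path = out / "apa" / "apa_table.tsv"
        if not apa_path.exists():
            raise FileNotFoundError(f"apa requires the abundance table at {apa_path}")
        table = io.read_tsv(apa_path)
        result = ppau_analysis(table)
        io.write_tsv(result, out / "apa" / "ppau.tsv")

    manifest = {
        "version": __version__,
        "config": json.loads(config.to_json()),
        "stage_seeds": seeds,
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
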