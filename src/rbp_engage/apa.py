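"""Proximal polyA site usage (PPAU), between-condition deltas, and the
shortened/lengthened 3'UTR classification.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

APA_COLUMNS = ["gene_id", "condition", "replicate_id", "isoform_id", "is_proximal", "abundance"]

SHORTENED = "shortened"
LENGTHENED = "lengthened"
UNCHANGED = "unchanged"
UNDETERMINED = "undetermined"

DEFAULT_DELTA_THRESHOLD = 20.0


def validate_apa_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-isoform abundance table invariants.

    Every gene x condition x replicate group must have >=1 isoform with
    exactly one flagged proximal; abundances must be finite and nonnegative.
    """
    missing = [c for c in APA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"APA table missing columns: {missing}")
    ab = table["abundance"].to_numpy(dtype=float)
    if not np.isfinite(ab).all() or (ab < 0).any():
        raise ValueError("abundances must be finite and nonnegative")
    flags = table.groupby(["gene_id", "condition", "replicate_id"])["is_proximal"].sum()
    if (flags != 1).any():
        bad = flags[flags != 1].index[0]
        raise ValueError(f"group {bad} must have exactly one proximal isoform")
    return table


def compute_ppau(abundances, is_proximal) -> float:
    """PPAU = 100 * proximal / total for one gene/replicate; NaN when total 0."""
    ab = np.asarray(abundances, dtype=float)
    prox = np.asarray(is_proximal, dtype=bool)
    if len(ab) == 0:
        raise ValueError("no isoforms")
    if prox.sum() != 1:
        raise ValueError(f"expected exactly one proximal isoform, got {int(prox.sum())}")
    total = ab.sum()
    if total == 0:
        return float("nan")
    return float(100.0 * ab[prox][0] / total)


def delta_ppau(ppau_wt, ppau_ko) -> float:
    """median(KO replicates) - median(WT replicates), in percentage points.

    Undetermined (NaN) replicates are dropped with a log message; if either
    condition loses all replicates, raises.
    """
    wt = np.asarray(ppau_wt, dtype=float)
    ko = np.asarray(ppau_ko, dtype=float)
    n_drop = int(np.isnan(wt).sum() + np.isnan(ko).sum())
    if n_drop:
        logger.info("dropping %d undetermined replicate PPAU values", n_drop)
    wt = wt[~np.isnan(wt)]
    ko = ko[~np.isnan(ko)]
    if len(wt) == 0 or len(ko) == 0:
        raise ValueError("all replicates undetermined in one condition")
    return float(np.median(ko) - np.median(wt))


def classify_apa(delta: float, threshold: float = DEFAULT_DELTA_THRESHOLD) -> str:
    """delta > threshold -> shortened; delta < -threshold -> lengthened;
    otherwise unchanged (strict inequalities: exactly +-threshold is
    unchanged); non-finite -> undetermined."""
    if not np.isfinite(delta):
        return UNDETERMINED
    if delta > threshold:
        return SHORTENED
    if delta < -threshold:
        return LENGTHENED
    return UNCHANGED


def ppau_analysis(
    table: pd.DataFrame,
    *,
    wt_condition: str = "WT",
    ko_condition: str = "KO",
    threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> pd.DataFrame:
    """Full per-gene PPAU/delta/class table from a per-isoform abundance table.

    Output columns: gene_id, per-replicate PPAU columns (ppau_<cond>_<rep>),
    median_ppau_wt, median_ppau_ko, delta_ppau, apa_class.
    """
    validate_apa_table(table)
    rows = []
    for gene_id, sub in table.groupby("gene_id", sort=True):
        reps: dict[str, float] = {}
        per_cond: dict[str, list[float]] = {wt_condition: [], ko_condition: []}
        for (cond, rep), grp in sub.groupby(["condition", "replicate_id"], sort=True):
            p = compute_ppau(grp["abundance"].to_numpy(), grp["is_proximal"].to_numpy())
            reps[f"ppau_{cond}_{rep}"] = p
            if cond in per_cond:
                per_cond[cond].append(p)
        wt = np.asarray(per_cond[wt_condition], dtype=float)
        ko = np.asarray(per_cond[ko_condition], dtype=float)
        wt_ok, ko_ok = wt[~np.isnan(wt)], ko[~np.isnan(ko)]
        if len(wt_ok) == 0 or len(ko_ok) == 0:
            med_wt = float(np.median(wt_ok)) if len(wt_ok) else float("nan")
            med_ko = float(np.median(ko_ok)) if len(ko_ok) else float("nan")
            delta = float("nan")
        else:
            med_wt = float(np.median(wt_ok))
            med_ko = float(np.median(ko_ok))
            delta = med_ko - med_wt
        rows.append(
            {
                "gene_id": gene_id,
                **reps,
                "median_ppau_wt": med_wt,
                "median_ppau_ko": med_ko,
                "delta_ppau": delta,
                "apa_class": classify_apa(delta, threshold),
            }
        )
    return pd.DataFrame(rows)
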