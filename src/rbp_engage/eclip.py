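"""eCLIP peak enrichment: IP-vs-input fold enrichment, Fisher's exact test
with Bonferroni control, and derivation of a target gene set from the
significant peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .engagement import TargetSet

logger = logging.getLogger(__name__)

#: sentinel for fold enrichment of an empty peak (0 reads in both libraries)
FE_UNDEFINED = float("nan")

PEAK_COLUMNS = ["peak_id", "chrom", "start", "end", "strand", "ip_reads", "input_reads"]


@dataclass
class PeakSet:
    """Candidate peak intervals with IP / size-matched-input read counts.

    ``peaks`` holds one row per candidate peak; enrichment statistics
    (``fold_enrichment``, ``p_raw``, ``p_bonf``, ``significant``) are added by
    :func:`call_significant`.  Totals are usable-read library sizes supplied
    as metadata, not recomputed from the candidate windows.
    """

    peaks: pd.DataFrame
    ip_total: int
    input_total: int

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.peaks.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        if self.ip_total <= 0 or self.input_total <= 0:
            raise ValueError("library totals must be positive")
        p = self.peaks
        if (p["start"] >= p["end"]).any():
            raise ValueError("peaks must satisfy start < end")
        if (p["ip_reads"] > self.ip_total).any() or (p["input_reads"] > self.input_total).any():
            raise ValueError("peak read counts exceed library totals")
        if (p[["ip_reads", "input_reads"]] < 0).to_numpy().any():
            raise ValueError("negative read counts")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def significant(self) -> pd.DataFrame:
        if "significant" not in self.peaks.columns:
            raise ValueError("call_significant has not been run")
        return self.peaks[self.peaks["significant"]]


def fold_enrichment(ip_reads, input_reads, ip_total: int, input_total: int):
    """FE = (ip/ip_total) / (input/input_total).

    Vectorized.  input=0 with ip>0 gives +inf; both zero gives NaN.
    """
    if ip_total <= 0 or input_total <= 0:
        raise ValueError("totals must be positive")
    ip = np.asarray(ip_reads, dtype=float)
    inp = np.asarray(input_reads, dtype=float)
    if (ip > ip_total).any() or (inp > input_total).any():
        raise ValueError("reads exceed totals")
    with np.errstate(divide="ignore", invalid="ignore"):
        fe = (ip / ip_total) / (inp / input_total)
    fe = np.where((ip == 0) & (inp == 0), FE_UNDEFINED, fe)
    if fe.ndim == 0:
        return float(fe)
    return fe


def _fisher_two_sided(a: np.ndarray, n1: int, n2: int, b: np.ndarray) -> np.ndarray:
    """Two-sided Fisher p for tables [[a, n1-a], [b, n2-b]], vectorized.

    Enumerates the hypergeometric support in log space.  A table counts
    toward the p-value when its pmf is <= the observed pmf times (1+1e-7),
    the conventional guard against ties lost to rounding.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    M = n1 + n2
    out = np.empty(a.shape, dtype=float)
    for i in np.ndindex(a.shape):
        n = int(a[i] + b[i])  # first-column margin
        lo = max(0, n - n2)
        hi = min(n, n1)
        ks = np.arange(lo, hi + 1)
        # pmf of hypergeom(M, n, n1) at k, in log space
        logpmf = (
            gammaln(n + 1)
            - gammaln(ks + 1)
            - gammaln(n - ks + 1)
            + gammaln(M - n + 1)
            - gammaln(n1 - ks + 1)
            - gammaln(M - n - n1 + ks + 1)
            + gammaln(n1 + 1)
            + gammaln(M - n1 + 1)
            - gammaln(M + 1)
        )
        pmf = np.exp(logpmf)
        p_obs = pmf[int(a[i]) - lo]
        out[i] = min(1.0, float(pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    return out


def fisher_peak_test(ip_reads, input_reads, ip_total: int, input_total: int):
    """Two-sided Fisher's exact p on [[ip, ip_total-ip], [input, input_total-input]].

    Vectorized over peaks; cost scales with ip+input per peak, not with the
    library totals.
    """
    if ip_total <= 0 or input_total <= 0:
        raise ValueError("totals must be positive")
    ip = np.asarray(ip_reads)
    inp = np.asarray(input_reads)
    if (ip > ip_total).any() or (inp > input_total).any():
        raise ValueError("reads exceed totals")
    p = _fisher_two_sided(ip, ip_total, input_total, inp)
    if p.ndim == 0:
        return float(p)
    return p


def call_significant(
    peakset: PeakSet, alpha: float = 1e-8, *, one_sided: bool = False
) -> PeakSet:
    """Annotate a PeakSet with FE, raw and Bonferroni p-values and the
    significance flag: ip_reads > input_reads AND p_bonf < alpha.

    Bonferroni multiplies by the number of candidate peaks tested.
    ``one_sided`` switches to the greater-tail Fisher test.
    """
    m = len(peakset)
    if m == 0:
        raise ValueError("no peaks to test")
    df = peakset.peaks.copy()
    ip = df["ip_reads"].to_numpy()
    inp = df["input_reads"].to_numpy()
    df["fold_enrichment"] = fold_enrichment(ip, inp, peakset.ip_total, peakset.input_total)
    if one_sided:
        from scipy import stats

        p_raw = np.array(
            [
                stats.hypergeom.sf(
                    a - 1, peakset.ip_total + peakset.input_total, a + b, peakset.ip_total
                )
                for a, b in zip(ip, inp)
            ]
        )
    else:
        p_raw = fisher_peak_test(ip, inp, peakset.ip_total, peakset.input_total)
    df["p_raw"] = p_raw
    df["p_bonf"] = np.minimum(1.0, p_raw * m)
    df["significant"] = (ip > inp) & (df["p_bonf"] < alpha)
    return PeakSet(peaks=df, ip_total=peakset.ip_total, input_total=peakset.input_total)


def derive_target_set(
    peakset: PeakSet,
    annotation,
    rbp_gene_id: str,
    *,
    provenance: str = "eCLIP significant peaks",
) -> TargetSet:
    """Genes overlapped (strand-aware, >=1 nt) by at least one significant peak.

    The RBP's own gene stays in the peak report but is removed from the
    returned target set.
    """
    sig = peakset.significant
    if len(sig) == 0:
        raise ValueError(
            "no significant peaks; relax alpha or check counts before deriving targets"
        )
    hits: set[str] = set()
    for _, pk in sig.iterrows():
        for g in annotation.overlapping_genes(
            pk["chrom"], int(pk["start"]), int(pk["end"]), pk["strand"]
        ):
            hits.add(g)
    dropped_self = rbp_gene_id in hits
    hits.discard(rbp_gene_id)
    if dropped_self:
        logger.info("RBP's own gene removed from target set")
    if not hits:
        raise ValueError("significant peaks overlap no genes other than the RBP itself")
    return TargetSet(rbp_gene_id=rbp_gene_id, target_gene_ids=hits, provenance=provenance)
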