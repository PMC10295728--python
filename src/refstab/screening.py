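"""Candidate reference-gene screening from an RNA-seq FPKM matrix.

A good housekeeping candidate is abundantly and *uniformly* expressed across
libraries: high mean FPKM, low coefficient of variation (CV = sample SD /
mean) and low maximum fold change (MFC = max / min).  The screen computes
the three statistics per gene, applies one threshold per statistic and
nominates the intersection of the three pass sets (the Venn-overlap rule).

CV uses the n-1 (sample) standard deviation — appropriate for the small
library counts typical of these designs.  A gene with any zero FPKM has an
undefined MFC, reported as +inf so it fails any finite MFC threshold; a gene
with all-zero FPKM has an undefined CV and is excluded with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = [
    "ScreenThresholds",
    "compute_fpkm_stats",
    "screen_candidates",
    "read_fpkm_matrix",
    "write_screen_report",
]

#: Reconstruction of the published screening regime: the printed candidate
#: table spans mean FPKM 50.26-378.38, CV 0.03-0.06 and MFC 1.11-1.22, so
#: thresholds consistent with those extremes are the package default.  The
#: study's exact cutoffs are not printed; these are configurable.
DEFAULT_MIN_MEAN_FPKM = 50.0
DEFAULT_MAX_CV = 0.06
DEFAULT_MAX_MFC = 1.22


@dataclass(frozen=True)
class ScreenThresholds:
    min_mean_fpkm: float = DEFAULT_MIN_MEAN_FPKM
    max_cv: float = DEFAULT_MAX_CV
    max_mfc: float = DEFAULT_MAX_MFC

    def __post_init__(self):
        for name in ("min_mean_fpkm", "max_cv", "max_mfc"):
            v = getattr(self, name)
            if not np.isfinite(v) and not (v == np.inf and name != "min_mean_fpkm"):
                raise DataError(f"threshold {name} must be finite (or +inf for a max)")
        if self.max_mfc < 1:
            raise DataError("threshold max_mfc must be >= 1")


def read_fpkm_matrix(path) -> pd.DataFrame:
    """Read a genes x samples FPKM TSV (first column gene ids, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise DataError(f"FPKM matrix {path} needs >= 2 sample columns")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene ids in FPKM matrix: {dups}")
    vals = df.to_numpy(dtype=float)
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise DataError("FPKM matrix must be non-negative and finite")
    return df


def compute_fpkm_stats(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean FPKM, CV and MFC.

    Returns a frame indexed by gene with columns ``mean_fpkm, cv, mfc,
    excluded, reason``.  ``excluded`` is True only for all-zero genes
    (CV undefined); genes with some zeros stay in with ``mfc = inf``.
    """
    vals = matrix.to_numpy(dtype=float)
    if matrix.shape[1] < 2:
        raise DataError("compute_fpkm_stats needs >= 2 samples per gene")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
        mn = vals.min(axis=1)
        mx = vals.max(axis=1)
        mfc = np.where(mn > 0, mx / mn, np.inf)
    excluded = mean == 0
    reason = np.where(excluded, "all-zero FPKM: CV undefined", "")
    out = pd.DataFrame(
        {
            "mean_fpkm": mean,
            "cv": cv,
            "mfc": np.where(excluded, np.nan, mfc),
            "excluded": excluded,
            "reason": reason,
        },
        index=matrix.index.copy(),
    )
    out.index.name = "gene"
    return out


def screen_candidates(stats: pd.DataFrame, thresholds: ScreenThresholds = None):
    """Apply the three filters and intersect.

    Returns ``(candidates, membership)``: the sorted candidate gene list and
    a per-gene boolean frame with columns ``pass_fpkm, pass_cv, pass_mfc,
    candidate``.  Genes flagged ``excluded`` by :func:`compute_fpkm_stats`
    fail every filter.  An empty intersection is a valid (warned, not
    raised) outcome.
    """
    thresholds = thresholds or ScreenThresholds()
    ok = ~stats["excluded"].to_numpy()
    pass_fpkm = ok & (stats["mean_fpkm"].to_numpy() >= thresholds.min_mean_fpkm)
    pass_cv = ok & (stats["cv"].to_numpy() <= thresholds.max_cv)
    pass_mfc = ok & (stats["mfc"].to_numpy() <= thresholds.max_mfc)
    membership = pd.DataFrame(
        {
            "pass_fpkm": pass_fpkm,
            "pass_cv": pass_cv,
            "pass_mfc": pass_mfc,
            "candidate": pass_fpkm & pass_cv & pass_mfc,
        },
        index=stats.index.copy(),
    )
    candidates = sorted(membership.index[membership["candidate"]])
    return candidates, membership


def write_screen_report(stats: pd.DataFrame, membership: pd.DataFrame, path) -> None:
    report = stats.drop(columns=["excluded", "reason"]).join(membership)
    report.to_csv(Path(path), sep="\t", float_format="%.6g")
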