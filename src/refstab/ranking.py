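"""Comprehensive rank aggregation (geometric mean of per-method ranks).

Each stability method ranks the panel; the comprehensive score of a gene is
the geometric mean of its per-method ranks, smaller = more stable.  Ranks
are *competition* ranks: tied genes share the minimal rank and the next
gene skips the tie width — e.g. a tied most-stable pair takes ranks (1, 1)
and the runner-up takes rank 3.  The convention matters: comprehensive
scores are only reproducible when every method ranks with the same rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataError

__all__ = ["rank_with_ties", "comprehensive_score", "assemble_ranking_report"]


def rank_with_ties(values, ascending: bool = True) -> pd.Series:
    """Competition ranking of stability values (1 = most stable).

    Equivalent to 1 + the number of strictly better values.  Accepts any
    1-d sequence or Series; returns integer ranks aligned to the input
    index.
    """
    s = pd.Series(values, dtype=float)
    arr = s.to_numpy()
    if not np.all(np.isfinite(arr)):
        raise DataError("rank_with_ties requires finite values")
    ranked = sps.rankdata(arr if ascending else -arr, method="min")
    return pd.Series(ranked.astype(int), index=s.index, name="rank")


def comprehensive_score(ranks) -> float:
    """Geometric mean of the available per-method ranks of one gene.

    Missing entries (NaN) are excluded; at least one rank must be present
    and all present ranks must be positive.
    """
    arr = pd.Series(ranks, dtype=float).dropna().to_numpy()
    if arr.size == 0:
        raise DataError("comprehensive_score needs >= 1 method rank")
    if np.any(arr <= 0):
        raise DataError("ranks must be positive")
    return float(sps.gmean(arr))


def assemble_ranking_report(method_ranks: dict) -> pd.DataFrame:
    """Combine per-method rank vectors for one stratum into a ranked table.

    *method_ranks* maps method name -> per-gene rank Series (NaN allowed for
    a method that could not rank a gene is **not** allowed — every method
    must cover the identical gene set; a mismatch raises listing the
    symmetric difference).

    Returns a frame sorted by comprehensive score (ties broken by gene
    label) with columns ``rank, score`` plus one ``rank_<method>`` column
    per input method.  Scores are reported to 2 decimals in
    ``score`` with full precision kept in ``score_full``.
    """
    if not method_ranks:
        raise DataError("no method rankings supplied")
    items = sorted(method_ranks.items())
    base = set(items[0][1].index)
    for name, series in items[1:]:
        diff = base.symmetric_difference(series.index)
        if diff:
            raise DataError(
                f"gene sets differ between methods ({items[0][0]} vs {name}): "
                f"{sorted(diff)}"
            )
    genes = sorted(base)
    frame = pd.DataFrame(
        {f"rank_{name}": series.reindex(genes) for name, series in items},
        index=pd.Index(genes, name="gene"),
    )
    full = frame.apply(comprehensive_score, axis=1)
    out = frame.copy()
    out.insert(0, "score_full", full)
    out.insert(0, "score", full.round(2))
    out = (
        out.reset_index()
        .sort_values(["score_full", "gene"], kind="mergesort")
        .set_index("gene")
    )
    out.insert(0, "rank", range(1, len(out) + 1))
    return out
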