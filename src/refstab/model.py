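"""Model/Results facade over the stability workflow.

:class:`ReferenceGeneStability` is constructed from qPCR data (a long-format
replicate table or an already-collapsed :class:`~refstab.qpcr.CtMatrix`);
:meth:`ReferenceGeneStability.fit` runs the abundance filter once on the
pooled data, then every requested stability method on every stratum (each
stage group plus the pooled "total"), aggregates the per-method rankings
into comprehensive scores, and returns a
:class:`ReferenceGeneStabilityResults` holding all tables, diagnostics and
a ``summary()``.

Typical use::

    model = ReferenceGeneStability.from_records(ct_long_table)
    res = model.fit()
    print(res.summary())
    res.most_stable("total", 4)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, InsufficientDataError
from .qpcr import (
    CtMatrix,
    collapse_replicates,
    filter_by_mean_ct,
    overview_relative_expression,
)
from .ranking import assemble_ranking_report
from .stability import (
    GENORM_V_CUTOFF,
    bestkeeper_stats,
    delta_ct_stability,
    genorm_stability,
    normfinder_stability,
)

__all__ = ["ReferenceGeneStability", "ReferenceGeneStabilityResults", "ALL_METHODS"]

ALL_METHODS = ("delta_ct", "bestkeeper", "normfinder", "genorm")
TOTAL = "total"


class ReferenceGeneStability:
    """Reference-gene stability model for a qPCR candidate panel.

    Parameters
    ----------
    matrix : CtMatrix
        Collapsed mean-Ct matrix with stage groups and efficiencies.
    ct_threshold : float
        Grand-mean-Ct abundance cutoff applied once to the pooled data
        (default 28 cycles); the retained panel is shared by all strata.
    methods : sequence of str
        Subset of ``("delta_ct", "bestkeeper", "normfinder", "genorm")``.
    bestkeeper_sd : str
        ``"mad"`` or ``"sample_sd"`` dispersion flavor.
    normfinder_grouped : bool
        Use the grouped decomposition on the pooled stratum when >= 2
        groups are present (per-stage strata always run ungrouped).
    exclude_genes : sequence of str
        Genes dropped from the candidate panel before anything runs —
        typically the target genes, which are stage-regulated by design
        and must not compete in the stability ranking.
    """

    def __init__(
        self,
        matrix: CtMatrix,
        ct_threshold: float = 28.0,
        ct_boundary: str = "exclude_equal",
        methods=ALL_METHODS,
        bestkeeper_sd: str = "mad",
        normfinder_grouped: bool = True,
        genorm_cutoff: float = GENORM_V_CUTOFF,
        exclude_genes=(),
    ):
        bad = [m for m in methods if m not in ALL_METHODS]
        if bad:
            raise DataError(f"unknown stability methods: {bad}")
        if not methods:
            raise DataError("at least one stability method is required")
        if exclude_genes:
            keep = [g for g in matrix.data.index if g not in set(exclude_genes)]
            matrix = matrix.subset(genes=keep)
        self.matrix = matrix
        self.ct_threshold = ct_threshold
        self.ct_boundary = ct_boundary
        self.methods = tuple(methods)
        self.bestkeeper_sd = bestkeeper_sd
        self.normfinder_grouped = normfinder_grouped
        self.genorm_cutoff = genorm_cutoff

    # ---- constructors ----------------------------------------------------

    @classmethod
    def from_records(cls, records: pd.DataFrame, efficiency=None, **kwargs):
        """Build from a long-format replicate table
        (columns ``sample_id, group, gene, replicate, ct``)."""
        return cls(collapse_replicates(records, efficiency=efficiency), **kwargs)

    @classmethod
    def from_ct_matrix(cls, data: pd.DataFrame, groups, efficiency=None, **kwargs):
        """Build from an already-collapsed genes x samples frame plus a
        sample -> group mapping."""
        return cls(
            CtMatrix(data=data, groups=pd.Series(groups), efficiency=efficiency),
            **kwargs,
        )

    # ---- fitting ---------------------------------------------------------

    def _run_methods(self, sub: CtMatrix, grouped_ok: bool) -> dict:
        out = {}
        if "delta_ct" in self.methods:
            out["delta_ct"] = delta_ct_stability(sub)
        if "bestkeeper" in self.methods:
            out["bestkeeper"] = bestkeeper_stats(sub, sd_flavor=self.bestkeeper_sd)
        if "normfinder" in self.methods:
            grouped = (
                grouped_ok
                and self.normfinder_grouped
                and len(set(sub.groups)) >= 2
            )
            out["normfinder"], _ = normfinder_stability(sub, grouped=grouped)
        if "genorm" in self.methods:
            out["genorm"] = genorm_stability(sub, cutoff=self.genorm_cutoff)
        return out

    def fit(self) -> "ReferenceGeneStabilityResults":
        retained, excluded = filter_by_mean_ct(
            self.matrix, threshold=self.ct_threshold, boundary=self.ct_boundary
        )
        if retained.data.shape[0] < 3:
            raise InsufficientDataError(
                "fewer than 3 genes survive the abundance filter"
            )
        overview = overview_relative_expression(retained)

        strata = {}
        for label in retained.group_labels:
            strata[label] = retained.subset_group(label)
        strata[TOTAL] = retained

        method_results = {}
        comprehensive = {}
        for label, sub in strata.items():
            method_results[label] = self._run_methods(sub, grouped_ok=label == TOTAL)
            comprehensive[label] = assemble_ranking_report(
                {m: r.ranks for m, r in method_results[label].items()}
            )
        return ReferenceGeneStabilityResults(
            model=self,
            matrix=retained,
            excluded=excluded,
            overview=overview,
            method_results=method_results,
            comprehensive=comprehensive,
        )


@dataclass
class ReferenceGeneStabilityResults:
    """Fitted stability analysis: tables, diagnostics and reports."""

    model: ReferenceGeneStability
    matrix: CtMatrix
    excluded: pd.DataFrame
    overview: pd.Series
    method_results: dict   # stratum -> {method: StabilityResult}
    comprehensive: dict    # stratum -> ranked DataFrame

    @property
    def strata(self) -> list:
        return list(self.comprehensive)

    def genorm(self, stratum: str = TOTAL):
        """The GenormResult (exclusion order, V series) for a stratum."""
        try:
            return self.method_results[stratum]["genorm"].extras
        except KeyError as e:
            raise DataError(f"no geNorm result for stratum {stratum!r}") from e

    def most_stable(self, stratum: str = TOTAL, n: int = 4) -> list:
        return list(self.comprehensive[stratum].index[:n])

    def least_stable(self, stratum: str = TOTAL, n: int = 4) -> list:
        return list(self.comprehensive[stratum].index[-n:])[::-1]

    def stability_table(self, stratum: str, method: str) -> pd.DataFrame:
        res = self.method_results[stratum][method]
        out = res.table.copy()
        out.insert(0, "rank", res.ranks.reindex(out.index))
        return out.sort_values("rank", kind="mergesort")

    # ---- reporting -------------------------------------------------------

    def summary(self) -> str:
        lines = []
        k, n = self.matrix.data.shape
        lines.append("Reference-gene stability analysis")
        lines.append("=" * 60)
        lines.append(f"genes retained: {k}   samples: {n}   "
                     f"groups: {', '.join(self.matrix.group_labels)}")
        lines.append(f"abundance filter: grand mean Ct < {self.model.ct_threshold:g}"
                     f"  (excluded {len(self.excluded)}: "
                     f"{', '.join(self.excluded.index) if len(self.excluded) else 'none'})")
        lines.append(f"methods: {', '.join(self.model.methods)}")
        lines.append("")
        for stratum in self.strata:
            comp = self.comprehensive[stratum]
            top = ", ".join(
                f"{g} ({comp.at[g, 'score']:.2f})" for g in comp.index[:4]
            )
            bottom = ", ".join(comp.index[-2:])
            line = f"[{stratum}] top: {top}   least stable: {bottom}"
            gres = None
            if "genorm" in self.method_results[stratum]:
                gres = self.method_results[stratum]["genorm"].extras
            if gres is not None and gres.v_series is not None:
                v2 = gres.v_series.get(2, np.nan)
                rec = gres.recommended_n
                line += (f"   geNorm V2={v2:.3f}"
                         + (f", panel size {rec}" if rec else ", V never < cutoff"))
            lines.append(line)
        return "\n".join(lines)

    def to_dir(self, outdir) -> dict:
        """Write every table as TSV; returns {name: path}."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _w(name, frame):
            p = outdir / f"{name}.tsv"
            frame.to_csv(p, sep="\t", float_format="%.6g")
            paths[name] = p

        _w("excluded_genes", self.excluded)
        _w("overview_expression", self.overview.to_frame())
        for stratum, methods in self.method_results.items():
            for m, res in methods.items():
                _w(f"stability_{m}_{stratum}", self.stability_table(stratum, m))
            _w(f"comprehensive_{stratum}", self.comprehensive[stratum])
            if "genorm" in methods and methods["genorm"].extras.v_series is not None:
                _w(
                    f"genorm_v_{stratum}",
                    methods["genorm"].extras.v_series.to_frame(),
                )
        return paths

    # ---- plotting (convenience) -----------------------------------------

    def plot_stability(self, stratum: str = TOTAL, method: str = "genorm", ax=None):
        """Bar plot of a method's stability values, most stable first."""
        import matplotlib.pyplot as plt

        res = self.method_results[stratum][method]
        order = res.values.sort_values().index
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        ax.bar(range(len(order)), res.values[order])
        ax.set_xticks(range(len(order)))
        ax.set_xticklabels(order, rotation=90)
        ax.set_ylabel(f"{method} stability value")
        ax.set_title(f"{method} ({stratum})")
        return ax

    def plot_pairwise_variation(self, stratum: str = TOTAL, ax=None):
        """Bar plot of the geNorm V_n series with the cutoff line."""
        import matplotlib.pyplot as plt

        gres = self.genorm(stratum)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        v = gres.v_series
        ax.bar([f"V{n}/{n + 1}" for n in v.index], v.to_numpy())
        ax.axhline(gres.cutoff, ls="--", color="crimson")
        ax.set_ylabel("pairwise variation")
        ax.set_title(f"geNorm V ({stratum})")
        return ax
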