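"""The four reference-gene stability algorithms.

All four operate on a complete genes x samples matrix of mean Ct values
(:class:`~refstab.qpcr.CtMatrix`) and produce a per-gene stability value —
smaller is more stable — plus a competition ranking:

* **Comparative delta-Ct** — for each gene, the mean over partner genes of
  the sample SD of the pairwise Ct difference.  A gene that moves with the
  panel has small pairwise SDs.
* **BestKeeper** — descriptive statistics of each gene's raw Ct (default
  dispersion: mean absolute deviation from the arithmetic mean, the
  original tool's statistic) plus the Pearson correlation of each gene with
  the BestKeeper index (per-sample geometric mean of Ct across the panel).
  Genes with SD > 1 cycle are flagged unstable.
* **NormFinder** — a model-based variance decomposition.  After removing
  per-sample effects (centering each sample across genes), the per-gene
  intragroup variance is estimated with a bias correction for the centering
  step, and — in grouped mode — a shrunken intergroup bias is added.  The
  stability value combines both components.
* **geNorm** — the M value: mean SD of the pairwise log2 expression ratios
  with every other panel gene, computed on log2 quantities (so per-gene
  amplification efficiency enters); stepwise exclusion of the
  highest-M gene down to an inseparable final pair, plus the pairwise
  variation series V_n used to choose how many reference genes to combine.

delta-Ct works on the Ct scale, geNorm on log2 quantities; at 100%
efficiency (E = 2) the two scales differ only by per-gene anchoring
constants, so full-panel geNorm M equals the delta-Ct statistic exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataError, InsufficientDataError
from .qpcr import CtMatrix, ct_to_log_quantity
from .ranking import rank_with_ties

__all__ = [
    "StabilityResult",
    "GenormResult",
    "NormfinderInternals",
    "delta_ct_stability",
    "bestkeeper_stats",
    "normfinder_stability",
    "genorm_m_values",
    "genorm_rank",
    "genorm_pairwise_variation",
    "genorm_stability",
    "BESTKEEPER_SD_CUTOFF",
    "GENORM_V_CUTOFF",
]

#: genes whose BestKeeper SD exceeds one cycle are deemed unstable
BESTKEEPER_SD_CUTOFF = 1.0
#: pairwise variation below this means an extra reference gene adds nothing
GENORM_V_CUTOFF = 0.15


@dataclass
class StabilityResult:
    """Per-gene stability values and ranks for one method.

    ``values`` is indexed by gene (smaller = more stable), ``ranks`` is the
    matching competition ranking, ``table`` carries the method's full output
    (extra columns vary by method).
    """

    method: str
    values: pd.Series
    ranks: pd.Series
    table: pd.DataFrame
    extras: object = None

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "rank", self.ranks.reindex(out.index))
        out.sort_values(["rank", out.index.name or "gene"]).to_csv(
            path, sep="\t", float_format="%.6g"
        )


@dataclass
class GenormResult:
    """Stepwise-exclusion output of geNorm."""

    exclusion_order: list          # first removed (least stable) ... last removed
    m_trajectory: list             # per-step pd.Series of M values
    final_pair: tuple              # the two inseparable most-stable genes
    ranking: list                  # most-stable-first listing (final pair first)
    v_series: pd.Series = None     # V_n indexed by n = 2..k-1
    recommended_n: int = None
    cutoff: float = GENORM_V_CUTOFF
    degenerate: bool = False       # all-identical panel


@dataclass
class NormfinderInternals:
    """Intermediate quantities of the NormFinder decomposition (grouped mode)."""

    z: pd.DataFrame                 # sample-centered values
    s2: pd.DataFrame                # per-gene per-group variance of z
    sigma2: pd.DataFrame            # intragroup variance estimates
    d: pd.DataFrame = None          # per-gene per-group means of z
    gamma2: pd.Series = None        # intergroup variance per gene
    delta: pd.DataFrame = None      # shrunken group differences
    grouped: bool = True


def _pairwise_sd_means(values: np.ndarray) -> np.ndarray:
    """For each row i: mean over rows k != i of SD(row_i - row_k) (ddof=1)."""
    diffs = values[:, None, :] - values[None, :, :]
    sd = diffs.std(axis=2, ddof=1)
    k = values.shape[0]
    return (sd.sum(axis=1)) / (k - 1)


def delta_ct_stability(matrix: CtMatrix) -> StabilityResult:
    """Comparative delta-Ct stability (the 'std-value').

    For gene *j* the value is the mean over all other genes *k* of the
    sample standard deviation (n-1) of ``Ct_j - Ct_k`` across biological
    samples.  Shared per-sample effects cancel in the difference, so the
    statistic isolates gene-specific variation.
    """
    matrix.check_complete()
    k, n = matrix.data.shape
    if k < 3:
        raise InsufficientDataError("delta-Ct needs >= 3 genes")
    if n < 3:
        raise InsufficientDataError("delta-Ct needs >= 3 samples")
    values = pd.Series(
        _pairwise_sd_means(matrix.data.to_numpy()), index=matrix.data.index, name="std_value"
    )
    ranks = rank_with_ties(values)
    table = pd.DataFrame({"std_value": values})
    return StabilityResult("delta_ct", values, ranks, table)


def bestkeeper_stats(matrix: CtMatrix, sd_flavor: str = "mad") -> StabilityResult:
    """BestKeeper descriptive statistics and index correlation.

    ``sd_flavor="mad"`` (default) is the original tool's dispersion: the
    mean absolute deviation of a gene's Ct from its arithmetic mean;
    ``"sample_sd"`` substitutes the n-1 standard deviation.  The BestKeeper
    index is the per-sample geometric mean of Ct over the panel; each gene's
    Pearson r (and two-sided p) against the index is reported.  Ranking is
    ascending by SD; genes above ``BESTKEEPER_SD_CUTOFF`` are flagged.
    """
    if sd_flavor not in ("mad", "sample_sd"):
        raise DataError("sd_flavor must be 'mad' or 'sample_sd'")
    matrix.check_complete()
    ct = matrix.data.to_numpy()
    if ct.shape[1] < 3:
        raise InsufficientDataError("BestKeeper needs >= 3 samples")
    am = ct.mean(axis=1)
    if sd_flavor == "mad":
        sd = np.abs(ct - am[:, None]).mean(axis=1)
    else:
        sd = ct.std(axis=1, ddof=1)
    index = sps.gmean(ct, axis=0)
    r = np.full(ct.shape[0], np.nan)
    p = np.full(ct.shape[0], np.nan)
    zero_var = ct.std(axis=1) == 0
    for i in range(ct.shape[0]):
        if not zero_var[i] and index.std() > 0:
            r[i], p[i] = sps.pearsonr(ct[i], index)
    values = pd.Series(sd, index=matrix.data.index, name="sd")
    ranks = rank_with_ties(values)
    table = pd.DataFrame(
        {
            "geo_mean": sps.gmean(ct, axis=1),
            "arith_mean": am,
            "min_ct": ct.min(axis=1),
            "max_ct": ct.max(axis=1),
            "sd": sd,
            "cv_pct": 100.0 * sd / am,
            "r": r,
            "p_value": p,
            "r_undefined": zero_var,
            "unstable": sd > BESTKEEPER_SD_CUTOFF,
        },
        index=matrix.data.index.copy(),
    )
    return StabilityResult("bestkeeper", values, ranks, table, extras={"index": pd.Series(index, index=matrix.data.columns)})


def _normfinder_group(z: np.ndarray):
    """Intragroup variance estimates for one group's centered values.

    z has shape (k genes, n samples).  Centering each sample over k genes
    couples the genes, so the naive per-gene variance s2_i underestimates
    sigma2_i; the correction inverts E[s2_i] = sigma2_i (1 - 2/k) + S/k^2
    with S = sum_i sigma2_i estimated from sum_i s2_i = S (k-1)/k.
    """
    k = z.shape[0]
    s2 = z.var(axis=1, ddof=1)
    S_hat = (k / (k - 1)) * s2.sum()
    sigma2 = (s2 - S_hat / k**2) / (1.0 - 2.0 / k)
    return s2, S_hat, np.maximum(sigma2, 0.0)


def normfinder_stability(matrix: CtMatrix, grouped: bool = True):
    """NormFinder model-based stability.

    Works on sample-centered Ct values ``z_ij = Ct_ij - mean_genes(Ct_.j)``
    (per-sample effects removed).  Ungrouped mode: the stability value is
    the bias-corrected intragroup SD.  Grouped mode additionally estimates
    a per-gene intergroup variance ``gamma2`` from the spread of the per-group
    means of z, shrinks each observed group difference toward zero in
    proportion to its sampling noise, and reports

        rho_i = mean_g ( |shrunken difference_ig| + sqrt(sigma2_ig / n_g) ).

    Returns ``(StabilityResult, NormfinderInternals)``.  Requires >= 3 genes
    (the bias correction divides by 1 - 2/k) and, in grouped mode, >= 2
    groups of >= 2 samples.  Negative variance estimates clamp to zero.
    """
    matrix.check_complete()
    genes = matrix.data.index
    k = len(genes)
    if k < 3:
        raise InsufficientDataError("NormFinder needs >= 3 genes")
    ct = matrix.data.to_numpy()
    z = ct - ct.mean(axis=0, keepdims=True)
    zf = pd.DataFrame(z, index=genes, columns=matrix.data.columns)

    if not grouped:
        if ct.shape[1] < 3:
            raise InsufficientDataError("NormFinder needs >= 3 samples")
        s2, S_hat, sigma2 = _normfinder_group(z)
        rho = np.sqrt(sigma2)
        internals = NormfinderInternals(
            z=zf,
            s2=pd.DataFrame({"all": s2}, index=genes),
            sigma2=pd.DataFrame({"all": sigma2}, index=genes),
            grouped=False,
        )
    else:
        labels = matrix.group_labels
        sizes = {g: int((matrix.groups == g).sum()) for g in labels}
        if len(labels) < 2:
            raise InsufficientDataError("grouped NormFinder needs >= 2 groups")
        small = [g for g, n in sizes.items() if n < 2]
        if small:
            raise InsufficientDataError(f"groups with < 2 samples: {small}")
        s2 = {}
        sigma2 = {}
        d = {}
        for g in labels:
            cols = matrix.groups == g
            zg = z[:, cols.to_numpy()]
            s2[g], _, sigma2[g] = _normfinder_group(zg)
            d[g] = zg.mean(axis=1)
        s2 = pd.DataFrame(s2, index=genes)
        sigma2 = pd.DataFrame(sigma2, index=genes)
        d = pd.DataFrame(d, index=genes)
        G = len(labels)
        dbar = d.mean(axis=1)
        n_g = pd.Series(sizes)
        noise = (sigma2 / n_g).mean(axis=1)          # mean_g sigma2_ig / n_g
        gamma2 = np.maximum(d.var(axis=1, ddof=1) - noise, 0.0)
        dev = d.sub(dbar, axis=0)
        denom = sigma2.div(n_g, axis=1).add(gamma2, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            shrink = denom.rdiv(1.0).mul(gamma2, axis=0)  # gamma2/(gamma2 + s2/n)
        shrink = shrink.fillna(0.0)
        delta = dev * shrink
        rho = (delta.abs() + np.sqrt(sigma2.div(n_g, axis=1))).mean(axis=1).to_numpy()
        internals = NormfinderInternals(
            z=zf, s2=s2, sigma2=sigma2, d=d, gamma2=gamma2, delta=delta, grouped=True
        )

    values = pd.Series(rho, index=genes, name="stability_value")
    ranks = rank_with_ties(values)
    table = pd.DataFrame({"stability_value": values})
    return StabilityResult("normfinder", values, ranks, table, extras=internals), internals


def genorm_m_values(logq: pd.DataFrame, panel=None) -> pd.Series:
    """geNorm M value of each panel gene.

    ``M_j`` = mean over the other panel genes *k* of the sample SD (n-1) of
    ``q_j - q_k`` — the average pairwise log2-ratio SD.  *logq* is a genes x
    samples frame of log2 quantities (see
    :func:`refstab.qpcr.ct_to_log_quantity`).
    """
    if panel is None:
        panel = list(logq.index)
    panel = list(panel)
    if len(panel) < 2:
        raise InsufficientDataError("geNorm M needs a panel of >= 2 genes")
    missing = [g for g in panel if g not in logq.index]
    if missing:
        raise DataError(f"panel genes not in matrix: {missing}")
    sub = logq.loc[panel]
    if sub.shape[1] < 3:
        raise InsufficientDataError("geNorm M needs >= 3 samples")
    return pd.Series(_pairwise_sd_means(sub.to_numpy()), index=sub.index, name="m_value")


def genorm_rank(logq: pd.DataFrame, cutoff: float = GENORM_V_CUTOFF) -> GenormResult:
    """Stepwise geNorm ranking.

    Repeatedly drop the gene with the largest M (ties: drop the
    lexicographically last, a fixed deterministic rule) and recompute M on
    the shrinking panel until two genes remain; those two are inseparable
    and share rank 1.  The result carries the M trajectory, the V series
    from :func:`genorm_pairwise_variation` and the smallest panel size whose
    pairwise variation falls under *cutoff*.
    """
    if logq.shape[0] < 3:
        raise InsufficientDataError("geNorm ranking needs >= 3 genes")
    panel = list(logq.index)
    exclusion = []
    trajectory = []
    degenerate = False
    while len(panel) > 2:
        m = genorm_m_values(logq, panel)
        trajectory.append(m)
        if np.allclose(m.to_numpy(), 0.0):
            degenerate = True
        worst_value = m.max()
        worst = max(g for g in panel if m[g] == worst_value)
        exclusion.append(worst)
        panel.remove(worst)
    final_m = genorm_m_values(logq, panel)
    trajectory.append(final_m)
    final_pair = tuple(sorted(panel))
    ranking = list(final_pair) + list(reversed(exclusion))
    result = GenormResult(
        exclusion_order=exclusion,
        m_trajectory=trajectory,
        final_pair=final_pair,
        ranking=ranking,
        cutoff=cutoff,
        degenerate=degenerate,
    )
    v = genorm_pairwise_variation(logq, ranking, cutoff=cutoff)
    result.v_series = v["v_series"]
    result.recommended_n = v["recommended_n"]
    return result


def genorm_pairwise_variation(
    logq: pd.DataFrame, ranking, cutoff: float = GENORM_V_CUTOFF
) -> dict:
    """Pairwise variation series V_n for n = 2..k-1.

    ``NF_n`` (per sample) is the arithmetic mean of log2 quantities over the
    top-*n* genes of *ranking* — the log-domain geometric mean normalization
    factor.  ``V_n`` is the sample SD (n-1) of ``NF_n - NF_{n+1}``: how much
    the normalization factor moves when an (n+1)-th gene joins the panel.
    Returns the series and the smallest n with ``V_n < cutoff`` (None when
    the series never dips below it).
    """
    ranking = list(ranking)
    k = len(ranking)
    if k < 3:
        raise InsufficientDataError("pairwise variation needs >= 3 ranked genes")
    sub = logq.loc[ranking].to_numpy()
    v = {}
    for n in range(2, k):
        nf_n = sub[:n].mean(axis=0)
        nf_n1 = sub[: n + 1].mean(axis=0)
        v[n] = float(np.std(nf_n - nf_n1, ddof=1))
    series = pd.Series(v, name="V_n")
    below = [n for n, val in series.items() if val < cutoff]
    return {"v_series": series, "recommended_n": (min(below) if below else None)}


def genorm_stability(matrix: CtMatrix, cutoff: float = GENORM_V_CUTOFF) -> StabilityResult:
    """Full geNorm pass on a CtMatrix, packaged like the other methods.

    The per-gene value column is the *full-panel* M (comparable across
    genes); the rank is the stepwise-exclusion ranking with the final pair
    tied at 1.
    """
    logq = ct_to_log_quantity(matrix)
    m_full = genorm_m_values(logq)
    res = genorm_rank(logq, cutoff=cutoff)
    ranks = {}
    for pos, gene in enumerate(res.ranking):
        ranks[gene] = 1 if gene in res.final_pair else pos + 1
    ranks = pd.Series(ranks, name="rank").reindex(m_full.index).astype(int)
    table = pd.DataFrame({"m_value": m_full, "tied_pair": [
        "|".join(res.final_pair) if g in res.final_pair else "" for g in m_full.index
    ]}, index=m_full.index)
    return StabilityResult("genorm", m_full, ranks, table, extras=res)
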