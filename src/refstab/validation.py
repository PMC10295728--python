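"""Target-gene validation by relative quantification (2^-ddCt).

The point of choosing good reference genes is downstream: a target gene's
expression is normalized to one or more references and expressed relative
to a calibrator group.  Per sample,

    dCt  = Ct_target - mean(Ct of the reference genes)
    ddCt = dCt - mean(dCt over the calibrator-group samples)
    fold = 2^-ddCt

A multi-gene normalizer aggregates references by the arithmetic mean of
their Cts, i.e. the geometric mean of their quantities at 100% efficiency.
An unstable (stage-biased) reference leaks its own regulation into every
fold change it normalizes — a reference up-shifted by ``c`` cycles of Ct in
some stage inflates that stage's apparent fold change by 2^c, and a
down-shifted (up-regulated) reference attenuates it likewise.

Stage contrasts use Welch's t test on log2 fold changes; the cross-
normalizer correlation matrix (Pearson R over the concatenated log2 fold
changes of all targets) quantifies how interchangeable two normalizers are.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataError, InsufficientDataError
from .qpcr import CtMatrix

__all__ = [
    "NormalizerSpec",
    "RelativeExpression",
    "delta_delta_ct",
    "stage_comparison",
    "normalizer_correlation",
]


@dataclass(frozen=True)
class NormalizerSpec:
    """A normalizer: reference gene(s), aggregation and calibrator group."""

    references: tuple
    calibrator_group: str
    name: str = None

    def __post_init__(self):
        object.__setattr__(self, "references", tuple(self.references))
        if not self.references:
            raise DataError("NormalizerSpec needs >= 1 reference gene")
        if self.name is None:
            object.__setattr__(self, "name", "+".join(self.references))


@dataclass
class RelativeExpression:
    """2^-ddCt fold changes of one target under one normalizer."""

    target: str
    normalizer: str
    calibrator_group: str
    fold: pd.Series           # per sample
    delta_ct: pd.Series
    delta_delta_ct: pd.Series
    groups: pd.Series         # sample -> stage, aligned to fold

    @property
    def log2_fold(self) -> pd.Series:
        return -self.delta_delta_ct.rename("log2_fold")

    def stage_summary(self) -> pd.DataFrame:
        """Per-stage n, mean +/- SD of fold and geometric-mean fold."""
        df = pd.DataFrame(
            {"stage": self.groups, "fold": self.fold, "log2_fold": self.log2_fold}
        )
        g = df.groupby("stage", sort=False)
        out = pd.DataFrame(
            {
                "n": g["fold"].size(),
                "mean_fold": g["fold"].mean(),
                "sd_fold": g["fold"].std(ddof=1),
                "geomean_fold": np.power(2.0, g["log2_fold"].mean()),
            }
        )
        out.index.name = "stage"
        return out


def delta_delta_ct(matrix: CtMatrix, target: str, spec: NormalizerSpec) -> RelativeExpression:
    """Relative expression of *target* under *spec* (see module docstring)."""
    if target in spec.references:
        raise DataError(f"target {target!r} listed among the reference genes")
    missing = [g for g in (target, *spec.references) if g not in matrix.data.index]
    if missing:
        raise DataError(f"genes not in matrix: {missing}")
    matrix.check_complete()
    cal = matrix.groups == spec.calibrator_group
    if not cal.any():
        raise DataError(f"calibrator group {spec.calibrator_group!r} has no samples")
    ref_ct = matrix.data.loc[list(spec.references)].mean(axis=0)
    dct = matrix.data.loc[target] - ref_ct
    ddct = dct - dct[cal].mean()
    fold = np.power(2.0, -ddct)
    return RelativeExpression(
        target=target,
        normalizer=spec.name,
        calibrator_group=spec.calibrator_group,
        fold=fold.rename("fold"),
        delta_ct=dct.rename("delta_ct"),
        delta_delta_ct=ddct.rename("delta_delta_ct"),
        groups=matrix.groups.copy(),
    )


def _tier(p: float) -> str:
    if not np.isfinite(p):
        return "nt"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def stage_comparison(expr: RelativeExpression, correction: str = None) -> pd.DataFrame:
    """Pairwise stage contrasts of log2 fold changes (Welch's t).

    Returns one row per unordered stage pair with columns ``stage_a,
    stage_b, n_a, n_b, mean_log2_a, mean_log2_b, p_value, tier`` where tier
    is ``**`` (p < 0.01), ``*`` (p < 0.05), ``ns``, or ``nt`` (not testable:
    a stage with fewer than 2 samples, or zero variance in both with equal
    means, which is reported as ns).  ``correction="holm"`` applies a Holm
    step-down adjustment across the pairs.
    """
    lf = expr.log2_fold
    stages = []
    for g in expr.groups:
        if g not in stages:
            stages.append(g)
    rows = []
    for a, b in itertools.combinations(stages, 2):
        xa = lf[expr.groups == a].to_numpy()
        xb = lf[expr.groups == b].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            p = np.nan
        elif np.std(xa) == 0 and np.std(xb) == 0:
            p = np.nan if xa.mean() != xb.mean() else 1.0
        else:
            p = sps.ttest_ind(xa, xb, equal_var=False).pvalue
        rows.append(
            {
                "stage_a": a,
                "stage_b": b,
                "n_a": len(xa),
                "n_b": len(xb),
                "mean_log2_a": xa.mean() if len(xa) else np.nan,
                "mean_log2_b": xb.mean() if len(xb) else np.nan,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if correction == "holm" and len(out):
        ps = out["p_value"].to_numpy()
        order = np.argsort(np.where(np.isfinite(ps), ps, np.inf))
        m = np.isfinite(ps).sum()
        adj = np.full_like(ps, np.nan)
        running = 0.0
        for idx, i in enumerate(order[:m]):
            running = max(running, (m - idx) * ps[i])
            adj[i] = min(running, 1.0)
        out["p_value"] = adj
    out["tier"] = [_tier(p) for p in out["p_value"]]
    return out


def normalizer_correlation(matrix: CtMatrix, targets, normalizers) -> pd.DataFrame:
    """Pearson R between normalizers over all targets' log2 fold changes.

    *normalizers* is a list of :class:`NormalizerSpec` or bare gene names
    (each promoted to a single-gene normalizer calibrated on the matrix's
    first group).  For each normalizer the log2 fold changes of every
    target are concatenated across samples; the matrix of pairwise Pearson
    R values is symmetric with a unit diagonal.  A zero-variance profile
    yields NaN against everything (undefined correlation, flagged not
    fabricated).
    """
    if matrix.data.shape[1] < 3:
        raise InsufficientDataError("normalizer correlation needs >= 3 samples")
    targets = list(targets)
    if not targets:
        raise DataError("need >= 1 target gene")
    default_cal = matrix.group_labels[0]
    specs = []
    for nz in normalizers:
        if isinstance(nz, NormalizerSpec):
            specs.append(nz)
        else:
            specs.append(NormalizerSpec(references=(nz,), calibrator_group=default_cal))
    profiles = {}
    for spec in specs:
        chunks = [
            delta_delta_ct(matrix, t, spec).log2_fold.to_numpy() for t in targets
        ]
        profiles[spec.name] = np.concatenate(chunks)
    names = list(profiles)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        xa, xb = profiles[a], profiles[b]
        if np.std(xa) == 0 or np.std(xb) == 0:
            r = np.nan
        else:
            r = sps.pearsonr(xa, xb).statistic
        out.loc[a, b] = out.loc[b, a] = r
    return out
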