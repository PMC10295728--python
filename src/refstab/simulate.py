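"""Synthetic qPCR Ct and RNA-seq FPKM data with known stability structure.

The generator emulates a reference-gene selection study on goat uterus
caruncle tissue: 24 biological samples in three stage groups (non-pregnant,
early pregnancy, mid/late pregnancy), technical triplicates per well, a
shared per-sample loading effect, gene-specific biological noise, stage
effects for unstable candidates, and three stage-regulated target genes.

Model for a single well (gene *i*, biological sample *j* in group *g(j)*,
technical replicate *w*)::

    Ct_ijw = baseline_i + phi_j + b_{i,g(j)} + eps_ij + tau_w

with ``phi_j ~ N(0, sample_effect_sd^2)`` shared across genes (pipetting /
RNA-input variation), ``eps_ij ~ N(0, gene_noise_sd_i^2)`` the biological
gene-level noise, ``b`` the per-gene per-group Ct offset (a negative offset
means up-regulation), and ``tau_w ~ N(0, tech_rep_sd^2)`` per well.
Everything is on the Ct (log2-quantity) scale, so technical noise is
multiplicative on transcript quantity.

The true stability ordering of candidates is ascending
``gene_noise_sd_i + mean_g |b_ig|``, ties broken by gene label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "default_config",
    "simulate_ct_dataset",
    "simulate_fpkm_matrix",
    "ground_truth_ranking",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Candidate reference genes come first, then ``n_targets`` target genes;
    per-gene vectors (``gene_noise_sd``, ``group_effect`` rows,
    ``efficiency``) cover candidates followed by targets.
    """

    n_genes: int = 17
    n_targets: int = 0
    #: (group label, number of biological samples) in stage order
    groups: tuple = (("stage1", 8), ("stage2", 8), ("stage3", 8))
    #: uniform range the per-gene baseline Ct is drawn from (cycles)
    baseline_ct_range: tuple = (19.0, 26.0)
    #: SD of the shared per-sample loading effect (cycles)
    sample_effect_sd: float = 0.8
    #: per-gene biological noise SD (cycles); scalar or length n_genes+n_targets
    gene_noise_sd: object = 0.3
    #: per-gene per-group Ct offsets, shape (n_genes+n_targets, n_groups);
    #: None means no group structure
    group_effect: object = None
    #: SD of the per-well technical replicate noise (cycles)
    tech_rep_sd: float = 0.15
    n_tech_reps: int = 3
    #: per-gene amplification efficiency; scalar or vector, in (1, 2.2]
    efficiency: object = 2.0
    seed: int = 0
    gene_names: list = None
    target_names: list = None
    #: number of RNA-seq libraries for the FPKM matrix
    n_expression_samples: int = 9
    #: per-gene log-normal parameters for FPKM simulation; None derives
    #: defaults (tight dispersion for low-noise genes)
    fpkm_log_mean: object = None
    fpkm_log_sd: object = None

    # ---- derived helpers -------------------------------------------------

    @property
    def n_total(self) -> int:
        return self.n_genes + self.n_targets

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups)

    @property
    def group_labels(self) -> list:
        return [g for g, _ in self.groups]

    def resolved_gene_names(self) -> list:
        names = list(self.gene_names) if self.gene_names else [
            f"HKG{i + 1:02d}" for i in range(self.n_genes)
        ]
        targets = list(self.target_names) if self.target_names else [
            f"TGT{i + 1}" for i in range(self.n_targets)
        ]
        return names + targets

    def noise_sd_vector(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.gene_noise_sd, dtype=float), (self.n_total,)
        ).copy()

    def group_effect_matrix(self) -> np.ndarray:
        if self.group_effect is None:
            return np.zeros((self.n_total, len(self.groups)))
        return np.asarray(self.group_effect, dtype=float).reshape(
            self.n_total, len(self.groups)
        )

    def efficiency_vector(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.efficiency, dtype=float), (self.n_total,)
        ).copy()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_targets < 0:
            raise ConfigError("n_targets must be >= 0")
        if self.n_tech_reps < 1:
            raise ConfigError("n_tech_reps must be >= 1")
        if any(n < 2 for _, n in self.groups):
            raise ConfigError("groups: every group needs >= 2 samples")
        lo, hi = self.baseline_ct_range
        if not (0 < lo <= hi):
            raise ConfigError("baseline_ct_range must satisfy 0 < lo <= hi")
        if self.sample_effect_sd < 0:
            raise ConfigError("sample_effect_sd must be >= 0")
        if self.tech_rep_sd < 0:
            raise ConfigError("tech_rep_sd must be >= 0")
        if np.any(self.noise_sd_vector() < 0):
            raise ConfigError("gene_noise_sd entries must be >= 0")
        eff = self.efficiency_vector()
        if np.any((eff <= 1.0) | (eff > 2.2)):
            raise ConfigError("efficiency must lie in (1, 2.2]")
        names = self.resolved_gene_names()
        if len(set(names)) != len(names):
            raise ConfigError("gene_names/target_names must be unique")
        ge = self.group_effect
        if ge is not None:
            arr = np.asarray(ge, dtype=float)
            if arr.size != self.n_total * len(self.groups):
                raise ConfigError(
                    "group_effect must have shape (n_genes + n_targets, n_groups)"
                )


@dataclass
class SimulationTruth:
    """Ground-truth parameters recorded next to every simulated dataset."""

    gene_noise_sd: dict
    group_effect_magnitude: dict  # mean_g |b_ig| per gene
    stability_order: list  # candidate genes, most stable first
    target_genes: list
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study design used throughout the test-bench.

    17 candidate reference genes in three tiers:

    * 4 genuinely stable genes (sigma = 0.1 cycles, no stage effect),
    * 6 noisy genes with sigma spread over 0.5-1.5 cycles,
    * 7 stage-regulated genes (sigma = 0.3) whose stage-3 Ct shifts by
      0.5-2.0 cycles, alternating between up- and down-regulation so the
      panel average stays roughly stage-neutral (as in real candidate
      panels, where regulation direction varies gene by gene; a one-signed
      panel would shift the panel average itself, and stability measured
      relative to the panel would then penalize the truly stable genes).

    Plus 3 stage-responsive target genes: two rising monotonically across
    stages (4-fold then 16-fold on the expression scale) and one peaking in
    the middle stage, each with sigma = 0.2.
    """
    n_hkg, n_tgt = 17, 3
    sd = np.empty(n_hkg + n_tgt)
    sd[:4] = 0.1
    sd[4:10] = np.linspace(0.5, 1.5, 6)
    sd[10:17] = 0.3
    sd[17:] = 0.2
    b = np.zeros((n_hkg + n_tgt, 3))
    signs = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    b[10:17, 2] = signs * np.linspace(0.5, 2.0, 7)
    b[17] = (0.0, -2.0, -4.0)   # monotone up: 1x, 4x, 16x
    b[18] = (0.0, -2.0, -4.0)
    b[19] = (0.0, -3.0, -1.0)   # peaks in the middle stage
    return SimulationConfig(
        n_genes=n_hkg,
        n_targets=n_tgt,
        gene_noise_sd=sd,
        group_effect=b,
        seed=seed,
    )


def _sample_frame(config: SimulationConfig):
    """Sample ids, group labels and group index per biological sample."""
    ids, labels, gidx = [], [], []
    j = 0
    for g, (label, n) in enumerate(config.groups):
        for _ in range(n):
            ids.append(f"S{j + 1:02d}")
            labels.append(label)
            gidx.append(g)
            j += 1
    return ids, labels, np.asarray(gidx)


def simulate_ct_dataset(config: SimulationConfig):
    """Draw a long-format Ct table and its ground truth.

    Returns ``(table, truth)`` where *table* has columns
    ``sample_id, group, gene, replicate, ct`` with
    ``n_total * n_samples * n_tech_reps`` rows, and *truth* is a
    :class:`SimulationTruth`.  A fixed seed reproduces the table bitwise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.resolved_gene_names()
    noise = config.noise_sd_vector()
    b = config.group_effect_matrix()
    ids, labels, gidx = _sample_frame(config)
    n_s, n_g, n_r = config.n_samples, config.n_total, config.n_tech_reps

    lo, hi = config.baseline_ct_range
    baseline = rng.uniform(lo, hi, n_g)
    phi = rng.normal(0.0, config.sample_effect_sd, n_s)
    eps = rng.normal(0.0, 1.0, (n_g, n_s)) * noise[:, None]
    tau = rng.normal(0.0, config.tech_rep_sd, (n_g, n_s, n_r))

    ct = (
        baseline[:, None, None]
        + phi[None, :, None]
        + b[:, gidx][:, :, None]
        + eps[:, :, None]
        + tau
    )

    table = pd.DataFrame(
        {
            "sample_id": np.tile(np.repeat(ids, n_r), n_g),
            "group": np.tile(np.repeat(labels, n_r), n_g),
            "gene": np.repeat(names, n_s * n_r),
            "replicate": np.tile(np.arange(1, n_r + 1), n_g * n_s),
            "ct": ct.reshape(-1),
        }
    )

    mag = np.abs(b).mean(axis=1)
    candidates = names[: config.n_genes]
    order = sorted(candidates, key=lambda g: (noise[names.index(g)] + mag[names.index(g)], g))
    truth = SimulationTruth(
        gene_noise_sd=dict(zip(names, noise.tolist())),
        group_effect_magnitude=dict(zip(names, mag.tolist())),
        stability_order=order,
        target_genes=names[config.n_genes:],
        seed=config.seed,
    )
    return table, truth


def simulate_fpkm_matrix(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a candidate-gene FPKM matrix (genes x RNA-seq libraries).

    ``FPKM_ij = exp(Normal(log mu_i, s_i^2))`` — log-normal expression with
    per-gene dispersion.  By default stable candidates (biological noise SD
    <= 0.2 cycles) get ``s_i = 0.05`` (expected CV ~ 5%, the regime of genes
    worth nominating) and the rest ``s_i = 0.4``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    names = config.resolved_gene_names()[: config.n_genes]
    noise = config.noise_sd_vector()[: config.n_genes]
    n_lib = config.n_expression_samples

    if config.fpkm_log_mean is None:
        log_mu = rng.uniform(np.log(20.0), np.log(400.0), config.n_genes)
    else:
        log_mu = np.broadcast_to(
            np.asarray(config.fpkm_log_mean, dtype=float), (config.n_genes,)
        )
    if config.fpkm_log_sd is None:
        s = np.where(noise <= 0.2, 0.05, 0.4)
    else:
        s = np.broadcast_to(
            np.asarray(config.fpkm_log_sd, dtype=float), (config.n_genes,)
        )
    if np.any(np.asarray(s) < 0):
        raise ConfigError("fpkm_log_sd entries must be >= 0")

    vals = np.exp(log_mu[:, None] + rng.normal(0.0, 1.0, (config.n_genes, n_lib)) * np.asarray(s)[:, None])
    cols = [f"L{j + 1}" for j in range(n_lib)]
    return pd.DataFrame(vals, index=pd.Index(names, name="gene_id"), columns=cols)


def ground_truth_ranking(truth: SimulationTruth) -> list:
    """Candidate genes ordered most-stable-first.

    Ascending ``gene_noise_sd + mean_g |group effect|``; ties break on the
    gene label so the order is total and reproducible.
    """
    cands = [g for g in truth.gene_noise_sd if g not in set(truth.target_genes)]
    key = lambda g: (truth.gene_noise_sd[g] + truth.group_effect_magnitude[g], g)
    return sorted(cands, key=key)


def write_dataset(config: SimulationConfig, outdir) -> dict:
    """Simulate and write the Ct table, groups sidecar, FPKM matrix and truth.

    Returns the paths written.  File formats match the readers in
    :mod:`refstab.qpcr` and :mod:`refstab.screening`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_ct_dataset(config)
    fpkm = simulate_fpkm_matrix(config)
    paths = {
        "ct": outdir / "ct_long.tsv",
        "groups": outdir / "groups.tsv",
        "fpkm": outdir / "fpkm.tsv",
        "truth": outdir / "truth.json",
    }
    table.to_csv(paths["ct"], sep="\t", index=False)
    (
        table[["sample_id", "group"]]
        .drop_duplicates()
        .to_csv(paths["groups"], sep="\t", index=False)
    )
    fpkm.to_csv(paths["fpkm"], sep="\t")
    truth.to_json(paths["truth"])
    return paths
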