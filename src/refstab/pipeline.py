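"""End-to-end pipeline: simulate/load -> screen -> preprocess -> stability
-> comprehensive ranking -> target validation, with reproducible outputs.

Every run writes fixed-column-order TSV tables, a machine-readable
``summary.json`` (seed, config hash, retained panel, per-stratum most/least
stable sets, geNorm panel-size recommendation, validation summaries) and a
run log.  Re-running with an identical config reproduces the bundle
bitwise.  Any stage failure aborts the run and removes the partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import simulate as sim
from .exceptions import DataError, RefstabError
from .model import ALL_METHODS, TOTAL, ReferenceGeneStability
from .qpcr import collapse_replicates, read_ct_table
from .screening import (
    ScreenThresholds,
    compute_fpkm_stats,
    read_fpkm_matrix,
    screen_candidates,
    write_screen_report,
)
from .validation import (
    NormalizerSpec,
    delta_delta_ct,
    normalizer_correlation,
    stage_comparison,
)

__all__ = ["PipelineConfig", "run_full"]


@dataclass
class PipelineConfig:
    """Flat configuration of a full run.

    With ``ct_path`` unset the synthetic default study is simulated from
    ``seed``.  ``target_genes`` default to the simulated targets (or none
    when loading external data without targets).
    """

    seed: int = 0
    out_dir: str = "refstab_out"
    ct_path: str = None
    groups_path: str = None
    fpkm_path: str = None
    ct_threshold: float = 28.0
    ct_boundary: str = "exclude_equal"
    methods: tuple = ALL_METHODS
    bestkeeper_sd: str = "mad"
    screen_min_mean_fpkm: float = 50.0
    screen_max_cv: float = 0.06
    screen_max_mfc: float = 1.22
    target_genes: tuple = None
    normalizer_size: int = 4
    calibrator_group: str = None   # default: first group in the data

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise DataError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (the output
        directory does not change what is computed)."""
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(self).items()
                   if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_or_simulate(config: PipelineConfig, outdir: Path, log, written):
    if config.ct_path:
        log(f"loading Ct table {config.ct_path}")
        records = read_ct_table(config.ct_path, group_map=config.groups_path)
        truth = None
    else:
        log(f"simulating default study design (seed={config.seed})")
        sim_cfg = sim.default_config(seed=config.seed)
        records, truth = sim.simulate_ct_dataset(sim_cfg)
        p = outdir / "simulated_ct_long.tsv"
        records.to_csv(p, sep="\t", index=False)
        written.append(p)
        p = outdir / "simulation_truth.json"
        truth.to_json(p)
        written.append(p)
    return records, truth


def run_full(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the summary dict.

    Outputs land in ``config.out_dir``.  On any failure the partially
    written files are removed and the error re-raised with the failing
    stage named.
    """
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    log_lines = []

    def log(msg):
        log_lines.append(msg)
        print(f"[refstab] {msg}", file=sys.stderr)

    stage = "setup"
    try:
        log(f"config hash {config.digest()}")

        # ---- optional RNA-seq screen ------------------------------------
        screen_summary = None
        if config.fpkm_path:
            stage = "screen"
            fpkm = read_fpkm_matrix(config.fpkm_path)
            stats = compute_fpkm_stats(fpkm)
            thresholds = ScreenThresholds(
                config.screen_min_mean_fpkm, config.screen_max_cv, config.screen_max_mfc
            )
            candidates, membership = screen_candidates(stats, thresholds)
            p = outdir / "screen_report.tsv"
            write_screen_report(stats, membership, p)
            written.append(p)
            screen_summary = {"n_candidates": len(candidates), "candidates": candidates}
            log(f"screen: {len(candidates)} candidate(s) pass all three filters")

        # ---- qPCR preprocessing + stability -----------------------------
        stage = "load"
        records, truth = _load_or_simulate(config, outdir, log, written)

        stage = "stability"
        targets = list(config.target_genes or (truth.target_genes if truth else []))
        model = ReferenceGeneStability.from_records(
            records,
            ct_threshold=config.ct_threshold,
            ct_boundary=config.ct_boundary,
            methods=tuple(config.methods),
            bestkeeper_sd=config.bestkeeper_sd,
            exclude_genes=targets,
        )
        results = model.fit()
        paths = results.to_dir(outdir)
        written.extend(paths.values())
        log(
            f"stability: {results.matrix.data.shape[0]} genes retained, "
            f"{len(results.excluded)} excluded by the Ct filter"
        )

        # ---- target validation ------------------------------------------
        stage = "validate"
        full_matrix = collapse_replicates(records)
        targets = [t for t in targets if t in full_matrix.data.index]
        validation = None
        if targets:
            vmatrix = full_matrix.subset(
                genes=list(results.matrix.data.index) + targets
            )
            cal = config.calibrator_group or vmatrix.group_labels[0]
            n = config.normalizer_size
            best = results.most_stable(TOTAL, n)
            worst = results.least_stable(TOTAL, n)
            specs = {
                "most_stable": NormalizerSpec(tuple(best), cal, name="most_stable"),
                "least_stable": NormalizerSpec(tuple(worst), cal, name="least_stable"),
            }
            validation = {"calibrator": cal, "targets": {},
                          "most_stable_panel": best, "least_stable_panel": worst}
            frames = []
            for t in targets:
                validation["targets"][t] = {}
                for label, spec in specs.items():
                    expr = delta_delta_ct(vmatrix, t, spec)
                    frames.append(
                        pd.DataFrame(
                            {
                                "target": t,
                                "normalizer": label,
                                "sample_id": expr.fold.index,
                                "stage": expr.groups.to_numpy(),
                                "fold_change": expr.fold.to_numpy(),
                            }
                        )
                    )
                    comp = stage_comparison(expr)
                    validation["targets"][t][label] = {
                        "stage_summary": expr.stage_summary().reset_index().to_dict("records"),
                        "contrasts": comp.to_dict("records"),
                    }
            p = outdir / "validation_fold_changes.tsv"
            pd.concat(frames, ignore_index=True).to_csv(p, sep="\t", index=False, float_format="%.6g")
            written.append(p)
            single = results.most_stable(TOTAL, 2) + results.least_stable(TOTAL, 2)
            corr = normalizer_correlation(
                vmatrix, targets,
                [NormalizerSpec((g,), cal) for g in dict.fromkeys(single) if g not in targets],
            )
            p = outdir / "normalizer_correlation.tsv"
            corr.to_csv(p, sep="\t", float_format="%.4f")
            written.append(p)
            log(f"validation: {len(targets)} target(s) under most/least stable panels")

        # ---- summary ----------------------------------------------------
        stage = "summary"
        summary = {
            "seed": config.seed,
            "config_hash": config.digest(),
            "methods": list(config.methods),
            "retained_genes": list(results.matrix.data.index),
            "excluded_genes": {
                g: round(float(v), 4)
                for g, v in results.excluded["grand_mean_ct"].items()
            },
            "screen": screen_summary,
            "strata": {},
            "validation": validation,
        }
        for stratum in results.strata:
            gres = (
                results.method_results[stratum].get("genorm")
            )
            summary["strata"][stratum] = {
                "most_stable": results.most_stable(stratum, 4),
                "least_stable": results.least_stable(stratum, 4),
                "comprehensive_top_score": float(
                    results.comprehensive[stratum]["score"].iloc[0]
                ),
                "genorm_recommended_n": (
                    gres.extras.recommended_n if gres is not None else None
                ),
            }
        p = outdir / "summary.json"
        p.write_text(json.dumps(summary, indent=2, default=str) + "\n")
        written.append(p)
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        return summary
    except Exception as e:
        for p in written:
            Path(p).unlink(missing_ok=True)
        if isinstance(e, RefstabError):
            raise type(e)(f"pipeline stage {stage!r} failed: {e}") from e
        raise RefstabError(f"pipeline stage {stage!r} failed: {e}") from e
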