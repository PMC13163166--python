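"""End-to-end orchestration: read/simulate -> features -> models -> reports.

`run_pipeline` executes the full analysis sequence — validation,
architecture summaries, fragmentation indices, Markov matrices, split-night
stratification, and the cohort-level mixed-model comparisons — and writes
tidy CSV outputs plus a JSON run summary capturing the seed, policies and
every exclusion. The simulate→analyze path is fully deterministic under a
fixed seed.

Outputs written to the run directory:

* ``architecture.csv``    — per subject x resolution architecture summary;
* ``fragmentation.csv``   — transition indices and wake-period rates;
* ``matrices_long.csv``   — long-format per-subject transition matrices;
* ``splitnight_long.csv`` — per-half repeated-measures metric table;
* ``models.csv``          — group and split-night model results;
* ``grid.csv``            — per-cell probability comparisons with BH flags;
* ``summary.json``        — seed, versions, counts, exclusions, policies.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .architecture import architecture_table
from .fragmentation import transition_indices, wake_period_counts
from .hypnogram import Hypnogram, validate
from .io import read_cohort_table, read_hypnogram
from .markov import estimate_transition_matrix, matrix_table
from .simulate import GeneratorConfig, generate_cohort
from .splitnight import split_night_table
from .stats import (
    compare_transition_probabilities,
    fit_group_comparison,
    split_night_model,
)

logger = logging.getLogger(__name__)

INDEX_METRICS = ("index_all_stages", "index_nrem_rem", "index_sleep_wake")
WAKE_METRICS = ("rate_wake_short", "rate_wake_intermediate", "rate_wake_long")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Exactly one of ``input_dir`` (hypnogram directory + cohort CSV) or
    ``generator`` must be provided.
    """

    output_dir: str | Path
    input_dir: str | Path | None = None
    cohort_csv: str | Path | None = None
    generator: GeneratorConfig | None = None
    resolutions: tuple[str, ...] = ("epoch30", "miniepoch5")
    split_night: bool = True
    split_boundary: str = "spt"  # or "lights"
    transform_policy: str = "auto"
    fdr_q: float = 0.05
    min_cell_subjects: int = 10
    include_grid: bool = True
    strict: bool = False
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.generator is None):
            raise ValueError(
                "exactly one of input_dir or generator must be set"
            )
        if self.input_dir is not None:
            if not Path(self.input_dir).exists():
                raise ValueError(f"input_dir {self.input_dir} does not exist")
            if self.cohort_csv is None or not Path(self.cohort_csv).exists():
                raise ValueError("cohort_csv missing or does not exist")

    def to_jsonable(self) -> dict:
        d = {
            "output_dir": str(self.output_dir),
            "input_dir": str(self.input_dir) if self.input_dir else None,
            "cohort_csv": str(self.cohort_csv) if self.cohort_csv else None,
            "resolutions": list(self.resolutions),
            "split_night": self.split_night,
            "split_boundary": self.split_boundary,
            "transform_policy": self.transform_policy,
            "fdr_q": self.fdr_q,
            "min_cell_subjects": self.min_cell_subjects,
            "include_grid": self.include_grid,
            "strict": self.strict,
            "seed": self.seed,
        }
        if self.generator is not None:
            g = self.generator
            d["generator"] = {
                "n_patients": g.n_patients,
                "n_siblings": g.n_siblings,
                "family_pairing": g.family_pairing,
                "subject_heterogeneity": g.subject_heterogeneity,
                "family_effect_sd": g.family_effect_sd,
                "night_length_miniepochs": g.night_length_miniepochs,
                "seed": g.seed,
            }
        return d


def _load_inputs(
    config: RunConfig,
) -> tuple[list[Hypnogram], pd.DataFrame, dict]:
    if config.generator is not None:
        cohort = generate_cohort(config.generator)
        hyps = list(cohort.hypnograms_5s) + list(cohort.hypnograms_30s)
        return hyps, cohort.cohort_table, {"source": "simulated"}
    hyps = []
    excluded = []
    for path in sorted(Path(config.input_dir).glob("*.csv")):
        try:
            h = read_hypnogram(path)
            issues = validate(h)
            if issues:
                raise ValueError("; ".join(issues))
            hyps.append(h)
        except (ValueError, OSError) as exc:
            if config.strict:
                raise RuntimeError(f"invalid hypnogram file {path}: {exc}")
            excluded.append({"file": str(path), "reason": str(exc)})
    table = read_cohort_table(config.cohort_csv)
    return hyps, table, {"source": "files", "excluded_files": excluded}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run summary dict."""
    config.validate()
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "package_version": __version__,
        "config": config.to_jsonable(),
        "timings_s": {},
        "exclusions": {},
    }

    hyps, cohort, meta = _load_inputs(config)
    summary["input"] = meta
    summary["exclusions"]["invalid_files"] = len(meta.get("excluded_files", []))
    summary["timings_s"]["load"] = round(time.time() - t0, 3)

    by_res: dict[str, list[Hypnogram]] = {r: [] for r in config.resolutions}
    for h in hyps:
        if h.resolution_tag in by_res:
            by_res[h.resolution_tag].append(h)
    summary["n_hypnograms"] = {r: len(v) for r, v in by_res.items()}
    summary["n_subjects"] = int(cohort["subject_id"].nunique())

    # -- per-subject features ----------------------------------------------
    t = time.time()
    arch = architecture_table(hyps)
    frag_rows, zero_tst = [], []
    for h in hyps:
        try:
            row = transition_indices(h).to_row()
        except ValueError:
            zero_tst.append((h.subject_id, h.resolution_tag))
            continue
        if h.epoch_seconds == 5:
            try:
                row |= wake_period_counts(h).to_row()
            except ValueError:
                pass
        frag_rows.append(row)
    frag = pd.DataFrame(frag_rows)
    summary["exclusions"]["zero_tst_nights"] = len(zero_tst)

    matrices = [
        estimate_transition_matrix(h) for h in hyps if h.n_units >= 2
    ]
    mat_long = matrix_table(matrices) if matrices else pd.DataFrame()
    split_long = (
        split_night_table(hyps, boundary=config.split_boundary)
        if config.split_night
        else pd.DataFrame()
    )
    summary["timings_s"]["features"] = round(time.time() - t, 3)

    arch.to_csv(outdir / "architecture.csv", index=False, lineterminator="\n")
    frag.to_csv(outdir / "fragmentation.csv", index=False, lineterminator="\n")
    mat_long.to_csv(outdir / "matrices_long.csv", index=False, lineterminator="\n")
    split_long.to_csv(
        outdir / "splitnight_long.csv", index=False, lineterminator="\n"
    )

    # -- cohort statistics --------------------------------------------------
    t = time.time()
    model_rows = []
    two_groups = cohort["group"].nunique() == 2
    if two_groups and not frag.empty:
        for resolution in config.resolutions:
            sub = frag[frag["resolution"] == resolution].merge(
                cohort, on="subject_id", how="inner"
            )
            if sub.empty:
                continue
            outcomes = list(INDEX_METRICS)
            if resolution == "miniepoch5" and "rate_wake_short" in sub:
                outcomes += list(WAKE_METRICS)
            for outcome in outcomes:
                if outcome not in sub:
                    continue
                try:
                    res = fit_group_comparison(
                        sub,
                        outcome=outcome,
                        transform_policy=config.transform_policy,
                    )
                except ValueError as exc:
                    logger.warning("full-night model %s/%s failed: %s",
                                   resolution, outcome, exc)
                    continue
                model_rows.append(
                    {"analysis": "full_night_group", "resolution": resolution,
                     "contrast": "group"} | res.to_row()
                )
    if config.split_night and two_groups and not split_long.empty:
        for resolution in config.resolutions:
            sub = split_long[split_long["resolution"] == resolution]
            if sub.empty:
                continue
            metrics = sorted(set(sub["metric"]))
            for metric in metrics:
                try:
                    contrasts = split_night_model(
                        sub, cohort, metric,
                        transform_policy=config.transform_policy,
                    )
                except ValueError as exc:
                    logger.warning("split-night model %s/%s failed: %s",
                                   resolution, metric, exc)
                    continue
                for name, res in contrasts.items():
                    model_rows.append(
                        {"analysis": "split_night", "resolution": resolution,
                         "contrast": name} | res.to_row()
                    )
    models = pd.DataFrame(model_rows)
    models.to_csv(outdir / "models.csv", index=False, lineterminator="\n")

    if config.include_grid and two_groups and not mat_long.empty:
        grid = compare_transition_probabilities(
            mat_long,
            cohort,
            fdr_q=config.fdr_q,
            min_subjects=config.min_cell_subjects,
        )
        grid.to_frame().to_csv(
            outdir / "grid.csv", index=False, lineterminator="\n"
        )
        summary["grid"] = {
            "n_models": grid.n_models,
            "n_fitted": len(grid.cells),
            "n_unfit": len(grid.unfit),
            "n_bh_rejected": int(sum(grid.bh_rejected.values())),
            "fdr_q": grid.fdr_q,
        }
        summary["exclusions"]["unfit_grid_cells"] = len(grid.unfit)
    summary["timings_s"]["models"] = round(time.time() - t, 3)

    summary["n_models"] = len(model_rows)
    summary["timings_s"]["total"] = round(time.time() - t0, 3)
    summary["status"] = "success"
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
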