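"""Synthetic sleep-cohort generator.

Generates desk-scale cohorts of paired 5-s/30-s hypnograms with the
statistical structure the analysis layer assumes, plus the ground-truth
parameters needed for recovery testing:

* per-group, per-night-half 5x5 row-stochastic generating matrices — the
  patient presets carry elevated wake-entry probabilities that rise further
  in the second night-half, REM-instability (wake->REM, N1->REM, REM->wake,
  REM->N1) and N2->N1 elevation; the sibling presets are half-stationary;
* between-subject heterogeneity via Dirichlet row perturbation of the group
  matrices;
* sibling-pair family clustering with a shared per-family multiplier on
  wake-entry probabilities;
* occasional early-REM onsets (REM within 15 min of sleep onset), more
  frequent in patients;
* 30-s twins derived from the 5-s night by within-window majority vote.

Effects are injected on the transition-matrix scale, never on the index
scale, so every downstream statistic is an emergent consequence of the
generating dynamics. All entry points are deterministic under a fixed seed.

The preset matrices are plausibility-tuned (no cohort-level matrices are
published for this design): diagonals set stage-bout time scales, rows are
tuned so the stationary stage occupancies and per-hour transition indices
fall in the range reported for sibling/patient groups in mini-epoch
scorings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, downsample_majority, ensure_valid
from .markov import estimate_transition_matrix
from .stages import N_STAGES, SleepStage

_W = int(SleepStage.WAKE)
_R = int(SleepStage.REM)
_SLEEP_ROWS = (1, 2, 3, 4)  # N1, N2, N3, REM rows (wake-entry origins)

GROUPS = ("patient", "sibling")
HALVES = ("first", "second")

#: Sibling base dynamics at 5-s steps, order (W, N1, N2, N3, R).
SIBLING_BASE = np.array(
    [
        [0.900, 0.060, 0.025, 0.002, 0.013],
        [0.030, 0.850, 0.105, 0.001, 0.014],
        [0.010, 0.005, 0.965, 0.013, 0.007],
        [0.004, 0.002, 0.038, 0.955, 0.001],
        [0.016, 0.012, 0.014, 0.000, 0.958],
    ]
)


def scale_cells(
    P: np.ndarray, factors: Mapping[tuple[int, int], float]
) -> np.ndarray:
    """Multiply selected off-diagonal cells, absorbing the change into the
    diagonal so rows stay stochastic."""
    Q = P.copy()
    for (i, j), f in factors.items():
        if i == j:
            raise ValueError("diagonal cells are adjusted implicitly")
        delta = Q[i, j] * (f - 1.0)
        if Q[i, i] - delta <= 0:
            raise ValueError(f"factor {f} on cell ({i},{j}) empties the diagonal")
        Q[i, j] += delta
        Q[i, i] -= delta
    return Q


def scale_wake_entry(P: np.ndarray, factor: float) -> np.ndarray:
    """Scale all sleep->WAKE probabilities by ``factor`` (diagonal absorbs)."""
    return scale_cells(P, {(i, _W): factor for i in _SLEEP_ROWS})


def default_matrices() -> dict[tuple[str, str], np.ndarray]:
    """The documented group x night-half generating presets."""
    sib = SIBLING_BASE
    pat_first = scale_wake_entry(sib, 2.0)
    pat_first = scale_cells(
        pat_first,
        {
            (_W, _R): 3.0,   # wake -> REM instability
            (1, _R): 2.5,    # N1 -> REM
            (2, 1): 2.0,     # N2 -> N1 lightening
            (_R, 1): 2.0,    # REM -> N1
        },
    )
    pat_second = scale_wake_entry(pat_first, 1.4)
    return {
        ("patient", "first"): pat_first,
        ("patient", "second"): pat_second,
        ("sibling", "first"): sib.copy(),
        ("sibling", "second"): sib.copy(),
    }


@dataclass
class GeneratorConfig:
    """Cohort-generation parameters.

    Defaults mirror the target study conditions: 125 patients and 100
    non-narcoleptic siblings, each sibling sharing a family with one
    patient; ~8 h nights of 5-s mini-epochs; early-REM frequencies of
    0.60 (patients) and 0.14 (siblings).
    """

    n_patients: int = 125
    n_siblings: int = 100
    family_pairing: float = 1.0
    matrices: dict[tuple[str, str], np.ndarray] = field(
        default_factory=default_matrices
    )
    subject_heterogeneity: float = 150.0  # Dirichlet concentration
    family_effect_sd: float = 0.2  # log-sd of wake-entry multiplier
    night_length_miniepochs: int = 5760  # ~8 h of 5-s units
    lights_padding: tuple[int, int] = (60, 24)  # pre/post wake mini-epochs
    init_distribution: tuple[float, ...] = (0.95, 0.04, 0.01, 0.0, 0.0)
    early_rem_prob: dict[str, float] = field(
        default_factory=lambda: {"patient": 0.60, "sibling": 0.14}
    )
    rem_onset_floor_minutes: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_siblings < 0:
            raise ValueError("cohort counts must be positive")
        if not 0.0 <= self.family_pairing <= 1.0:
            raise ValueError("family_pairing must lie in [0, 1]")
        for key, P in self.matrices.items():
            P = np.asarray(P)
            if P.shape != (N_STAGES, N_STAGES) or np.any(P < 0):
                raise ValueError(f"matrix {key}: need nonnegative 5x5")
            if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"matrix {key}: rows must sum to 1")
        if not np.isclose(sum(self.init_distribution), 1.0):
            raise ValueError("init_distribution must sum to 1")
        if self.night_length_miniepochs < 2:
            raise ValueError("night_length_miniepochs must be >= 2")


def _sample_chain(
    P_first: np.ndarray,
    P_second: np.ndarray,
    length: int,
    init_distribution: np.ndarray,
    rng: np.random.Generator,
    rem_floor_units: int = 0,
) -> np.ndarray:
    """Step-wise chain sampling; ``P_first`` governs steps before the
    midpoint, ``P_second`` after. During the first ``rem_floor_units`` steps
    REM entry is disabled (its probability folded into staying put),
    emulating the normally long latency to the first REM period."""
    cum_first = np.cumsum(P_first, axis=1)
    cum_second = np.cumsum(P_second, axis=1)
    if rem_floor_units > 0:
        P_floor = P_first.copy()
        P_floor[:_R, _R] = 0.0  # zero REM-entry column on non-REM rows
        P_floor[np.arange(_R), np.arange(_R)] += P_first[:_R, _R]
        cum_floor = np.cumsum(P_floor, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    s = int(np.searchsorted(np.cumsum(init_distribution), u[0], side="right"))
    s = min(s, N_STAGES - 1)
    out[0] = s
    mid = length // 2
    for t in range(1, length):
        if t < rem_floor_units and s != _R:
            row = cum_floor[s]
        elif t < mid:
            row = cum_first[s]
        else:
            row = cum_second[s]
        v = u[t]
        s = 0
        while row[s] < v:
            s += 1
        out[t] = s
    return out


def generate_hypnogram(
    matrix_first: np.ndarray,
    matrix_second: np.ndarray,
    length: int,
    init_distribution=(0.95, 0.04, 0.01, 0.0, 0.0),
    seed: int | np.random.Generator = 0,
    subject_id: str = "SIM",
    epoch_seconds: float = 5.0,
) -> Hypnogram:
    """Sample one Markov night: ``matrix_first`` governs steps before the
    midpoint, ``matrix_second`` after. Deterministic under a fixed seed."""
    for P in (matrix_first, matrix_second):
        P = np.asarray(P)
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9) or np.any(P < 0):
            raise ValueError("generating matrix rows must be stochastic")
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    chain = _sample_chain(
        np.asarray(matrix_first, dtype=float),
        np.asarray(matrix_second, dtype=float),
        length,
        np.asarray(init_distribution, dtype=float),
        rng,
    )
    return ensure_valid(
        Hypnogram(subject_id, chain, epoch_seconds, 0, length)
    )


def _personalize(
    P: np.ndarray, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet row perturbation; zero cells stay zero, rows stay stochastic."""
    Q = np.empty_like(P)
    for i in range(N_STAGES):
        alpha = concentration * P[i]
        pos = alpha > 0
        draw = np.zeros(N_STAGES)
        draw[pos] = rng.dirichlet(alpha[pos])
        Q[i] = draw
    return Q


def _inject_early_rem(
    chain: np.ndarray, rng: np.random.Generator, window_units: int = 180
) -> np.ndarray:
    """Force a brief REM bout within 15 min (180 mini-epochs) of sleep onset."""
    sleep = np.isin(chain, (1, 2, 3, 4))
    if not sleep.any():
        return chain
    onset = int(np.flatnonzero(sleep)[0])
    hi = min(onset + window_units, chain.size - 3)
    if hi <= onset:
        return chain
    if np.any(chain[onset:hi] == _R):
        return chain  # already early-REM
    t = int(rng.integers(onset, hi))
    chain = chain.copy()
    chain[t : t + 3] = _R
    return chain


@dataclass
class SyntheticCohort:
    """Generated cohort: paired hypnograms, covariates, and ground truth."""

    hypnograms_5s: list[Hypnogram]
    hypnograms_30s: list[Hypnogram]
    cohort_table: pd.DataFrame
    ground_truth: dict
    config: GeneratorConfig


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort under ``config``.

    Per subject: personalize the group matrices (Dirichlet rows), apply the
    family wake-entry multiplier (shared within family), sample the 5-s
    night, optionally inject early REM, pad with lights-on wake, and derive
    the 30-s twin by majority downsampling.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pairs = int(round(config.family_pairing * min(config.n_patients,
                                                    config.n_siblings)))
    subjects: list[dict] = []
    fam_counter = 0
    sib_fams: list[str] = []
    for i in range(config.n_patients):
        fam = f"FAM{fam_counter:04d}"
        fam_counter += 1
        if i < n_pairs:
            sib_fams.append(fam)
        subjects.append({"subject_id": f"P{i:03d}", "family_id": fam,
                         "group": "patient"})
    for j in range(config.n_siblings):
        if j < len(sib_fams):
            fam = sib_fams[j]
        else:
            fam = f"FAM{fam_counter:04d}"
            fam_counter += 1
        subjects.append({"subject_id": f"S{j:03d}", "family_id": fam,
                         "group": "sibling"})

    family_factor = {
        fam: float(np.exp(rng.normal(0.0, config.family_effect_sd)))
        for fam in {s["family_id"] for s in subjects}
    }

    pre, post = config.lights_padding
    h5s: list[Hypnogram] = []
    h30s: list[Hypnogram] = []
    truth_subjects: dict[str, dict] = {}
    records: list[dict] = []
    for sub in subjects:
        sid, grp, fam = sub["subject_id"], sub["group"], sub["family_id"]
        mats = {}
        for half in HALVES:
            P = np.asarray(config.matrices[(grp, half)], dtype=float)
            P = _personalize(P, config.subject_heterogeneity, rng)
            P = scale_wake_entry(
                P, _clip_factor(P, family_factor[fam])
            )
            mats[half] = P
        floor_units = int(round(config.rem_onset_floor_minutes * 60 / 5))
        chain = _sample_chain(
            mats["first"], mats["second"],
            config.night_length_miniepochs,
            np.asarray(config.init_distribution), rng,
            rem_floor_units=min(floor_units,
                                config.night_length_miniepochs // 2),
        )
        early_rem_forced = False
        if rng.random() < config.early_rem_prob.get(grp, 0.0):
            new_chain = _inject_early_rem(chain, rng)
            early_rem_forced = new_chain is not chain
            chain = new_chain
        stages = np.concatenate(
            [np.full(pre, _W, dtype=np.int8), chain,
             np.full(post, _W, dtype=np.int8)]
        )
        h5 = Hypnogram(sid, stages, 5.0, 0, stages.size)
        h5s.append(h5)
        h30s.append(downsample_majority(h5, factor=6))
        truth_subjects[sid] = {
            "group": grp,
            "family_id": fam,
            "matrix_first": mats["first"],
            "matrix_second": mats["second"],
            "family_factor": family_factor[fam],
            "chain_start": pre,
            "chain_length": config.night_length_miniepochs,
            "early_rem_forced": early_rem_forced,
        }
        records.append(sub | _sample_covariates(grp, rng))

    cohort_table = pd.DataFrame(records)
    return SyntheticCohort(
        hypnograms_5s=h5s,
        hypnograms_30s=h30s,
        cohort_table=cohort_table,
        ground_truth={
            "subjects": truth_subjects,
            "base_matrices": {k: np.asarray(v) for k, v in
                              config.matrices.items()},
            "family_factor": family_factor,
        },
        config=config,
    )


def _clip_factor(P: np.ndarray, factor: float) -> float:
    """Largest wake-entry multiplier <= factor keeping all diagonals positive."""
    for i in _SLEEP_ROWS:
        if P[i, _W] > 0:
            limit = 1.0 + 0.9 * P[i, i] / P[i, _W]
            factor = min(factor, limit)
    return max(factor, 0.0)


def _sample_covariates(group: str, rng: np.random.Generator) -> dict:
    """Covariate model: age/sex and predictor-flag frequencies shaped on the
    target cohort's demographics."""
    cov = {
        "age_years": float(np.clip(rng.normal(31.0, 11.0), 8.0, 70.0)),
        "sex": "M" if rng.random() < 0.5 else "F",
    }
    if group == "patient":
        cov |= {
            "h1n1_vaccinated": bool(rng.random() < 0.86),
            "hcrt1_undetectable": (
                bool(rng.random() < 0.59) if rng.random() > 0.04 else None
            ),
            "all_core_symptoms": bool(rng.random() < 0.58),
            "any_core_symptom": True,
            "hla_dqb1_0602": bool(rng.random() < 0.98),
            "disease_duration_years": float(rng.uniform(2.0, 25.0)),
        }
    else:
        cov |= {
            "h1n1_vaccinated": bool(rng.random() < 0.73),
            "hcrt1_undetectable": None,
            "all_core_symptoms": False,
            "any_core_symptom": bool(rng.random() < 0.35),
            "hla_dqb1_0602": bool(rng.random() < 0.61),
            "disease_duration_years": None,
        }
    return cov


def parameter_recovery_report(cohort: SyntheticCohort) -> dict[str, pd.DataFrame]:
    """Generating-vs-estimated matrix discrepancies and index summaries.

    Per-subject errors compare each half of the generated chain against that
    subject's realized matrix; pooled errors sum transition counts within
    group x half and compare against the configured base matrices.
    """
    truth = cohort.ground_truth.get("subjects")
    if not truth:
        raise ValueError("cohort carries no ground truth")
    from .fragmentation import transition_indices

    err_rows = []
    pooled_counts: dict[tuple[str, str], np.ndarray] = {
        (g, h): np.zeros((N_STAGES, N_STAGES)) for g in GROUPS for h in HALVES
    }
    idx_rows = []
    for h5 in cohort.hypnograms_5s:
        info = truth[h5.subject_id]
        start, length = info["chain_start"], info["chain_length"]
        mid = length // 2
        pieces = {
            "first": h5.stages[start : start + mid],
            "second": h5.stages[start + mid : start + length],
        }
        for half, seg in pieces.items():
            est = estimate_transition_matrix(
                Hypnogram(h5.subject_id, seg, 5.0, 0, seg.size)
            )
            pooled_counts[(info["group"], half)] += est.counts
            P_true = info[f"matrix_{half}"]
            defined = est.defined_rows
            diff = np.abs(est.probs[defined] - P_true[defined])
            err_rows.append(
                {
                    "scope": "subject",
                    "subject_id": h5.subject_id,
                    "group": info["group"],
                    "half": half,
                    "max_abs_error": float(diff.max()),
                    "mean_abs_error": float(diff.mean()),
                }
            )
        ti = transition_indices(h5)
        idx_rows.append(
            {"subject_id": h5.subject_id, "group": info["group"]}
            | {f"index_{k}": v for k, v in ti.indices_per_hour.items()}
        )
    base = cohort.ground_truth["base_matrices"]
    for (g, half), counts in pooled_counts.items():
        totals = counts.sum(axis=1)
        defined = totals > 0
        probs = np.full_like(counts, np.nan)
        probs[defined] = counts[defined] / totals[defined, None]
        diff = np.abs(probs[defined] - base[(g, half)][defined])
        err_rows.append(
            {
                "scope": "pooled",
                "subject_id": None,
                "group": g,
                "half": half,
                "max_abs_error": float(diff.max()),
                "mean_abs_error": float(diff.mean()),
            }
        )
    idx = pd.DataFrame(idx_rows)
    summaries = []
    for g, sub in idx.groupby("group"):
        for col in [c for c in idx.columns if c.startswith("index_")]:
            vals = sub[col].to_numpy()
            summaries.append(
                {
                    "group": g,
                    "metric": col,
                    "mean": float(vals.mean()),
                    "mc_low": float(np.percentile(vals, 2.5)),
                    "mc_high": float(np.percentile(vals, 97.5)),
                    "n": len(vals),
                }
            )
    return {
        "matrix_errors": pd.DataFrame(err_rows),
        "index_summary": pd.DataFrame(summaries),
    }


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write canonical hypnogram CSVs, the covariate CSV and ground truth."""
    import json

    from .io import write_cohort_table, write_hypnogram

    outdir = Path(outdir)
    (outdir / "hypnograms").mkdir(parents=True, exist_ok=True)
    for h in cohort.hypnograms_5s:
        write_hypnogram(h, outdir / "hypnograms" / f"{h.subject_id}_5s.csv")
    for h in cohort.hypnograms_30s:
        write_hypnogram(h, outdir / "hypnograms" / f"{h.subject_id}_30s.csv")
    write_cohort_table(cohort.cohort_table, outdir / "cohort.csv")
    truth = {
        sid: {
            "group": info["group"],
            "family_id": info["family_id"],
            "matrix_first": np.asarray(info["matrix_first"]).tolist(),
            "matrix_second": np.asarray(info["matrix_second"]).tolist(),
            "family_factor": info["family_factor"],
            "chain_start": info["chain_start"],
            "chain_length": info["chain_length"],
            "early_rem_forced": bool(info["early_rem_forced"]),
        }
        for sid, info in cohort.ground_truth["subjects"].items()
    }
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump({"subjects": truth, "seed": cohort.config.seed}, fh, indent=1)
    return outdir
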