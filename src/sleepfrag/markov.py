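"""Per-subject discrete-time Markov transition matrices over the five stages.

The model assumes the probability of the next stage depends only on the
current stage. For each ordered adjacent pair of scored units (self-pairs
included) the count matrix cell ``counts[from, to]`` is incremented;
probabilities are the counts row-normalized by the total number of
transitions originating from each stage. Diagonal elements are the
stage-stability probabilities. The final unit of the window originates no
transition, so origin totals exclude it; rows whose stage never originates
a transition are explicitly undefined (NaN probabilities, flagged), never
silently zero.

Matrix ordering is fixed as (WAKE, N1, N2, N3, REM) everywhere, including
file output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram
from .stages import N_STAGES, STAGE_NAMES, STAGE_ORDER, SleepStage

_U = int(SleepStage.UNSCORED)
STAGE_LABELS = [STAGE_NAMES[s] for s in STAGE_ORDER]


@dataclass
class TransitionMatrix:
    """5x5 transition counts and row-stochastic probabilities.

    ``probs`` rows with ``origin_totals == 0`` are NaN and flagged in
    ``defined_rows``.
    """

    subject_id: str
    resolution_tag: str
    counts: np.ndarray  # (5, 5) int
    probs: np.ndarray  # (5, 5) float, NaN on undefined rows
    origin_totals: np.ndarray  # (5,) int
    defined_rows: np.ndarray  # (5,) bool

    def prob(self, frm: SleepStage, to: SleepStage) -> float:
        return float(self.probs[STAGE_ORDER.index(frm), STAGE_ORDER.index(to)])

    @property
    def n_steps(self) -> int:
        """Number of counted steps (scored adjacencies)."""
        return int(self.counts.sum())

    def to_long(self) -> pd.DataFrame:
        """Long-format export: subject, resolution, from, to, count, prob."""
        rows = []
        for i, frm in enumerate(STAGE_LABELS):
            for j, to in enumerate(STAGE_LABELS):
                rows.append(
                    {
                        "subject_id": self.subject_id,
                        "resolution": self.resolution_tag,
                        "from_stage": frm,
                        "to_stage": to,
                        "count": int(self.counts[i, j]),
                        "prob": float(self.probs[i, j]),
                        "origin_total": int(self.origin_totals[i]),
                    }
                )
        return pd.DataFrame(rows)


def estimate_transition_matrix(h: Hypnogram) -> TransitionMatrix:
    """Estimate the per-subject transition matrix from the lights window.

    Adjacent pairs containing an UNSCORED unit are skipped; at least two
    scored adjacent units are required.
    """
    window = h.window
    a, b = window[:-1], window[1:]
    scored = (a != _U) & (b != _U)
    if int(scored.sum()) < 1:
        raise ValueError(
            f"{h.subject_id}: fewer than 2 adjacent scored units, "
            "cannot estimate transition matrix"
        )
    counts = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(counts, (a[scored].astype(int), b[scored].astype(int)), 1)
    origin_totals = counts.sum(axis=1)
    defined = origin_totals > 0
    probs = np.full((N_STAGES, N_STAGES), np.nan)
    probs[defined] = counts[defined] / origin_totals[defined, None]
    return TransitionMatrix(
        subject_id=h.subject_id,
        resolution_tag=h.resolution_tag,
        counts=counts,
        probs=probs,
        origin_totals=origin_totals,
        defined_rows=defined,
    )


def stage_occupancy(h: Hypnogram) -> np.ndarray:
    """Fraction of scored window units per stage, ordered (W, N1, N2, N3, R)."""
    window = h.window
    scored = window[window != _U]
    if scored.size == 0:
        raise ValueError(f"{h.subject_id}: window entirely UNSCORED")
    counts = np.bincount(scored.astype(int), minlength=N_STAGES)[:N_STAGES]
    return counts / scored.size


def stationary_distribution(
    P: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000
) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix by power iteration."""
    P = np.asarray(P, dtype=float)
    pi = np.full(P.shape[0], 1.0 / P.shape[0])
    for _ in range(max_iter):
        nxt = pi @ P
        if np.max(np.abs(nxt - pi)) < tol:
            return nxt / nxt.sum()
        pi = nxt
    return pi / pi.sum()


def matrix_table(matrices: list[TransitionMatrix]) -> pd.DataFrame:
    """Concatenate long-format exports across subjects."""
    return pd.concat([m.to_long() for m in matrices], ignore_index=True)


def write_matrix_csv(m: TransitionMatrix, path) -> None:
    """Per-subject CSV: probability block then parallel counts block."""
    prob_df = pd.DataFrame(m.probs, index=STAGE_LABELS, columns=STAGE_LABELS)
    count_df = pd.DataFrame(m.counts, index=STAGE_LABELS, columns=STAGE_LABELS)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# subject_id,{m.subject_id}\n# block,probs\n")
        prob_df.to_csv(fh, lineterminator="\n")
        fh.write("# block,counts\n")
        count_df.to_csv(fh, lineterminator="\n")
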