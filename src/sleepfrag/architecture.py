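"""Conventional sleep-architecture summaries at either scoring resolution.

All quantities are computed on the lights window ``[lights_off, lights_on)``
in units of the hypnogram's own scoring window (30-s epochs or 5-s
mini-epochs), then reported in hours/minutes:

* TIB — time in bed, the lights-window duration;
* TST — total duration scored in any sleep stage (N1, N2, N3, REM);
* SE — sleep efficiency, ``100 * TST / TIB``;
* sleep latency — lights-off to the first sleep-scored unit;
* REM latency — sleep onset to the first REM unit;
* early-appearing REM (SOREMP analogue) — at least one REM unit beginning
  strictly less than 15 minutes after sleep onset.

Sleep onset is the first unit scored as any sleep stage after lights off,
the same rule at both resolutions. Stage percentages use the non-UNSCORED
window duration as denominator, so WAKE% and the four sleep-stage
percentages always partition 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram
from .stages import SLEEP_STAGES, STAGE_NAMES, STAGE_ORDER, SleepStage

_SLEEP_CODES = np.array(sorted(int(s) for s in SLEEP_STAGES))


def sleep_onset_index(h: Hypnogram) -> int | None:
    """0-based index (within the lights window) of the first sleep unit."""
    window = h.window
    mask = np.isin(window, _SLEEP_CODES)
    idx = np.flatnonzero(mask)
    return int(idx[0]) if idx.size else None


def last_sleep_index(h: Hypnogram) -> int | None:
    """Index within the lights window of the last sleep-scored unit."""
    window = h.window
    idx = np.flatnonzero(np.isin(window, _SLEEP_CODES))
    return int(idx[-1]) if idx.size else None


@dataclass
class ArchitectureSummary:
    """Per-night sleep architecture metrics (one scoring resolution)."""

    subject_id: str
    resolution_tag: str
    tib_hours: float
    tst_hours: float
    sleep_efficiency_pct: float
    stage_pct: dict[str, float]
    sleep_latency_min: float | None
    rem_latency_min: float | None
    early_rem_flag: bool
    epochs_per_stage: dict[str, int]

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "resolution": self.resolution_tag,
            "tib_hours": self.tib_hours,
            "tst_hours": self.tst_hours,
            "sleep_efficiency_pct": self.sleep_efficiency_pct,
            "sleep_latency_min": self.sleep_latency_min,
            "rem_latency_min": self.rem_latency_min,
            "early_rem_flag": self.early_rem_flag,
        }
        for name, pct in self.stage_pct.items():
            row[f"pct_{name}"] = pct
        for name, n in self.epochs_per_stage.items():
            row[f"n_units_{name}"] = n
        return row


def compute_architecture(h: Hypnogram) -> ArchitectureSummary:
    """Compute the full architecture summary for one hypnogram."""
    window = h.window
    if window.size == 0:
        raise ValueError(f"{h.subject_id}: empty lights window")
    es = h.epoch_seconds
    tib_hours = window.size * es / 3600.0
    sleep_mask = np.isin(window, _SLEEP_CODES)
    n_sleep = int(sleep_mask.sum())
    tst_hours = n_sleep * es / 3600.0
    se = 100.0 * tst_hours / tib_hours

    counts = {
        STAGE_NAMES[s]: int((window == int(s)).sum()) for s in STAGE_ORDER
    }
    n_scored = sum(counts.values())  # excludes UNSCORED
    if n_scored > 0:
        stage_pct = {k: 100.0 * v / n_scored for k, v in counts.items()}
    else:
        stage_pct = {k: float("nan") for k in counts}

    onset = sleep_onset_index(h)
    if onset is None:
        sleep_latency_min = None
        rem_latency_min = None
        early_rem = False
    else:
        sleep_latency_min = onset * es / 60.0
        early_rem, rem_latency_min = detect_early_rem(h)

    return ArchitectureSummary(
        subject_id=h.subject_id,
        resolution_tag=h.resolution_tag,
        tib_hours=tib_hours,
        tst_hours=tst_hours,
        sleep_efficiency_pct=se,
        stage_pct=stage_pct,
        sleep_latency_min=sleep_latency_min,
        rem_latency_min=rem_latency_min,
        early_rem_flag=early_rem,
        epochs_per_stage=counts,
    )


def detect_early_rem(
    h: Hypnogram, window_minutes: float = 15.0
) -> tuple[bool, float | None]:
    """Early-appearing REM: first REM unit strictly < ``window_minutes``
    after sleep onset.

    Returns ``(flag, rem_latency_min)``; latency is ``None`` when the night
    has no sleep onset or no REM. The rule is identical for 30-s and 5-s
    inputs (at 5 s a single REM mini-epoch suffices).
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    onset = sleep_onset_index(h)
    if onset is None:
        return False, None
    window = h.window
    rem_idx = np.flatnonzero(window[onset:] == int(SleepStage.REM))
    if rem_idx.size == 0:
        return False, None
    rem_latency_min = rem_idx[0] * h.epoch_seconds / 60.0
    return bool(rem_latency_min < window_minutes), float(rem_latency_min)


def architecture_table(hypnograms: list[Hypnogram]) -> pd.DataFrame:
    """Tidy table: one row per subject x resolution."""
    return pd.DataFrame([compute_architecture(h).to_row() for h in hypnograms])
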