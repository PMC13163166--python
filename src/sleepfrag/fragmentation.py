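"""Stage-transition counting, transition indices, and wake-period taxonomy.

A transition is an ordered adjacent pair ``(s_t, s_{t+1})`` with
``s_t != s_{t+1}``, both scored (non-UNSCORED). The three categories
partition all stage changes among the five stages:

* ``sleep_wake``  — WAKE <-> {N1, N2, N3, REM}, either direction;
* ``nrem_rem``    — {N1, N2, N3} <-> REM, either direction;
* ``within_nrem`` — changes among {N1, N2, N3};
* ``all_stages``  — any change (the sum of the three above).

Transition indices divide the category counts by TST and are expressed per
hour of TST.

Wake-periods are maximal runs of consecutive WAKE mini-epochs inside the
counting region (sleep onset through the last sleep unit, so sleep latency
and terminal wake are excluded), classified by run length:
short (1 mini-epoch, <=5 s), intermediate (2-3 mini-epochs),
long (>=4 mini-epochs, >15 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import last_sleep_index, sleep_onset_index
from .hypnogram import Hypnogram
from .stages import NREM_STAGES, SLEEP_STAGES, SleepStage

CATEGORIES = ("all_stages", "nrem_rem", "sleep_wake", "within_nrem")

_SLEEP = np.array(sorted(int(s) for s in SLEEP_STAGES))
_NREM = np.array(sorted(int(s) for s in NREM_STAGES))
_W = int(SleepStage.WAKE)
_R = int(SleepStage.REM)
_U = int(SleepStage.UNSCORED)


def _pair_masks(codes: np.ndarray) -> dict[str, np.ndarray]:
    a, b = codes[:-1], codes[1:]
    scored = (a != _U) & (b != _U)
    change = (a != b) & scored
    a_nrem = np.isin(a, _NREM)
    b_nrem = np.isin(b, _NREM)
    return {
        "all_stages": change,
        "sleep_wake": change
        & (((a == _W) & np.isin(b, _SLEEP)) | (np.isin(a, _SLEEP) & (b == _W))),
        "nrem_rem": change & ((a_nrem & (b == _R)) | ((a == _R) & b_nrem)),
        "within_nrem": change & a_nrem & b_nrem,
    }


def count_transitions(h: Hypnogram, category: str) -> int:
    """Count stage changes of one category inside the lights window."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown transition category {category!r}")
    window = h.window
    if window.size < 2:
        return 0
    return int(_pair_masks(window)[category].sum())


@dataclass
class TransitionIndexSet:
    """Category transition counts and per-hour-of-TST indices for one night."""

    subject_id: str
    resolution_tag: str
    counts: dict[str, int]
    indices_per_hour: dict[str, float]
    tst_hours: float

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "resolution": self.resolution_tag,
            "tst_hours": self.tst_hours,
        }
        for cat in CATEGORIES:
            row[f"count_{cat}"] = self.counts[cat]
            row[f"index_{cat}"] = self.indices_per_hour[cat]
        return row


def transition_indices(h: Hypnogram) -> TransitionIndexSet:
    """All four category counts divided by TST, per hour.

    Raises
    ------
    ValueError
        If the window contains no sleep (TST = 0 leaves every index
        undefined).
    """
    window = h.window
    tst_hours = np.isin(window, _SLEEP).sum() * h.epoch_seconds / 3600.0
    if tst_hours <= 0:
        raise ValueError(
            f"{h.subject_id}: TST is zero, transition indices undefined"
        )
    masks = _pair_masks(window) if window.size >= 2 else {
        c: np.zeros(0, dtype=bool) for c in CATEGORIES
    }
    counts = {c: int(masks[c].sum()) for c in CATEGORIES}
    return TransitionIndexSet(
        subject_id=h.subject_id,
        resolution_tag=h.resolution_tag,
        counts=counts,
        indices_per_hour={c: counts[c] / tst_hours for c in CATEGORIES},
        tst_hours=float(tst_hours),
    )


@dataclass
class WakePeriodCounts:
    """Wake-run duration taxonomy for one 5-s night (or night-half)."""

    subject_id: str
    n_short: int
    n_intermediate: int
    n_long: int
    rates_per_hour: dict[str, float]
    tst_hours: float

    @property
    def n_total(self) -> int:
        return self.n_short + self.n_intermediate + self.n_long

    def to_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "n_wake_short": self.n_short,
            "n_wake_intermediate": self.n_intermediate,
            "n_wake_long": self.n_long,
            "rate_wake_short": self.rates_per_hour["short"],
            "rate_wake_intermediate": self.rates_per_hour["intermediate"],
            "rate_wake_long": self.rates_per_hour["long"],
            "tst_hours": self.tst_hours,
        }


def wake_run_lengths(codes: np.ndarray) -> list[int]:
    """Lengths of maximal consecutive-WAKE runs in a stage-code array."""
    wake = codes == _W
    if not wake.any():
        return []
    padded = np.concatenate(([False], wake, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return (ends - starts).tolist()


def wake_period_counts(h5: Hypnogram) -> WakePeriodCounts:
    """Classify wake runs in the post-onset region of a 5-s hypnogram.

    The counting region runs from sleep onset through the last sleep unit;
    a region boundary is always a sleep unit, so every wake run is interior.
    Rates are per hour of the night's TST.
    """
    if h5.epoch_seconds != 5:
        raise ValueError(
            "wake-period taxonomy is defined on 5-s mini-epoch hypnograms, "
            f"got epoch_seconds={h5.epoch_seconds}"
        )
    onset = sleep_onset_index(h5)
    if onset is None:
        raise ValueError(f"{h5.subject_id}: no sleep, no wake-period region")
    last = last_sleep_index(h5)
    region = h5.window[onset : last + 1]
    tst_hours = np.isin(h5.window, _SLEEP).sum() * h5.epoch_seconds / 3600.0
    runs = wake_run_lengths(region)
    n_short = sum(1 for r in runs if r == 1)
    n_intermediate = sum(1 for r in runs if 2 <= r <= 3)
    n_long = sum(1 for r in runs if r >= 4)
    return WakePeriodCounts(
        subject_id=h5.subject_id,
        n_short=n_short,
        n_intermediate=n_intermediate,
        n_long=n_long,
        rates_per_hour={
            "short": n_short / tst_hours,
            "intermediate": n_intermediate / tst_hours,
            "long": n_long / tst_hours,
        },
        tst_hours=float(tst_hours),
    )
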