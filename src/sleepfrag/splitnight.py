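"""Split-night stratification: equal halves of the total sleep period.

The total sleep period (SPT) runs from sleep onset through the last
sleep-scored unit, inclusive — sleep latency and terminal wake are excluded
so that half-specific fragmentation is not contaminated by settling-in or
final-awakening wake. The SPT is divided at ``floor(len/2)``; when the SPT
length is odd the extra unit goes to the second half. Every fragmentation
metric is then recomputed on each half exactly as on full nights, giving
one value per night-half per metric per subject for repeated-measures
modelling.

An alternative convention halving the whole lights window is available via
``boundary="lights"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import last_sleep_index, sleep_onset_index
from .fragmentation import (
    CATEGORIES,
    TransitionIndexSet,
    WakePeriodCounts,
    transition_indices,
    wake_period_counts,
)
from .hypnogram import Hypnogram
from .markov import TransitionMatrix, estimate_transition_matrix

HALVES = ("first", "second")


def split_total_sleep_period(
    h: Hypnogram, boundary: str = "spt"
) -> tuple[Hypnogram, Hypnogram]:
    """Divide a night into two equal halves.

    ``boundary="spt"`` (default) halves the total sleep period;
    ``boundary="lights"`` halves the whole lights window. Both halves are
    returned as hypnograms whose lights windows span their full extent.
    """
    if boundary == "spt":
        onset = sleep_onset_index(h)
        if onset is None:
            raise ValueError(f"{h.subject_id}: no sleep, cannot split night")
        last = last_sleep_index(h)
        region = h.window[onset : last + 1]
    elif boundary == "lights":
        region = h.window
    else:
        raise ValueError(f"unknown boundary convention {boundary!r}")
    mid = region.size // 2
    if mid == 0 or region.size - mid == 0:
        raise ValueError(f"{h.subject_id}: sleep period too short to split")
    first = Hypnogram(
        h.subject_id, region[:mid].copy(), h.epoch_seconds, 0, mid
    )
    second = Hypnogram(
        h.subject_id,
        region[mid:].copy(),
        h.epoch_seconds,
        0,
        region.size - mid,
    )
    return first, second


@dataclass
class HalfMetrics:
    """Fragmentation metrics of one night-half."""

    half: str
    tst_hours: float
    indices: TransitionIndexSet | None
    wake_periods: WakePeriodCounts | None
    matrix: TransitionMatrix | None


@dataclass
class SplitNightResult:
    """Per-half metric bundles for one subject x resolution."""

    subject_id: str
    resolution_tag: str
    halves: dict[str, HalfMetrics]
    half_boundary_index: int

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per half x metric."""
        rows = []
        for half in HALVES:
            hm = self.halves[half]
            base = {
                "subject_id": self.subject_id,
                "resolution": self.resolution_tag,
                "half": half,
                "tst_hours": hm.tst_hours,
            }
            if hm.indices is not None:
                for cat in CATEGORIES:
                    rows.append(
                        base
                        | {
                            "metric": f"index_{cat}",
                            "value": hm.indices.indices_per_hour[cat],
                        }
                    )
            if hm.wake_periods is not None:
                for name in ("short", "intermediate", "long"):
                    rows.append(
                        base
                        | {
                            "metric": f"rate_wake_{name}",
                            "value": hm.wake_periods.rates_per_hour[name],
                        }
                    )
        return pd.DataFrame(rows)


def per_half_metrics(
    h: Hypnogram,
    boundary: str = "spt",
    include_matrices: bool = False,
) -> SplitNightResult:
    """Recompute fragmentation metrics on each night-half.

    A half with zero TST keeps its slot with indices flagged undefined
    (``None``) rather than failing the whole night. Wake-period taxonomy is
    computed only for 5-s inputs.
    """
    first, second = split_total_sleep_period(h, boundary=boundary)
    halves: dict[str, HalfMetrics] = {}
    for half, hh in zip(HALVES, (first, second)):
        try:
            idx = transition_indices(hh)
            tst = idx.tst_hours
        except ValueError:
            idx, tst = None, 0.0
        wp = None
        if hh.epoch_seconds == 5 and idx is not None:
            try:
                wp = wake_period_counts(hh)
            except ValueError:
                wp = None
        mat = None
        if include_matrices and hh.n_units >= 2:
            mat = estimate_transition_matrix(hh)
        halves[half] = HalfMetrics(
            half=half, tst_hours=tst, indices=idx, wake_periods=wp, matrix=mat
        )
    return SplitNightResult(
        subject_id=h.subject_id,
        resolution_tag=h.resolution_tag,
        halves=halves,
        half_boundary_index=first.n_units,
    )


def split_night_table(
    hypnograms: list[Hypnogram], boundary: str = "spt"
) -> pd.DataFrame:
    """Long-format repeated-measures table across subjects."""
    frames = [per_half_metrics(h, boundary=boundary).to_long() for h in hypnograms]
    return pd.concat(frames, ignore_index=True)
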