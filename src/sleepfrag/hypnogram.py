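"""Hypnogram container, validation, lights-window cropping, downsampling.

A hypnogram is the per-unit sequence of scored sleep stages for one night,
together with the lights-off/lights-on analysis window. Conventions used
throughout the package:

* 0-based unit indices;
* half-open lights window ``[lights_off_index, lights_on_index)``;
* all analyses operate on the lights-cropped window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .stages import (
    N_STAGES,
    STAGE_NAMES,
    SleepStage,
)

#: Resolution tags for the two canonical scoring windows.
EPOCH30 = "epoch30"
MINIEPOCH5 = "miniepoch5"
OTHER = "other"


def resolution_tag_for(epoch_seconds: float) -> str:
    """Canonical tag for a scoring window length (30 s, 5 s, or ``other``)."""
    if epoch_seconds == 30:
        return EPOCH30
    if epoch_seconds == 5:
        return MINIEPOCH5
    return OTHER


@dataclass(frozen=True)
class Hypnogram:
    """A timed sleep-stage sequence with its lights window.

    Parameters
    ----------
    subject_id : str
        Identifier of the recorded subject.
    stages : numpy.ndarray
        Integer stage codes (:class:`~sleepfrag.stages.SleepStage` values),
        one per scoring unit.
    epoch_seconds : float
        Duration of one scoring unit; canonically 30 (epoch) or 5 (mini-epoch).
    lights_off_index, lights_on_index : int
        Half-open analysis window ``[off, on)`` in unit indices.
    """

    subject_id: str
    stages: np.ndarray
    epoch_seconds: float
    lights_off_index: int
    lights_on_index: int

    def __post_init__(self) -> None:
        # Coerce only; invariants are checked by validate()/ensure_valid() so
        # that malformed objects can still be inspected and reported on.
        codes = np.asarray(self.stages, dtype=np.int8)
        object.__setattr__(self, "stages", codes)

    # -- derived properties -------------------------------------------------

    @property
    def n_units(self) -> int:
        return int(self.stages.size)

    @property
    def resolution_tag(self) -> str:
        return resolution_tag_for(self.epoch_seconds)

    @property
    def window(self) -> np.ndarray:
        """Stage codes inside the lights window (view, not copy)."""
        return self.stages[self.lights_off_index : self.lights_on_index]

    def stage_labels(self) -> list[str]:
        return [STAGE_NAMES[SleepStage(int(c))] for c in self.stages]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.epoch_seconds == other.epoch_seconds
            and self.lights_off_index == other.lights_off_index
            and self.lights_on_index == other.lights_on_index
            and np.array_equal(self.stages, other.stages)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(
            (self.subject_id, self.epoch_seconds, self.lights_off_index,
             self.lights_on_index, self.stages.tobytes())
        )


def from_labels(
    subject_id: str,
    labels: Sequence[SleepStage | int | str],
    epoch_seconds: float,
    lights: tuple[int, int] | None = None,
) -> Hypnogram:
    """Build a Hypnogram from stage labels, tokens or codes.

    ``lights=None`` sets the window to the full sequence.
    """
    from .stages import parse_stage_token

    codes = []
    for lab in labels:
        if isinstance(lab, str):
            codes.append(int(parse_stage_token(lab)))
        else:
            codes.append(int(lab))
    arr = np.asarray(codes, dtype=np.int8)
    off, on = lights if lights is not None else (0, arr.size)
    return ensure_valid(Hypnogram(subject_id, arr, epoch_seconds, off, on))


def validate(h: Hypnogram) -> list[str]:
    """Check type invariants; return issue descriptions (empty iff valid).

    Reports rather than raises, so callers can collect issues across a
    cohort before deciding how to proceed.
    """
    issues: list[str] = []
    codes = np.asarray(h.stages)
    if codes.size == 0:
        issues.append("stages: sequence is empty")
    if not (h.epoch_seconds > 0):
        issues.append(f"epoch_seconds: must be positive, got {h.epoch_seconds}")
    if codes.size and (codes.min() < 0 or codes.max() > int(SleepStage.UNSCORED)):
        bad = int(np.flatnonzero((codes < 0) | (codes > int(SleepStage.UNSCORED)))[0])
        issues.append(f"stages: code outside vocabulary at unit {bad}")
    if not (0 <= h.lights_off_index < h.lights_on_index <= codes.size):
        issues.append(
            "lights window: require 0 <= lights_off_index < lights_on_index "
            f"<= n_units, got [{h.lights_off_index}, {h.lights_on_index}) "
            f"with n_units={codes.size}"
        )
    return issues


def ensure_valid(h: Hypnogram) -> Hypnogram:
    """Raise ``ValueError`` listing all violated invariants; return ``h``."""
    issues = validate(h)
    if issues:
        raise ValueError(
            f"invalid hypnogram for {h.subject_id!r}: " + "; ".join(issues)
        )
    return h


def crop_to_lights(h: Hypnogram) -> Hypnogram:
    """Restrict the sequence to the lights window and rebase indices.

    Idempotent: cropping a cropped hypnogram is a no-op.
    """
    window = h.stages[h.lights_off_index : h.lights_on_index].copy()
    return Hypnogram(
        subject_id=h.subject_id,
        stages=window,
        epoch_seconds=h.epoch_seconds,
        lights_off_index=0,
        lights_on_index=window.size,
    )


def downsample_majority(h5: Hypnogram, factor: int = 6) -> Hypnogram:
    """Majority-vote downsampling of a fine-grained hypnogram.

    Each output unit covers ``factor`` consecutive input units starting at
    ``lights_off_index``; its stage is the modal stage of the window. Ties
    are resolved deterministically in favour of the tied stage whose last
    occurrence lies latest in the window (forward-continuity bias). A
    trailing partial window is dropped. With the default ``factor=6`` a 5-s
    sequence becomes its 30-s twin.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    window = h5.stages[h5.lights_off_index : h5.lights_on_index]
    n_out = window.size // factor
    out = np.empty(n_out, dtype=np.int8)
    for i in range(n_out):
        out[i] = _majority_stage(window[i * factor : (i + 1) * factor])
    return Hypnogram(
        subject_id=h5.subject_id,
        stages=out,
        epoch_seconds=h5.epoch_seconds * factor,
        lights_off_index=0,
        lights_on_index=n_out,
    )


def _majority_stage(window: np.ndarray) -> int:
    """Modal stage of a window; ties go to the stage occurring last."""
    counts = np.bincount(window, minlength=N_STAGES + 1)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if tied.size == 1:
        return int(tied[0])
    # last position of each tied stage decides
    last_pos = {int(s): int(np.flatnonzero(window == s)[-1]) for s in tied}
    return max(last_pos, key=last_pos.get)


def concatenate_window(
    subject_id: str,
    pieces: Iterable[np.ndarray],
    epoch_seconds: float,
) -> Hypnogram:
    """Join stage-code arrays into one lights-spanning hypnogram (test helper)."""
    arr = np.concatenate([np.asarray(p, dtype=np.int8) for p in pieces])
    return Hypnogram(subject_id, arr, epoch_seconds, 0, arr.size)
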