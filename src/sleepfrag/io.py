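"""Hypnogram and cohort-table file I/O.

Canonical hypnogram CSV dialect (UTF-8, comma-separated, LF):

.. code-block:: text

    subject_id,S001
    epoch_seconds,5
    lights,120,5880
    index,stage
    0,W
    1,W
    2,N1
    ...

Three key-value header rows (``subject_id``; ``epoch_seconds``; ``lights``
with the half-open ``off,on`` window), a column-header row, then one row per
scoring unit with a 0-based index and a stage token. Stage tokens may be
letters (W/N1/N2/N3/R/U) or AASM numerics (0/1/2/3/5 with unscored sentinel
9); the two encodings are interchangeable and round-trip identically.

An optional EDF+ convenience reader maps "Sleep stage W/1/2/3/R" annotation
texts onto the same vocabulary; the canonical exchange path is CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, ensure_valid
from .stages import (
    STAGE_TO_LETTER,
    STAGE_TO_NUMERIC,
    SleepStage,
    parse_stage_token,
)


class HypnogramParseError(ValueError):
    """Malformed hypnogram file; the message names the offending row."""


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a canonical hypnogram CSV into a validated :class:`Hypnogram`.

    Letter-coded and numeric-coded files with identical content yield
    identical objects.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    header: dict[str, list[str]] = {}
    i = 0
    while i < len(rows) and rows[i] and rows[i][0] not in ("index",):
        key, *vals = rows[i]
        header[key.strip()] = [v.strip() for v in vals]
        i += 1
    for key in ("subject_id", "epoch_seconds", "lights"):
        if key not in header:
            raise HypnogramParseError(f"{path}: missing header row {key!r}")
    subject_id = header["subject_id"][0]
    epoch_seconds = float(header["epoch_seconds"][0])
    if len(header["lights"]) != 2:
        raise HypnogramParseError(
            f"{path}: lights header must be 'lights,off,on'"
        )
    lights_off, lights_on = (int(v) for v in header["lights"])
    if i >= len(rows) or rows[i][:2] != ["index", "stage"]:
        raise HypnogramParseError(f"{path}: expected 'index,stage' header row")
    i += 1
    codes: list[int] = []
    expected = 0
    for rownum, row in enumerate(rows[i:], start=i + 1):
        if not row:
            continue
        if len(row) < 2:
            raise HypnogramParseError(f"{path}: row {rownum}: need index,stage")
        try:
            idx = int(row[0])
        except ValueError as exc:
            raise HypnogramParseError(
                f"{path}: row {rownum}: non-integer index {row[0]!r}"
            ) from exc
        if idx != expected:
            raise HypnogramParseError(
                f"{path}: row {rownum}: non-monotone epoch index "
                f"{idx} (expected {expected})"
            )
        try:
            codes.append(int(parse_stage_token(row[1])))
        except ValueError as exc:
            raise HypnogramParseError(f"{path}: row {rownum}: {exc}") from exc
        expected += 1
    h = Hypnogram(
        subject_id=subject_id,
        stages=np.asarray(codes, dtype=np.int8),
        epoch_seconds=epoch_seconds,
        lights_off_index=lights_off,
        lights_on_index=lights_on,
    )
    return ensure_valid(h)


def write_hypnogram(
    h: Hypnogram, path: str | Path, token_style: str = "letter"
) -> Path:
    """Write a hypnogram in the canonical CSV dialect.

    ``token_style`` selects letter (W/N1/...) or ``"numeric"`` (0/1/...)
    stage tokens; both re-read to the identical object.
    """
    if token_style == "letter":
        tok = STAGE_TO_LETTER
    elif token_style == "numeric":
        tok = STAGE_TO_NUMERIC
    else:
        raise ValueError(f"unknown token_style {token_style!r}")
    path = Path(path)
    with path.open("w", newline="\n", encoding="utf-8") as fh:
        fh.write(f"subject_id,{h.subject_id}\n")
        es = h.epoch_seconds
        fh.write(f"epoch_seconds,{int(es) if es == int(es) else es}\n")
        fh.write(f"lights,{h.lights_off_index},{h.lights_on_index}\n")
        fh.write("index,stage\n")
        for i, code in enumerate(h.stages):
            fh.write(f"{i},{tok[SleepStage(int(code))]}\n")
    return path


# -- cohort covariate table -------------------------------------------------

COHORT_REQUIRED = ["subject_id", "family_id", "group", "age_years", "sex"]
COHORT_OPTIONAL = [
    "h1n1_vaccinated",
    "hcrt1_undetectable",
    "all_core_symptoms",
    "any_core_symptom",
    "hla_dqb1_0602",
    "disease_duration_years",
]
VALID_GROUPS = {"patient", "sibling"}


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the cohort covariate CSV.

    Required columns: subject_id, family_id, group (patient/sibling),
    age_years, sex (F/M). Optional predictor flags may be missing per
    subject; such subjects are excluded only from analyses using that
    predictor.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "family_id": str})
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r} in cohort table")
    bad_groups = set(df["group"].unique()) - VALID_GROUPS
    if bad_groups:
        raise ValueError(f"unknown group labels {sorted(bad_groups)}")
    bad_sex = set(df["sex"].unique()) - {"F", "M"}
    if bad_sex:
        raise ValueError(f"unknown sex labels {sorted(bad_sex)}")
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


# -- EDF+ annotation import (optional convenience) --------------------------

_EDF_STAGE_MAP = {
    "Sleep stage W": SleepStage.WAKE,
    "Sleep stage 1": SleepStage.N1,
    "Sleep stage N1": SleepStage.N1,
    "Sleep stage 2": SleepStage.N2,
    "Sleep stage N2": SleepStage.N2,
    "Sleep stage 3": SleepStage.N3,
    "Sleep stage N3": SleepStage.N3,
    "Sleep stage 4": SleepStage.N3,
    "Sleep stage R": SleepStage.REM,
    "Sleep stage ?": SleepStage.UNSCORED,
}


def hypnogram_from_annotations(
    subject_id: str,
    onsets: Sequence[float],
    durations: Sequence[float],
    descriptions: Sequence[str],
    epoch_seconds: float = 30.0,
    lights: tuple[float, float] | None = None,
) -> Hypnogram:
    """Convert EDF+-style sleep-stage annotations to a Hypnogram.

    Each annotation covers ``duration`` seconds from ``onset`` with a
    "Sleep stage X" description; unrecognised descriptions are ignored.
    ``lights`` is the (off, on) window in seconds; default spans the
    annotated extent.
    """
    events = [
        (float(o), float(d), _EDF_STAGE_MAP[desc])
        for o, d, desc in zip(onsets, durations, descriptions)
        if desc in _EDF_STAGE_MAP
    ]
    if not events:
        raise ValueError("no recognised sleep-stage annotations")
    start = min(o for o, _, _ in events)
    end = max(o + d for o, d, _ in events)
    n_units = int(round((end - start) / epoch_seconds))
    codes = np.full(n_units, int(SleepStage.UNSCORED), dtype=np.int8)
    for onset, dur, stage in events:
        i0 = int(round((onset - start) / epoch_seconds))
        i1 = int(round((onset + dur - start) / epoch_seconds))
        codes[i0:i1] = int(stage)
    if lights is None:
        off_idx, on_idx = 0, n_units
    else:
        off_idx = int(round((lights[0] - start) / epoch_seconds))
        on_idx = int(round((lights[1] - start) / epoch_seconds))
    return ensure_valid(
        Hypnogram(subject_id, codes, epoch_seconds, off_idx, on_idx)
    )


def read_edf_annotations(
    path: str | Path, subject_id: str | None = None, epoch_seconds: float = 30.0
) -> Hypnogram:
    """Read sleep-stage annotations from an EDF+ file (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "EDF+ import requires the optional dependency 'mne'"
        ) from exc
    ann = mne.read_annotations(str(path))
    return hypnogram_from_annotations(
        subject_id or Path(path).stem,
        ann.onset,
        ann.duration,
        ann.description,
        epoch_seconds=epoch_seconds,
    )
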