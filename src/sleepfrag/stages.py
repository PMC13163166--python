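"""Sleep-stage vocabulary.

The five AASM stages (wake, N1, N2, N3, REM) plus an UNSCORED sentinel for
artifact segments. UNSCORED units are carried through sequences but never
enter any metric: adjacency counts skip pairs containing UNSCORED and
occupancy denominators exclude it.
"""

from __future__ import annotations

from enum import IntEnum


class SleepStage(IntEnum):
    """The closed five-stage vocabulary plus the unscored sentinel."""

    WAKE = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4
    UNSCORED = 5


#: Canonical matrix/report ordering of the five scored stages.
STAGE_ORDER: tuple[SleepStage, ...] = (
    SleepStage.WAKE,
    SleepStage.N1,
    SleepStage.N2,
    SleepStage.N3,
    SleepStage.REM,
)

N_STAGES = 5

#: Stages counting toward total sleep time.
SLEEP_STAGES = frozenset(
    {SleepStage.N1, SleepStage.N2, SleepStage.N3, SleepStage.REM}
)
NREM_STAGES = frozenset({SleepStage.N1, SleepStage.N2, SleepStage.N3})

# Letter tokens (canonical CSV) and AASM numeric tokens (0/1/2/3/5, unscored 9).
LETTER_TO_STAGE = {
    "W": SleepStage.WAKE,
    "N1": SleepStage.N1,
    "N2": SleepStage.N2,
    "N3": SleepStage.N3,
    "R": SleepStage.REM,
    "U": SleepStage.UNSCORED,
}
STAGE_TO_LETTER = {v: k for k, v in LETTER_TO_STAGE.items()}

NUMERIC_TO_STAGE = {
    "0": SleepStage.WAKE,
    "1": SleepStage.N1,
    "2": SleepStage.N2,
    "3": SleepStage.N3,
    "5": SleepStage.REM,
    "9": SleepStage.UNSCORED,
}
STAGE_TO_NUMERIC = {v: k for k, v in NUMERIC_TO_STAGE.items()}

STAGE_NAMES = {
    SleepStage.WAKE: "WAKE",
    SleepStage.N1: "N1",
    SleepStage.N2: "N2",
    SleepStage.N3: "N3",
    SleepStage.REM: "REM",
    SleepStage.UNSCORED: "UNSCORED",
}


def parse_stage_token(token: str) -> SleepStage:
    """Map a letter (W/N1/N2/N3/R/U) or numeric (0/1/2/3/5/9) token to a stage.

    Raises
    ------
    ValueError
        If the token is outside the closed vocabulary.
    """
    token = token.strip().upper()
    if token in LETTER_TO_STAGE:
        return LETTER_TO_STAGE[token]
    if token in NUMERIC_TO_STAGE:
        return NUMERIC_TO_STAGE[token]
    raise ValueError(f"unknown sleep stage token {token!r}")
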