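"""Transition counting, per-hour indices and the wake-period taxonomy."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepfrag.fragmentation import (
    CATEGORIES,
    count_transitions,
    transition_indices,
    wake_period_counts,
    wake_run_lengths,
)
from sleepfrag.hypnogram import Hypnogram, from_labels

NREM = {1, 2, 3}
SLEEP = {1, 2, 3, 4}


def pair_scan_oracle(codes: list[int]) -> dict[str, int]:
    """Independent brute-force enumeration of adjacent ordered pairs."""
    counts = dict.fromkeys(CATEGORIES, 0)
    for a, b in zip(codes, codes[1:]):
        if a == 5 or b == 5 or a == b:
            continue
        counts["all_stages"] += 1
        if (a == 0 and b in SLEEP) or (a in SLEEP and b == 0):
            counts["sleep_wake"] += 1
        if (a in NREM and b == 4) or (a == 4 and b in NREM):
            counts["nrem_rem"] += 1
        if a in NREM and b in NREM:
            counts["within_nrem"] += 1
    return counts


def run_length_oracle(codes: list[int]) -> list[int]:
    """Wake-run lengths by itertools.groupby."""
    return [
        len(list(g)) for k, g in itertools.groupby(codes) if k == 0
    ]


class TestCountTransitions:
    def test_constant_sequence(self):
        h = from_labels("S", ["N2"] * 10, 30)
        assert all(count_transitions(h, c) == 0 for c in CATEGORIES)

    def test_worked_example(self):
        h = from_labels("S", ["W", "N1", "N2", "R", "W"], 30)
        assert count_transitions(h, "all_stages") == 4
        assert count_transitions(h, "sleep_wake") == 2
        assert count_transitions(h, "nrem_rem") == 1
        assert count_transitions(h, "within_nrem") == 1

    def test_unknown_category(self):
        with pytest.raises(ValueError, match="category"):
            count_transitions(from_labels("S", ["W", "N1"], 30), "rem_only")

    def test_matches_oracle_on_random_sequences(self, rng):
        """Counts equal brute-force pair scans on 500 sequences <= 100 units,
        with UNSCORED gaps never counted."""
        for _ in range(500):
            n = int(rng.integers(2, 101))
            codes = rng.integers(0, 6, n).tolist()
            h = Hypnogram("S", np.array(codes, dtype=np.int8), 30, 0, n)
            oracle = pair_scan_oracle(codes)
            for cat in CATEGORIES:
                assert count_transitions(h, cat) == oracle[cat]

    def test_reversal_invariance(self, rng):
        """All categories are direction-symmetric."""
        for _ in range(500):
            n = int(rng.integers(2, 60))
            codes = rng.integers(0, 6, n).tolist()
            fwd = Hypnogram("S", np.array(codes, dtype=np.int8), 30, 0, n)
            rev = Hypnogram("S", np.array(codes[::-1], dtype=np.int8), 30, 0, n)
            for cat in CATEGORIES:
                assert count_transitions(fwd, cat) == count_transitions(rev, cat)

    def test_category_partition_identity(self, rng):
        for _ in range(500):
            n = int(rng.integers(2, 80))
            codes = rng.integers(0, 6, n).tolist()
            o = pair_scan_oracle(codes)
            h = Hypnogram("S", np.array(codes, dtype=np.int8), 30, 0, n)
            assert count_transitions(h, "all_stages") == (
                o["sleep_wake"] + o["nrem_rem"] + o["within_nrem"]
            )


stage_sequences = st.lists(st.integers(0, 5), min_size=2, max_size=80)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(codes=stage_sequences)
def test_counts_equal_oracle_for_any_sequence(codes):
    """Property: every category count matches the brute-force pair scan and
    the three categories partition the all-stages count."""
    h = Hypnogram("S", np.array(codes, dtype=np.int8), 30, 0, len(codes))
    oracle = pair_scan_oracle(codes)
    got = {cat: count_transitions(h, cat) for cat in CATEGORIES}
    assert got == oracle
    assert got["all_stages"] == (
        got["sleep_wake"] + got["nrem_rem"] + got["within_nrem"]
    )


@settings(max_examples=200, derandomize=True, deadline=None)
@given(codes=st.lists(st.integers(0, 2), min_size=1, max_size=60))
def test_wake_runs_equal_groupby_oracle(codes):
    """Property: run-length encoding of wake agrees with itertools.groupby."""
    assert wake_run_lengths(np.array(codes)) == run_length_oracle(codes)


class TestTransitionIndices:
    def test_unit_arithmetic(self):
        """12 all-stage changes over exactly 1 h TST -> index 12.0/h."""
        block = ["N1", "N2"] * 6  # 11 within-NREM changes inside
        labels = block + ["N2"] * (120 - len(block) - 1) + ["N1"]
        h = from_labels("S", labels, 30)  # 120 sleep epochs = 1 h TST
        ti = transition_indices(h)
        assert ti.tst_hours == pytest.approx(1.0)
        assert ti.indices_per_hour["all_stages"] == pytest.approx(12.0)

    def test_zero_transition_night(self):
        ti = transition_indices(from_labels("S", ["N2"] * 20, 30))
        assert all(v == 0 for v in ti.indices_per_hour.values())

    def test_zero_tst_is_an_error(self):
        with pytest.raises(ValueError, match="TST"):
            transition_indices(from_labels("SUBJ", ["W"] * 10, 30))

    def test_partition_identity_on_random_nights(self, random_hypnogram, rng):
        for _ in range(200):
            h = random_hypnogram(n=int(rng.integers(10, 200)))
            ti = transition_indices(h)
            assert ti.counts["all_stages"] == (
                ti.counts["sleep_wake"] + ti.counts["nrem_rem"]
                + ti.counts["within_nrem"]
            )
            for cat in CATEGORIES:
                assert ti.indices_per_hour[cat] == pytest.approx(
                    ti.counts[cat] / ti.tst_hours
                )

    def test_miniepochs_detect_more_transitions(self, small_cohort):
        """All-stage counts in 5-s nights exceed their 30-s majority twins
        for >= 95% of synthetic nights."""
        wins = 0
        pairs = list(zip(small_cohort.hypnograms_5s, small_cohort.hypnograms_30s))
        for h5, h30 in pairs:
            if count_transitions(h5, "all_stages") >= count_transitions(
                h30, "all_stages"
            ):
                wins += 1
        assert wins / len(pairs) >= 0.95


class TestWakePeriods:
    def test_run_length_encoder_matches_groupby(self, rng):
        for _ in range(300):
            codes = rng.integers(0, 3, int(rng.integers(1, 80))).tolist()
            assert wake_run_lengths(np.array(codes)) == run_length_oracle(codes)

    def test_taxonomy_counts(self):
        """Wake runs of lengths 1, 3, 4 -> one short, one intermediate,
        one long."""
        labels = (
            ["W", "W"] + ["N2"] * 3 + ["W"] + ["N2"] * 3
            + ["W"] * 3 + ["N2"] * 3 + ["W"] * 4 + ["N2"] * 3 + ["W"]
        )
        wp = wake_period_counts(from_labels("S", labels, 5))
        assert (wp.n_short, wp.n_intermediate, wp.n_long) == (1, 1, 1)

    def test_two_miniepoch_run_is_intermediate(self):
        labels = ["N2"] * 4 + ["W", "W"] + ["N2"] * 4
        wp = wake_period_counts(from_labels("S", labels, 5))
        assert (wp.n_short, wp.n_intermediate, wp.n_long) == (0, 1, 0)

    def test_fully_asleep_region(self):
        wp = wake_period_counts(from_labels("S", ["W"] * 3 + ["N2"] * 20, 5))
        assert (wp.n_short, wp.n_intermediate, wp.n_long) == (0, 0, 0)

    def test_latency_and_terminal_wake_excluded(self):
        """Pre-onset and post-final-sleep wake never counts as a wake-period."""
        labels = ["W"] * 10 + ["N2"] * 5 + ["W"] + ["N2"] * 5 + ["W"] * 8
        wp = wake_period_counts(from_labels("S", labels, 5))
        assert wp.n_total == 1 and wp.n_short == 1

    def test_total_partition(self, rng):
        for _ in range(200):
            codes = rng.integers(0, 3, int(rng.integers(5, 120)))
            if not np.isin(codes, [1, 2]).any():
                continue
            h = Hypnogram("S", codes.astype(np.int8), 5, 0, codes.size)
            wp = wake_period_counts(h)
            sleep_idx = np.flatnonzero(np.isin(codes, [1, 2]))
            region = codes[sleep_idx[0] : sleep_idx[-1] + 1].tolist()
            assert wp.n_total == len(run_length_oracle(region))

    def test_requires_five_second_resolution(self):
        with pytest.raises(ValueError, match="5-s"):
            wake_period_counts(from_labels("S", ["N2"] * 5, 30))

    def test_no_sleep_is_an_error(self):
        with pytest.raises(ValueError, match="no sleep"):
            wake_period_counts(from_labels("S", ["W"] * 10, 5))

    def test_rates_scaled_by_tst(self):
        labels = ["N2"] * 719 + ["W"] + ["N2"] * 1  # 720 sleep units = 1 h TST
        wp = wake_period_counts(from_labels("S", labels, 5))
        assert wp.tst_hours == pytest.approx(1.0)
        assert wp.rates_per_hour["short"] == pytest.approx(1.0)
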