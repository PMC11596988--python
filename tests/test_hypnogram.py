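"""Hypnogram model, sleep-onset detection, quarters and sleep metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import quartersleep as qs
from quartersleep.errors import (
    EmptyInputError,
    HypnogramFormatError,
    NoSleepOnsetError,
    TooShortPeriodError,
)
from quartersleep.hypnogram import (
    REM_MISSING_FLAG,
    STAGES,
    Hypnogram,
    annotations_to_labels,
    find_persistent_sleep_onset,
    partition_quarters,
    quarter_night_metrics,
    read_hypnogram,
    sleep_period,
    stage_shift_index,
    whole_night_metrics,
    write_hypnogram_csv,
)

from .oracles import brute_quarters, brute_sleep_metrics, brute_sleep_period


def H(*labels):
    return Hypnogram(labels=tuple(labels))


class TestModel:
    def test_rejects_unknown_labels(self):
        with pytest.raises(HypnogramFormatError):
            H("W", "N4")

    def test_rejects_empty(self):
        with pytest.raises(EmptyInputError):
            Hypnogram(labels=())

    def test_codes_follow_canonical_order(self):
        h = H(*STAGES)
        assert list(h.codes) == [0, 1, 2, 3, 4]


class TestReadHypnogram:
    def test_csv_round_trip(self, tmp_path):
        h = H("W", "N1", "N2", "N3", "R")
        path = tmp_path / "h.csv"
        write_hypnogram_csv(h, path)
        back = read_hypnogram(path)
        assert back.labels == h.labels

    def test_csv_label_mapping(self, tmp_path):
        path = tmp_path / "h.csv"
        path.write_text("epoch_index,stage\n0,0\n1,1\n2,REM\n")
        assert read_hypnogram(path).labels == ("W", "N1", "R")

    def test_unmappable_label_raises(self, tmp_path):
        path = tmp_path / "h.csv"
        path.write_text("epoch_index,stage\n0,N4\n")
        with pytest.raises(HypnogramFormatError):
            read_hypnogram(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "h.csv"
        path.write_text("epoch_index,stage\n")
        with pytest.raises(EmptyInputError):
            read_hypnogram(path)

    def test_no_score_column(self, tmp_path):
        path = tmp_path / "h.csv"
        path.write_text("epoch_index,stage,no_score\n0,W,0\n1,N2,1\n")
        h = read_hypnogram(path)
        assert h.no_score == (False, True)

    def test_annotation_events_expand_to_epochs(self):
        # stage events as (onset s, duration s, description), as in an EDF+
        # annotation track; hand-parsed expectation
        onsets = [0.0, 60.0, 90.0]
        durations = [60.0, 30.0, 60.0]
        descriptions = ["Sleep stage W", "REM", "N2"]
        mapping = dict(qs.hypnogram.DEFAULT_LABEL_MAPPING)
        mapping["SLEEP STAGE W"] = "W"
        labels = annotations_to_labels(onsets, durations, descriptions, mapping)
        assert labels == ("W", "W", "R", "N2", "N2")


class TestPersistentSleepOnset:
    def test_immediate_onset(self):
        assert find_persistent_sleep_onset(H(*["N2"] * 10)) == 0

    def test_short_run_does_not_qualify(self):
        labels = ["W", "W", "W", "N1", "N2", "W"] + ["N1"] + ["N2"] * 9 + ["W"]
        assert find_persistent_sleep_onset(Hypnogram(tuple(labels))) == 6

    def test_all_wake_raises(self):
        with pytest.raises(NoSleepOnsetError):
            find_persistent_sleep_onset(H(*["W"] * 20))

    def test_onset_is_first_epoch_of_run(self):
        labels = ["W"] * 5 + ["N1"] * 12
        assert find_persistent_sleep_onset(Hypnogram(tuple(labels))) == 5


class TestSleepPeriod:
    def test_trailing_wake_trimmed(self):
        sp = sleep_period(H(*["N2"] * 10, "W", "W"))
        assert (sp.onset_epoch, sp.end_epoch) == (0, 10)

    def test_final_sleep_epoch_found_after_wake(self):
        sp = sleep_period(H("W", *["N2"] * 10, "W", "R", "W"))
        assert (sp.onset_epoch, sp.end_epoch) == (1, 13)

    def test_no_trailing_wake(self):
        sp = sleep_period(H(*["N2"] * 10))
        assert (sp.onset_epoch, sp.end_epoch) == (0, 10)


class TestQuarterPartition:
    @pytest.mark.parametrize("n,expected", [
        (40, [10, 10, 10, 10]),
        (42, [11, 11, 10, 10]),
        (41, [11, 10, 10, 10]),
        (43, [11, 11, 11, 10]),
    ])
    def test_remainder_goes_to_earliest_quarters(self, n, expected):
        qp = partition_quarters(qs.SleepPeriod(0, n))
        assert [b - a for a, b in qp.ranges] == expected

    def test_too_short_raises(self):
        with pytest.raises(TooShortPeriodError):
            partition_quarters(qs.SleepPeriod(0, 3))

    @given(st.integers(min_value=4, max_value=2000),
           st.integers(min_value=0, max_value=50))
    @settings(max_examples=200, deadline=None)
    def test_partition_invariants(self, n, offset):
        qp = partition_quarters(qs.SleepPeriod(offset, offset + n))
        lengths = [b - a for a, b in qp.ranges]
        assert sum(lengths) == n
        assert qp.ranges[0][0] == offset and qp.ranges[-1][1] == offset + n
        assert max(lengths) - min(lengths) <= 1
        for (a, b), (c, d) in zip(qp.ranges, qp.ranges[1:]):
            assert b == c  # contiguous, hence disjoint


class TestStageShiftIndex:
    def test_constant_night_is_zero(self):
        h = H(*["N2"] * 120)
        assert stage_shift_index(h, (0, 120)) == 0.0

    def test_alternating_night(self):
        h = Hypnogram(tuple(["N1", "N2"] * 60))
        assert stage_shift_index(h, (0, 120)) == pytest.approx(119.0)

    def test_hand_counted_example(self):
        labels = ("N1,N1,N2,N2,N3,N3,N3,N3,R,R,R,R,W,N1,N1,N1,N2,N2,N2,N2"
                  .split(","))
        h = Hypnogram(tuple(labels))
        assert stage_shift_index(h, (0, 20)) == pytest.approx(36.0)

    def test_permutation_invariance(self, rng):
        # relabelling stages must not change the number of shifts
        from .conftest import random_hypnogram
        h = random_hypnogram(rng, 20, 50)
        perm = rng.permutation(5)
        relabelled = Hypnogram(tuple(STAGES[perm[c]] for c in h.codes))
        assert stage_shift_index(h, (0, len(h))) == pytest.approx(
            stage_shift_index(relabelled, (0, len(h))))


class TestWholeNightMetrics:
    def test_single_stage_night(self):
        h = H(*["N2"] * 10)
        m = whole_night_metrics(h, sleep_period(h))
        assert m["N2-prop"] == 1.0 and m["W-prop"] == 0.0
        assert m["TST"] == 5.0 and m["SSI"] == 0.0
        assert m["REMonSet"] == 5.0 and m[REM_MISSING_FLAG] == 1.0

    def test_hand_worked_night(self):
        h = H("N1", "N2", "N2", "N2", "R", "R", "N2", "N2", "N2", "N2")
        m = whole_night_metrics(h, sleep_period(h))
        assert m["N1-prop"] == pytest.approx(0.1)
        assert m["N2-prop"] == pytest.approx(0.7)
        assert m["R-prop"] == pytest.approx(0.2)
        assert m["TST"] == pytest.approx(5.0)
        assert m["REMonSet"] == pytest.approx(2.0)
        assert m["SSI"] == pytest.approx(36.0)

    def test_schema(self):
        assert len(qs.WHOLE_NIGHT_FEATURES) == 8
        h = H(*["N2"] * 10)
        m = whole_night_metrics(h, sleep_period(h))
        assert set(qs.WHOLE_NIGHT_FEATURES) <= set(m)


class TestQuarterNightMetrics:
    def test_uniform_night(self):
        h = H(*["N2"] * 40)
        qp = partition_quarters(sleep_period(h))
        m = quarter_night_metrics(h, qp)
        for k in range(1, 5):
            assert m[f"N2-Q{k}"] == 1.0
            assert m[f"TST-Q{k}"] == 5.0
            assert m[f"SSI-Q{k}"] == 0.0

    def test_schema_and_proportions(self, rng):
        from .conftest import random_hypnogram
        assert len(qs.QUARTER_NIGHT_FEATURES) == 28
        for _ in range(20):
            h = random_hypnogram(rng, 16, 60)
            try:
                qp = partition_quarters(sleep_period(h))
            except (NoSleepOnsetError, TooShortPeriodError):
                continue
            m = quarter_night_metrics(h, qp)
            for k in range(1, 5):
                assert sum(m[f"{s}-Q{k}"] for s in STAGES) == pytest.approx(1.0)


class TestOracleEquivalence:
    def test_metrics_match_brute_force(self, rng):
        """Sleep period, quarters and all sleep metrics agree with an
        independent brute-force implementation on random hypnograms."""
        from .conftest import random_hypnogram
        checked = 0
        while checked < 150:
            h = random_hypnogram(rng, 12, 50)
            try:
                onset, end = brute_sleep_period(list(h.labels))
            except ValueError:
                with pytest.raises(NoSleepOnsetError):
                    sleep_period(h)
                continue
            sp = sleep_period(h)
            assert (sp.onset_epoch, sp.end_epoch) == (onset, end)
            if end - onset < 4:
                continue
            qp = partition_quarters(sp)
            assert list(qp.ranges) == brute_quarters(onset, end)
            expected = brute_sleep_metrics(list(h.labels), onset, end)
            got = whole_night_metrics(h, sp)
            for key, val in expected.items():
                assert got[key] == pytest.approx(val), key
            checked += 1
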