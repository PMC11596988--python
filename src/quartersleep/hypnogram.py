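"""Hypnogram data model, persistent-sleep-onset detection, quarter partitioning
and the whole-night / quarter-night sleep-metric feature sets.

A hypnogram is a sequence of 30-s epochs each scored as one of the five AASM
stages W, N1, N2, N3 or R (REM).  All analyses are restricted to the *sleep
period*: from persistent sleep onset (the first run of at least 5 min of
continuous sleep) to one past the final sleep epoch of the night.  Time-resolved
features divide that period into four equal quarter-nights.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    HypnogramFormatError,
    NoSleepOnsetError,
    TooShortPeriodError,
)

#: Canonical stage order used everywhere in the package.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")
STAGE_TO_CODE: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Default mapping from raw file labels to the canonical alphabet.  Covers the
#: common numeric conventions (0=W, 1..3=N1..N3, 5 or 4=REM) and spelled-out
#: REM labels.  Extend or override via the ``mapping`` argument of
#: :func:`read_hypnogram`.
DEFAULT_LABEL_MAPPING: dict[str, str] = {
    "W": "W", "WAKE": "W", "0": "W",
    "N1": "N1", "S1": "N1", "1": "N1",
    "N2": "N2", "S2": "N2", "2": "N2",
    "N3": "N3", "S3": "N3", "S4": "N3", "3": "N3",
    "R": "R", "REM": "R", "5": "R", "4": "R",
}

EPOCH_SECONDS_DEFAULT = 30.0


@dataclass(frozen=True)
class Hypnogram:
    """A scored night: one stage label per epoch.

    Parameters
    ----------
    labels
        Stage label per epoch, each in ``STAGES``.
    epoch_seconds
        Epoch duration in seconds (30 s unless resampled at read time).
    start_clock_time
        Optional lights-on timestamp; carried as metadata only.
    no_score
        Optional boolean mask of epochs manually marked unusable (arousal /
        noise); these are excluded from qEEG aggregation but keep their stage
        label for sleep metrics.
    """

    labels: tuple[str, ...]
    epoch_seconds: float = EPOCH_SECONDS_DEFAULT
    start_clock_time: _dt.datetime | None = None
    no_score: tuple[bool, ...] | None = None
    codes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise EmptyInputError("hypnogram has no epochs")
        if self.epoch_seconds <= 0:
            raise HypnogramFormatError("epoch_seconds must be positive")
        bad = sorted({l for l in self.labels if l not in STAGE_TO_CODE})
        if bad:
            raise HypnogramFormatError(f"labels outside alphabet {STAGES}: {bad}")
        if self.no_score is not None and len(self.no_score) != len(self.labels):
            raise HypnogramFormatError("no_score mask length mismatch")
        codes = np.array([STAGE_TO_CODE[l] for l in self.labels], dtype=np.int8)
        codes.setflags(write=False)
        object.__setattr__(self, "codes", codes)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_epochs(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SleepPeriod:
    """Half-open epoch range [onset_epoch, end_epoch) from persistent sleep
    onset to one past the final sleep epoch."""

    onset_epoch: int
    end_epoch: int

    def __post_init__(self) -> None:
        if not 0 <= self.onset_epoch < self.end_epoch:
            raise ValueError("require 0 <= onset_epoch < end_epoch")

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.onset_epoch


@dataclass(frozen=True)
class QuarterPartition:
    """Four contiguous half-open epoch ranges covering the sleep period."""

    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.ranges) != 4:
            raise ValueError("a quarter partition has exactly 4 ranges")
        for (a, b), (c, _) in zip(self.ranges, self.ranges[1:]):
            if b != c:
                raise ValueError("quarters must be contiguous")
        lengths = [b - a for a, b in self.ranges]
        if any(l <= 0 for l in lengths):
            raise ValueError("quarters must be non-empty")
        if max(lengths) - min(lengths) > 1:
            raise ValueError("quarter lengths may differ by at most one epoch")


def _labels_from_mapped(raw: Sequence[str], mapping: Mapping[str, str]) -> tuple[str, ...]:
    out = []
    for r in raw:
        key = str(r).strip()
        lab = mapping.get(key, mapping.get(key.upper()))
        if lab is None or lab not in STAGE_TO_CODE:
            raise HypnogramFormatError(f"unmappable stage label {key!r}")
        out.append(lab)
    return tuple(out)


def _resample_epochs(labels: tuple[str, ...], src_seconds: float,
                     dst_seconds: float = EPOCH_SECONDS_DEFAULT) -> tuple[str, ...]:
    """Resample a label sequence to 30-s epochs.

    Shorter source epochs are merged by per-window majority (ties go to the
    earlier label); longer ones are expanded by repetition.  Only integer
    ratios are supported.
    """
    if src_seconds == dst_seconds:
        return labels
    if dst_seconds > src_seconds:
        ratio = dst_seconds / src_seconds
        if ratio != int(ratio):
            raise HypnogramFormatError("non-integer epoch resampling ratio")
        r = int(ratio)
        n = len(labels) // r
        out = []
        for i in range(n):
            window = labels[i * r:(i + 1) * r]
            counts: dict[str, int] = {}
            for l in window:
                counts[l] = counts.get(l, 0) + 1
            out.append(max(counts, key=lambda k: (counts[k], -window.index(k))))
        return tuple(out)
    ratio = src_seconds / dst_seconds
    if ratio != int(ratio):
        raise HypnogramFormatError("non-integer epoch resampling ratio")
    r = int(ratio)
    return tuple(l for l in labels for _ in range(r))


def annotations_to_labels(onsets: Sequence[float], durations: Sequence[float],
                          descriptions: Sequence[str],
                          mapping: Mapping[str, str] | None = None,
                          epoch_seconds: float = EPOCH_SECONDS_DEFAULT) -> tuple[str, ...]:
    """Expand stage-event annotations (onset/duration/description triples, as in
    an EDF+ annotation track) into an equal-length per-epoch label sequence."""
    mapping = dict(DEFAULT_LABEL_MAPPING if mapping is None else mapping)
    events = sorted(zip(onsets, durations, descriptions))
    if not events:
        raise EmptyInputError("no stage annotations")
    labels: list[str] = []
    for onset, dur, desc in events:
        n = int(round(dur / epoch_seconds))
        lab = _labels_from_mapped([desc], mapping)[0]
        start_epoch = int(round(onset / epoch_seconds))
        if start_epoch > len(labels):  # gap: score as wake
            labels.extend("W" for _ in range(start_epoch - len(labels)))
        labels.extend(lab for _ in range(max(n, 1)))
    return tuple(labels)


def read_hypnogram(path, dialect: str = "csv",
                   mapping: Mapping[str, str] | None = None,
                   epoch_seconds: float = EPOCH_SECONDS_DEFAULT) -> Hypnogram:
    """Read a hypnogram from a CSV file or an EDF+ annotation track.

    CSV dialect: columns ``epoch_index,stage`` (header required), optional
    boolean column ``no_score``.  EDF dialect: stage events are read with
    :func:`mne.read_annotations` and expanded to 30-s epochs.
    """
    mapping = dict(DEFAULT_LABEL_MAPPING if mapping is None else mapping)
    if dialect == "csv":
        df = pd.read_csv(path, dtype=str, comment="#")
        if df.empty:
            raise EmptyInputError(f"{path}: no epochs")
        if "stage" not in df.columns:
            raise HypnogramFormatError(f"{path}: missing 'stage' column")
        if "epoch_index" in df.columns:
            df = df.sort_values("epoch_index", key=lambda s: s.astype(int))
        labels = _labels_from_mapped(df["stage"].tolist(), mapping)
        no_score = None
        if "no_score" in df.columns:
            no_score = tuple(str(v).strip().lower() in ("1", "true") for v in df["no_score"])
        if epoch_seconds != EPOCH_SECONDS_DEFAULT:
            labels = _resample_epochs(labels, epoch_seconds)
            no_score = None
        return Hypnogram(labels=labels, no_score=no_score)
    if dialect == "edf_annotations":
        import mne  # local import: EDF support is optional

        ann = mne.read_annotations(path)
        labels = annotations_to_labels(ann.onset, ann.duration, ann.description, mapping)
        return Hypnogram(labels=labels)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_hypnogram_csv(h: Hypnogram, path) -> None:
    df = pd.DataFrame({"epoch_index": np.arange(len(h)), "stage": list(h.labels)})
    if h.no_score is not None:
        df["no_score"] = [int(v) for v in h.no_score]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sleep period and quarters
# ---------------------------------------------------------------------------

def find_persistent_sleep_onset(h: Hypnogram, min_sleep_minutes: float = 5.0) -> int:
    """Index of the first epoch starting a run of continuous (non-W) sleep of at
    least ``min_sleep_minutes``.  Raises :class:`NoSleepOnsetError` if none."""
    min_epochs = min_sleep_minutes * 60.0 / h.epoch_seconds
    if min_epochs != int(min_epochs):
        raise ValueError("min_sleep_minutes must be a whole number of epochs")
    min_epochs = int(min_epochs)
    asleep = h.codes != STAGE_TO_CODE["W"]
    run = 0
    for i, a in enumerate(asleep):
        run = run + 1 if a else 0
        if run >= min_epochs:
            return i - min_epochs + 1
    raise NoSleepOnsetError(
        f"no run of >= {min_epochs} continuous sleep epochs ({min_sleep_minutes} min)")


def sleep_period(h: Hypnogram, min_sleep_minutes: float = 5.0) -> SleepPeriod:
    """Analysis window from persistent sleep onset to one past the final sleep
    epoch of the recording."""
    onset = find_persistent_sleep_onset(h, min_sleep_minutes)
    asleep = h.codes != STAGE_TO_CODE["W"]
    end = int(np.nonzero(asleep)[0][-1]) + 1
    return SleepPeriod(onset_epoch=onset, end_epoch=end)


def partition_quarters(sp: SleepPeriod) -> QuarterPartition:
    """Split the sleep period into four equal contiguous quarters.

    When the period length is not divisible by 4 the remainder epochs are
    assigned one each to the earliest quarters, so lengths differ by at most 1.
    """
    n = sp.n_epochs
    if n < 4:
        raise TooShortPeriodError(f"sleep period of {n} epochs cannot be quartered")
    base, rem = divmod(n, 4)
    lengths = [base + (1 if k < rem else 0) for k in range(4)]
    ranges = []
    start = sp.onset_epoch
    for l in lengths:
        ranges.append((start, start + l))
        start += l
    return QuarterPartition(ranges=tuple(ranges))


# ---------------------------------------------------------------------------
# Sleep metrics
# ---------------------------------------------------------------------------

#: Whole-night sleep-metric feature names (8 features).  ``REMonSet`` follows
#: the printed abbreviation for REM sleep-onset latency.
WHOLE_NIGHT_FEATURES: tuple[str, ...] = (
    "W-prop", "N1-prop", "N2-prop", "N3-prop", "R-prop", "TST", "SSI", "REMonSet",
)

#: Auxiliary flag column marking nights with no REM inside the sleep period
#: (their REMonSet is the sentinel: the full period duration).  Not part of any
#: feature set.
REM_MISSING_FLAG = "REM-missing"


def quarter_metric_names() -> tuple[str, ...]:
    """The 28 quarter-night sleep-metric names, `(metric)-(quarter)`."""
    names = []
    for k in range(1, 5):
        for s in STAGES:
            names.append(f"{s}-Q{k}")
        names.append(f"TST-Q{k}")
        names.append(f"SSI-Q{k}")
    return tuple(names)


QUARTER_NIGHT_FEATURES: tuple[str, ...] = quarter_metric_names()


def _stage_proportions(h: Hypnogram, rng: tuple[int, int]) -> np.ndarray:
    a, b = rng
    counts = np.bincount(h.codes[a:b], minlength=5).astype(float)
    return counts / (b - a)


def stage_shift_index(h: Hypnogram, rng: tuple[int, int]) -> float:
    """Stage changes per hour within the half-open epoch range (W counts as a
    stage, so sleep-wake switches are changes too)."""
    a, b = rng
    if b - a < 1:
        raise ValueError("empty range")
    codes = h.codes[a:b]
    n_changes = int(np.count_nonzero(np.diff(codes)))
    hours = (b - a) * h.epoch_seconds / 3600.0
    return n_changes / hours


def whole_night_metrics(h: Hypnogram, sp: SleepPeriod) -> dict[str, float]:
    """The 8 whole-night sleep metrics plus the REM-missing flag.

    Proportions (including W) are fractions of epochs in the sleep period, so
    they sum to 1.  TST is minutes of non-W epochs; SSI is stage changes per
    hour over the period; REMonSet is minutes from persistent sleep onset to
    the first REM epoch (sentinel: full period duration if REM never occurs).
    """
    a, b = sp.onset_epoch, sp.end_epoch
    props = _stage_proportions(h, (a, b))
    epoch_min = h.epoch_seconds / 60.0
    codes = h.codes[a:b]
    tst = float(np.count_nonzero(codes != STAGE_TO_CODE["W"])) * epoch_min
    ssi = stage_shift_index(h, (a, b))
    rem_idx = np.nonzero(codes == STAGE_TO_CODE["R"])[0]
    missing = rem_idx.size == 0
    rem_latency = (b - a) * epoch_min if missing else float(rem_idx[0]) * epoch_min
    out = {f"{s}-prop": float(props[i]) for i, s in enumerate(STAGES)}
    out["TST"] = tst
    out["SSI"] = ssi
    out["REMonSet"] = rem_latency
    out[REM_MISSING_FLAG] = float(missing)
    return out


def quarter_night_metrics(h: Hypnogram, qp: QuarterPartition) -> dict[str, float]:
    """The 28 quarter-night sleep metrics: 5 stage proportions, TST (minutes)
    and SSI (per hour) within each quarter, named `(metric)-Qk`."""
    epoch_min = h.epoch_seconds / 60.0
    out: dict[str, float] = {}
    for k, (a, b) in enumerate(qp.ranges, start=1):
        props = _stage_proportions(h, (a, b))
        for i, s in enumerate(STAGES):
            out[f"{s}-Q{k}"] = float(props[i])
        codes = h.codes[a:b]
        out[f"TST-Q{k}"] = float(np.count_nonzero(codes != STAGE_TO_CODE["W"])) * epoch_min
        out[f"SSI-Q{k}"] = stage_shift_index(h, (a, b))
    return out
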