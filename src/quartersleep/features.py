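"""Assemble the subjects x features table from the five feature extractors.

Feature sets (320 features total):

================  =====  ==========================================
whole_night           8  stage proportions, TST, SSI, REM-onset latency
quarter_metrics      28  7 sleep metrics per quarter-night
transitions         100  5x5 transition matrix per quarter-night
qeeg                120  6 bands x 5 stages per quarter-night
hypnodensity         64  16 soft-staging features per quarter-night
================  =====  ==========================================

Subjects without a persistent sleep onset are excluded (logged); subjects
lacking an EEG or hypnodensity channel get missing values in those columns,
to be imputed inside the training split of the classifier.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import NoSleepOnsetError, TooShortPeriodError
from .hypnogram import (
    QUARTER_NIGHT_FEATURES,
    REM_MISSING_FLAG,
    WHOLE_NIGHT_FEATURES,
    Hypnogram,
    partition_quarters,
    quarter_night_metrics,
    sleep_period,
    whole_night_metrics,
)
from .hypnodensity import (
    HYPNODENSITY_FEATURES,
    Hypnodensity,
    downsample_to_30s,
    hypnodensity_quarter_features,
)
from .qeeg import QEEG_FEATURES, EEGRecording, qeeg_quarter_features
from .simulate import SubjectRecord
from .transitions import TRANSITION_FEATURES, quarter_transition_features

logger = logging.getLogger(__name__)

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "whole_night": WHOLE_NIGHT_FEATURES,
    "quarter_metrics": QUARTER_NIGHT_FEATURES,
    "transitions": TRANSITION_FEATURES,
    "qeeg": QEEG_FEATURES,
    "hypnodensity": HYPNODENSITY_FEATURES,
}

ALL_FEATURES: tuple[str, ...] = sum((FEATURE_SETS[k] for k in FEATURE_SETS), ())

#: Non-feature columns of the assembled table.
META_COLUMNS = ("group", "age", REM_MISSING_FLAG)


def feature_set_columns(sets: str | Iterable[str]) -> list[str]:
    """Column names for one feature set, a comma-joined list, or 'all'.

    Names that are not feature-set names pass through as literal feature
    columns (validated against the table by the caller).
    """
    if isinstance(sets, str):
        sets = [s.strip() for s in sets.split(",")]
    cols: list[str] = []
    for s in sets:
        if s == "all":
            return list(ALL_FEATURES)
        if s in FEATURE_SETS:
            cols.extend(FEATURE_SETS[s])
        else:
            cols.append(s)
    return cols


def extract_subject_features(h: Hypnogram, eeg: EEGRecording | None = None,
                             hd: Hypnodensity | None = None) -> dict[str, float]:
    """All available features for one subject.

    Raises :class:`NoSleepOnsetError` / :class:`TooShortPeriodError` when the
    hypnogram has no analysable sleep period.
    """
    sp = sleep_period(h)
    qp = partition_quarters(sp)
    feats = whole_night_metrics(h, sp)
    feats.update(quarter_night_metrics(h, qp))
    feats.update(quarter_transition_features(h, qp))
    if eeg is not None:
        feats.update(qeeg_quarter_features(eeg, h, qp))
    else:
        feats.update({name: np.nan for name in QEEG_FEATURES})
    if hd is not None:
        feats.update(hypnodensity_quarter_features(downsample_to_30s(hd), qp))
    else:
        feats.update({name: np.nan for name in HYPNODENSITY_FEATURES})
    return feats


def extract_cohort_features(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Feature table for a cohort: index subject_id, columns group, age and the
    320 features (plus the REM-missing diagnostic flag)."""
    rows = {}
    meta = {}
    for rec in records:
        try:
            feats = extract_subject_features(rec.hypnogram, rec.eeg, rec.hypnodensity)
        except (NoSleepOnsetError, TooShortPeriodError) as exc:
            logger.warning("excluding subject %s: %s", rec.subject_id, exc)
            continue
        rows[rec.subject_id] = feats
        meta[rec.subject_id] = {"group": rec.group, "age": rec.age}
    if not rows:
        raise ValueError("no subject produced features")
    table = pd.DataFrame.from_dict(rows, orient="index")
    info = pd.DataFrame.from_dict(meta, orient="index")
    out = pd.concat([info, table], axis=1)
    order = ["group", "age"] + list(ALL_FEATURES) + [REM_MISSING_FLAG]
    return out[order]
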