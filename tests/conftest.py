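"""Shared fixtures: random hypnograms and a small synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

import quartersleep as qs
from quartersleep.hypnogram import STAGES, Hypnogram


def random_hypnogram(rng: np.random.Generator, n_min: int = 12,
                     n_max: int = 60, p_wake: float = 0.25) -> Hypnogram:
    """A random label sequence biased towards sleep so onsets usually exist."""
    n = int(rng.integers(n_min, n_max + 1))
    probs = np.array([p_wake] + [(1 - p_wake) / 4] * 4)
    codes = rng.choice(5, size=n, p=probs)
    return Hypnogram(labels=tuple(STAGES[c] for c in codes))


def random_hypnogram_with_period(rng: np.random.Generator, n_min: int = 16,
                                 n_max: int = 60) -> Hypnogram:
    """A random hypnogram guaranteed to have a quarterable sleep period."""
    from quartersleep.errors import NoSleepOnsetError, TooShortPeriodError
    from quartersleep.hypnogram import partition_quarters, sleep_period

    while True:
        h = random_hypnogram(rng, n_min, n_max)
        try:
            partition_quarters(sleep_period(h))
            return h
        except (NoSleepOnsetError, TooShortPeriodError):
            continue


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_cohort():
    """A light four-group cohort (no EEG, to keep the suite fast)."""
    cfg = qs.CohortConfig(
        n_per_group={"NT1": 12, "NT2": 8, "IH": 8, "control": 8},
        n_epochs=240, with_eeg=False, with_hypnodensity=True)
    records, manifest = qs.generate_cohort(cfg, seed=101)
    return records, manifest


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    records, _ = small_cohort
    return qs.extract_cohort_features(records)
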