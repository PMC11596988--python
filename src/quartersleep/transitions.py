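"""Quarter-night sleep-stage transition matrices.

Transitions between consecutive 30-s epochs (self-transitions included) are
counted within each quarter-night and normalized row-wise into conditional
probabilities P(next stage | current stage).  The full 5x5 matrix per quarter
yields 25 features, 100 across the night.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateRangeError
from .hypnogram import STAGES, Hypnogram, QuarterPartition


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-conditional transition probabilities over (W, N1, N2, N3, R).

    ``probs[i, j]`` = P(next = j | current = i) estimated within the range;
    rows of stages never observed as a "from" state are all zero and flagged
    in ``visited``.  Raw pair counts are retained for diagnostics and for the
    counts-per-hour representation.
    """

    probs: np.ndarray           # (5, 5) row-stochastic on visited rows
    counts: np.ndarray          # (5, 5) raw adjacent-pair counts
    visited: np.ndarray         # (5,) bool: stage occurred as a "from" state
    representation: str = "probability"

    def __post_init__(self) -> None:
        if self.representation == "probability":
            sums = self.probs.sum(axis=1)
            if not np.allclose(sums[self.visited], 1.0, atol=1e-9):
                raise ValueError("visited rows must sum to 1")
        if np.any(self.probs[~self.visited] != 0):
            raise ValueError("unvisited rows must be zero")


def transition_counts(h: Hypnogram, rng: tuple[int, int]) -> np.ndarray:
    """5x5 adjacent ordered-pair counts within the half-open epoch range."""
    a, b = rng
    if b - a < 2:
        raise DegenerateRangeError(f"range of {b - a} epochs has no transitions")
    codes = h.codes[a:b]
    counts = np.zeros((5, 5), dtype=np.int64)
    np.add.at(counts, (codes[:-1], codes[1:]), 1)
    return counts


def transition_matrix(h: Hypnogram, rng: tuple[int, int],
                      representation: str = "probability") -> TransitionMatrix:
    """Transition matrix of the epoch range.

    ``representation="probability"`` (default) gives row-conditional
    probabilities; ``"counts_per_hour"`` leaves rows unnormalized and scales
    pair counts by the range duration in hours (scale-dependent, provided for
    comparability with count-based conventions).
    """
    counts = transition_counts(h, rng)
    row_sums = counts.sum(axis=1)
    visited = row_sums > 0
    if representation == "probability":
        probs = np.zeros((5, 5), dtype=float)
        probs[visited] = counts[visited] / row_sums[visited, None]
    elif representation == "counts_per_hour":
        a, b = rng
        hours = (b - a) * h.epoch_seconds / 3600.0
        probs = counts / hours
        return TransitionMatrix(probs=np.where(visited[:, None], probs, 0.0),
                                counts=counts, visited=visited,
                                representation=representation)
    else:
        raise ValueError(f"unknown representation {representation!r}")
    return TransitionMatrix(probs=probs, counts=counts, visited=visited)


def transition_feature_names() -> tuple[str, ...]:
    """The 100 quarter-night transition feature names, `X to Y transition-Qk`."""
    names = []
    for k in range(1, 5):
        for a in STAGES:
            for b in STAGES:
                names.append(f"{a} to {b} transition-Q{k}")
    return tuple(names)


TRANSITION_FEATURES: tuple[str, ...] = transition_feature_names()


def quarter_transition_features(h: Hypnogram, qp: QuarterPartition,
                                representation: str = "probability") -> dict[str, float]:
    """Flatten the four quarter transition matrices into 100 named features.

    Pairs straddling a quarter boundary are not counted: each quarter is
    treated as an independent sequence, so across quarters the total number of
    counted pairs is the period length minus 4.
    """
    out: dict[str, float] = {}
    for k, rng in enumerate(qp.ranges, start=1):
        tm = transition_matrix(h, rng, representation=representation)
        for i, a in enumerate(STAGES):
            for j, b in enumerate(STAGES):
                out[f"{a} to {b} transition-Q{k}"] = float(tm.probs[i, j])
    return out
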