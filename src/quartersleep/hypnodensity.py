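"""Quarter-night hypnodensity features: marginals, pairwise mixtures, entropy.

A hypnodensity is a per-epoch probability distribution over the five sleep
stages (the soft output of an automated stager), which captures mixed
sleep/wake states that a hard hypnogram discards.  Native 15-s hypnodensities
are averaged pairwise down to the 30-s epoch grid.  Per quarter-night we
extract: the mean of each of the 5 stage probabilities (marginals), the mean
of each of the 10 pairwise products p_X * p_Y with X < Y in stage order
(mixed-state mass), and the mean per-epoch Shannon entropy in nats — 16
features per quarter, 64 per night.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .hypnogram import STAGES, QuarterPartition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Hypnodensity:
    """n_epochs x 5 stage-probability rows over (W, N1, N2, N3, R)."""

    probs: np.ndarray
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        if probs.ndim != 2 or probs.shape[1] != 5:
            raise ValueError("hypnodensity must be (n_epochs, 5)")
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each row must sum to 1")
        if self.epoch_seconds not in (15.0, 30.0):
            raise ValueError("epoch_seconds must be 15 or 30")
        object.__setattr__(self, "probs", probs)

    @property
    def n_epochs(self) -> int:
        return self.probs.shape[0]


def downsample_to_30s(hd: Hypnodensity) -> Hypnodensity:
    """Average consecutive 15-s row pairs down to 30-s epochs.

    An odd trailing epoch is dropped (logged).  Already-30-s input is returned
    unchanged.
    """
    if hd.epoch_seconds == 30.0:
        return hd
    n = hd.n_epochs
    if n % 2:
        logger.info("dropping odd trailing 15-s hypnodensity epoch")
        n -= 1
    pairs = hd.probs[:n].reshape(n // 2, 2, 5).mean(axis=1)
    return Hypnodensity(probs=pairs, epoch_seconds=30.0)


_PAIRS = tuple(itertools.combinations(range(5), 2))


def hypnodensity_feature_names() -> tuple[str, ...]:
    """The 64 hypnodensity feature names: marginals `pX-Qk`, mixtures `XY-Qk`,
    entropy `entropy-Qk` (e.g. `WR-Q1` = mean Pr(W)*Pr(R) in quarter 1)."""
    names = []
    for k in range(1, 5):
        for s in STAGES:
            names.append(f"p{s}-Q{k}")
        for i, j in _PAIRS:
            names.append(f"{STAGES[i]}{STAGES[j]}-Q{k}")
        names.append(f"entropy-Q{k}")
    return tuple(names)


HYPNODENSITY_FEATURES: tuple[str, ...] = hypnodensity_feature_names()


def row_entropy(probs: np.ndarray) -> np.ndarray:
    """Per-row Shannon entropy in nats, with 0 log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log(probs), 0.0)
    return -terms.sum(axis=-1)


def hypnodensity_quarter_features(hd: Hypnodensity, qp: QuarterPartition) -> dict[str, float]:
    """64 features: per quarter, mean marginals, mean per-epoch pairwise
    products, and mean per-epoch entropy.

    Mixtures are computed per epoch then averaged (capturing within-epoch
    state mixing) rather than as products of quarter-mean marginals.
    """
    if hd.epoch_seconds != 30.0:
        raise AlignmentError("hypnodensity must be on the 30-s grid; downsample first")
    if hd.n_epochs < qp.ranges[-1][1]:
        raise AlignmentError("hypnodensity shorter than the sleep period")
    out: dict[str, float] = {}
    for k, (a, b) in enumerate(qp.ranges, start=1):
        p = hd.probs[a:b]
        marg = p.mean(axis=0)
        for si, s in enumerate(STAGES):
            out[f"p{s}-Q{k}"] = float(marg[si])
        for i, j in _PAIRS:
            out[f"{STAGES[i]}{STAGES[j]}-Q{k}"] = float((p[:, i] * p[:, j]).mean())
        out[f"entropy-Q{k}"] = float(row_entropy(p).mean())
    return out


def read_hypnodensity(path) -> Hypnodensity:
    """Read a hypnodensity CSV with columns W,N1,N2,N3,R.  The epoch length is
    declared in a leading comment line `# epoch_seconds=15` (default 30)."""
    epoch_seconds = 30.0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "epoch_seconds" in first:
        epoch_seconds = float(first.split("=")[1])
    df = pd.read_csv(path, comment="#")
    missing = [c for c in STAGES if c not in df.columns]
    if missing:
        raise AlignmentError(f"{path}: missing stage columns {missing}")
    return Hypnodensity(probs=df[list(STAGES)].to_numpy(), epoch_seconds=epoch_seconds)


def write_hypnodensity_csv(hd: Hypnodensity, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# epoch_seconds={hd.epoch_seconds:g}\n")
        pd.DataFrame(hd.probs, columns=list(STAGES)).to_csv(fh, index=False)
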