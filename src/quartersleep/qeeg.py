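"""Quarter-night quantitative EEG: stage-conditional relative band powers.

Each 30-s epoch of the (single, typically C3) EEG channel is cut into fifteen
non-overlapping 2-s slices.  Slices containing clipping (samples at or beyond
the recorder limits) or flat-line stretches (three or more identical
consecutive samples) are rejected.  For every surviving slice a multitaper
power spectral density is computed (DPSS tapers, time-bandwidth 2, 3 tapers by
default) and integrated over six bands: delta 0.5-4, theta 4-8, alpha 8-12,
sigma 12-16, beta 16-30, gamma 30-47 Hz.  Relative power is each band divided
by the total over all six bands, so the six values sum to one.  Slice values
are averaged per epoch, then per (quarter-night x sleep stage) cell, giving
6 bands x 5 stages x 4 quarters = 120 features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

from .errors import AlignmentError, UndefinedPowerError
from .hypnogram import STAGES, Hypnogram, QuarterPartition

SLICE_SECONDS_DEFAULT = 2.0


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous frequency bands (Hz). Integration bins are half-open
    [low, high)."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("delta", 0.5, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 12.0),
        ("sigma", 12.0, 16.0),
        ("beta", 16.0, 30.0),
        ("gamma", 30.0, 47.0),
    )

    def __post_init__(self) -> None:
        for (_, _, hi), (_, lo2, _) in zip(self.bands, self.bands[1:]):
            if hi != lo2:
                raise ValueError("bands must be contiguous and non-overlapping")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    @property
    def fmin(self) -> float:
        return self.bands[0][1]

    @property
    def fmax(self) -> float:
        return self.bands[-1][2]


DEFAULT_BANDS = BandScheme()


@dataclass(frozen=True)
class EEGRecording:
    """Single-channel EEG aligned to a hypnogram's 30-s epoch grid.

    ``clip_min``/``clip_max`` are the recorder's physical limits used for
    clipping detection; when absent they default to the observed extrema (with
    a warning), which treats any sample touching the global range as clipped.
    """

    samples: np.ndarray
    rate: float
    clip_min: float | None = None
    clip_max: float | None = None

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(samples)):
            raise ValueError("EEG samples must be finite")
        object.__setattr__(self, "samples", samples)

    def n_epochs(self, epoch_seconds: float = 30.0) -> int:
        return int(len(self.samples) // (epoch_seconds * self.rate))

    def clip_limits(self) -> tuple[float, float]:
        if self.clip_min is not None and self.clip_max is not None:
            return float(self.clip_min), float(self.clip_max)
        warnings.warn("no recorder clip limits given; using observed extrema",
                      stacklevel=2)
        return float(self.samples.min()), float(self.samples.max())


@dataclass(frozen=True)
class EpochBandPower:
    """Mean relative band powers of one epoch over its valid 2-s slices."""

    relative: np.ndarray        # (n_bands,), sums to 1 when valid, NaN otherwise
    n_valid_slices: int
    valid: bool


@dataclass
class MultitaperConfig:
    """DPSS taper settings: half-bandwidth product NW and taper count."""

    time_bandwidth: float = 2.0
    n_tapers: int = 3


def _has_flat_run(x: np.ndarray, min_run: int = 3) -> np.ndarray:
    """Row-wise: does any run of >= min_run identical consecutive samples occur?"""
    same = np.diff(x, axis=-1) == 0
    # run of k identical samples == k-1 consecutive True in `same`
    w = min_run - 1
    if same.shape[-1] < w:
        return np.zeros(x.shape[:-1], dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(same, w, axis=-1)
    return windows.all(axis=-1).any(axis=-1)


def slice_quality_mask(e: EEGRecording, epoch: int,
                       epoch_seconds: float = 30.0,
                       slice_seconds: float = SLICE_SECONDS_DEFAULT) -> np.ndarray:
    """Boolean validity mask over the (15) slices of one epoch.

    A slice is invalid if any sample lies at or beyond the clip limits, or if
    it contains three or more identical consecutive samples.
    """
    slices = _epoch_slices(e, epoch, epoch_seconds, slice_seconds)
    return _slice_mask(slices, *e.clip_limits())


def _epoch_slices(e: EEGRecording, epoch: int, epoch_seconds: float,
                  slice_seconds: float) -> np.ndarray:
    n_per_epoch = int(round(epoch_seconds * e.rate))
    n_per_slice = int(round(slice_seconds * e.rate))
    start = epoch * n_per_epoch
    if start + n_per_epoch > len(e.samples):
        raise AlignmentError(f"epoch {epoch} beyond recording")
    seg = e.samples[start:start + n_per_epoch]
    n_slices = n_per_epoch // n_per_slice
    return seg[: n_slices * n_per_slice].reshape(n_slices, n_per_slice)


def _slice_mask(slices: np.ndarray, clip_min: float, clip_max: float) -> np.ndarray:
    clipped = ((slices <= clip_min) | (slices >= clip_max)).any(axis=-1)
    return ~(clipped | _has_flat_run(slices))


def _taper_bank(n: int, cfg: MultitaperConfig) -> np.ndarray:
    tapers = dpss(n, cfg.time_bandwidth, Kmax=cfg.n_tapers)
    return np.asarray(tapers)


def _band_bins(freqs: np.ndarray, scheme: BandScheme) -> list[np.ndarray]:
    return [(freqs >= lo) & (freqs < hi) for _, lo, hi in scheme.bands]


def multitaper_band_powers(slices: np.ndarray, rate: float,
                           scheme: BandScheme = DEFAULT_BANDS,
                           cfg: MultitaperConfig | None = None) -> np.ndarray:
    """Relative band powers for a batch of equal-length windows.

    Parameters
    ----------
    slices
        Array (n_windows, n_samples) — or a single window (n_samples,).

    Returns
    -------
    (n_windows, n_bands) relative powers, each row summing to 1.
    """
    cfg = cfg or MultitaperConfig()
    slices = np.atleast_2d(np.asarray(slices, dtype=np.float64))
    n = slices.shape[-1]
    tapers = _taper_bank(n, cfg)                      # (K, n)
    tapered = slices[:, None, :] * tapers[None, :, :]  # (m, K, n)
    spec = np.abs(rfft(tapered, axis=-1)) ** 2         # eigenspectra
    psd = spec.mean(axis=1)                            # (m, n_freq)
    freqs = rfftfreq(n, d=1.0 / rate)
    bins = _band_bins(freqs, scheme)
    band = np.stack([psd[:, b].sum(axis=-1) for b in bins], axis=-1)
    total = band.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise UndefinedPowerError("zero total power in a window")
    return band / total


def multitaper_relative_power(window: np.ndarray, rate: float,
                              scheme: BandScheme = DEFAULT_BANDS,
                              cfg: MultitaperConfig | None = None) -> np.ndarray:
    """Relative band powers of a single (2-s) window; sums to 1."""
    return multitaper_band_powers(window, rate, scheme, cfg)[0]


def epoch_band_powers(e: EEGRecording, epoch: int,
                      scheme: BandScheme = DEFAULT_BANDS,
                      cfg: MultitaperConfig | None = None,
                      epoch_seconds: float = 30.0,
                      slice_seconds: float = SLICE_SECONDS_DEFAULT) -> EpochBandPower:
    """Mean relative band powers over the valid slices of one epoch."""
    slices = _epoch_slices(e, epoch, epoch_seconds, slice_seconds)
    mask = _slice_mask(slices, *e.clip_limits())
    n_valid = int(mask.sum())
    if n_valid == 0:
        return EpochBandPower(relative=np.full(len(scheme.bands), np.nan),
                              n_valid_slices=0, valid=False)
    rel = multitaper_band_powers(slices[mask], e.rate, scheme, cfg)
    return EpochBandPower(relative=rel.mean(axis=0), n_valid_slices=n_valid, valid=True)


def qeeg_feature_names(scheme: BandScheme = DEFAULT_BANDS) -> tuple[str, ...]:
    """The 120 qEEG feature names, `band_stage_Qk`."""
    names = []
    for k in range(1, 5):
        for s in STAGES:
            for band in scheme.names:
                names.append(f"{band}_{s}_Q{k}")
    return tuple(names)


QEEG_FEATURES: tuple[str, ...] = qeeg_feature_names()


def qeeg_quarter_features(e: EEGRecording, h: Hypnogram, qp: QuarterPartition,
                          scheme: BandScheme = DEFAULT_BANDS,
                          cfg: MultitaperConfig | None = None,
                          slice_seconds: float = SLICE_SECONDS_DEFAULT) -> dict[str, float]:
    """120 stage-conditional relative band powers (quarter x stage x band).

    Epochs flagged ``no_score`` in the hypnogram and epochs with no valid
    slices are excluded; a stage never validly observed within a quarter
    yields NaN (imputed later, inside the training split of the classifier).
    """
    if e.n_epochs(h.epoch_seconds) < qp.ranges[-1][1]:
        raise AlignmentError("EEG shorter than the hypnogram sleep period")
    cfg = cfg or MultitaperConfig()
    n_per_epoch = int(round(h.epoch_seconds * e.rate))
    n_per_slice = int(round(slice_seconds * e.rate))
    slices_per_epoch = n_per_epoch // n_per_slice
    lo, hi = e.clip_limits()

    a0, b0 = qp.ranges[0][0], qp.ranges[-1][1]
    seg = e.samples[a0 * n_per_epoch: b0 * n_per_epoch]
    slices = seg.reshape((b0 - a0) * slices_per_epoch, n_per_slice)
    mask = _slice_mask(slices, lo, hi)
    rel = np.full((slices.shape[0], len(scheme.bands)), np.nan)
    if mask.any():
        rel[mask] = multitaper_band_powers(slices[mask], e.rate, scheme, cfg)
    rel = rel.reshape(b0 - a0, slices_per_epoch, -1)
    valid = mask.reshape(b0 - a0, slices_per_epoch)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN epochs
        epoch_rel = np.nanmean(np.where(valid[:, :, None], rel, np.nan), axis=1)
    epoch_valid = valid.any(axis=1)
    if h.no_score is not None:
        epoch_valid &= ~np.asarray(h.no_score[a0:b0], dtype=bool)

    out: dict[str, float] = {}
    codes = h.codes[a0:b0]
    for k, (qa, qb) in enumerate(qp.ranges, start=1):
        sel_q = slice(qa - a0, qb - a0)
        for si, s in enumerate(STAGES):
            in_cell = (codes[sel_q] == si) & epoch_valid[sel_q]
            if in_cell.any():
                cell = epoch_rel[sel_q][in_cell].mean(axis=0)
            else:
                cell = np.full(len(scheme.bands), np.nan)
            for bi, band in enumerate(scheme.names):
                out[f"{band}_{s}_Q{k}"] = float(cell[bi])
    return out
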