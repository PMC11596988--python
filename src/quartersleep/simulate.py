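"""Synthetic cohort generator for narcolepsy-vs-hypersomnia pipeline testing.

Generates labelled subjects (hypnogram + optional EEG + optional
hypnodensity + age) whose group structure emulates the reported contrasts
between narcolepsy type 1 (NT1), narcolepsy type 2 (NT2), idiopathic
hypersomnia (IH) and clinical controls:

* NT1 — short REM-onset latency, rising N1 pressure across the night,
  elevated stage-shift rate (sleep instability), flatter hypnodensities
  (mixed states);
* NT2 — intermediate instability, intermediate REM latency;
* IH / controls — long REM latency, stable near-normal architecture.

Hypnograms are drawn from a time-inhomogeneous Markov chain with
quarter-specific 5x5 transition matrices, so the transition-feature extractor
can recover the generating matrices exactly (a closed verification loop).
EEG is stage-dependent band-limited Gaussian noise whose expected relative
band powers equal the profile's band-weight table.  Hypnodensities are
Dirichlet draws concentrated on the scored stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .hypnogram import STAGES, STAGE_TO_CODE, Hypnogram, write_hypnogram_csv
from .hypnodensity import Hypnodensity, write_hypnodensity_csv
from .qeeg import DEFAULT_BANDS, BandScheme, EEGRecording

GROUPS = ("NT1", "NT2", "IH", "control")

#: Night length: 8-h recording window at 120 epochs/h.
N_EPOCHS_DEFAULT = 960
EEG_RATE_DEFAULT = 128.0


def _row_stochastic(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return m / m.sum(axis=1, keepdims=True)


def _base_matrix(stability: float, n1_pull: float) -> np.ndarray:
    """A plausible sleep-architecture transition matrix.

    ``stability`` is the common diagonal mass (stage persistence over 30-s
    epochs); ``n1_pull`` shifts off-diagonal mass towards N1, the signature of
    unstable, fragmented sleep.
    """
    off = 1.0 - stability
    # baseline off-diagonal routing (rows W, N1, N2, N3, R)
    route = np.array([
        #  W    N1    N2    N3     R
        [0.00, 0.60, 0.35, 0.00, 0.05],   # from W
        [0.25, 0.00, 0.65, 0.00, 0.10],   # from N1
        [0.15, 0.25, 0.00, 0.40, 0.20],   # from N2
        [0.10, 0.10, 0.80, 0.00, 0.00],   # from N3
        [0.30, 0.35, 0.35, 0.00, 0.00],   # from R
    ])
    route = route + n1_pull * np.array([
        [0.0, 1.0, -0.3, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 1.0, 0.0, -0.4, 0.0],
        [0.0, 0.5, -0.5, 0.0, 0.0],
        [0.0, 1.0, -0.3, 0.0, 0.0],
    ])
    route = np.clip(route, 0.0, None)
    np.fill_diagonal(route, 0.0)
    m = _row_stochastic(route) * off
    m[np.diag_indices(5)] += stability
    return m


@dataclass(frozen=True)
class GroupProfile:
    """All generator parameters for one diagnostic group.

    ``quarter_matrices`` are the group-level transition matrices used directly
    by :func:`generate_hypnogram`.  When ``stability``/``n1_pulls`` are set
    (they parameterize those matrices via the architecture template),
    :func:`sample_subject_profile` can jitter them per subject so that group
    distributions overlap, as they do in real cohorts.
    """

    group: str
    initial_dist: np.ndarray                 # (5,) distribution of the first epoch
    quarter_matrices: np.ndarray             # (4, 5, 5) row-stochastic
    rem_latency_scale_min: float             # mean REM-latency draw (minutes)
    band_weights: np.ndarray                 # (5 stages, 6 bands) relative power targets
    hd_concentration: float                  # Dirichlet sharpness of hypnodensities
    age_mean: float
    age_sd: float
    rem_latency_shape: float = 1.0           # gamma shape of the latency draw
    stability: float | None = None           # diagonal mass behind quarter_matrices
    n1_pulls: tuple[float, float, float, float] | None = None
    stability_sd: float = 0.0                # between-subject SD of stability
    pull_sd: float = 0.0                     # between-subject SD of the N1 pull
    hd_concentration_sigma: float = 0.0      # lognormal sigma of concentration

    def __post_init__(self) -> None:
        qm = np.asarray(self.quarter_matrices, dtype=float)
        if qm.shape != (4, 5, 5) or not np.allclose(qm.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("quarter matrices must be (4,5,5) row-stochastic")
        if self.rem_latency_scale_min <= 0 or self.hd_concentration <= 0:
            raise ValueError("scales must be positive")
        bw = np.asarray(self.band_weights, dtype=float)
        if bw.shape[0] != 5 or not np.allclose(bw.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("band weights must be (5, n_bands) rows summing to 1")
        object.__setattr__(self, "quarter_matrices", qm)
        object.__setattr__(self, "band_weights", bw)
        object.__setattr__(self, "initial_dist",
                           np.asarray(self.initial_dist, dtype=float))


#: Stage-dependent expected relative band powers
#: (delta, theta, alpha, sigma, beta, gamma): W alpha/beta-mixed, N1
#: theta-shifted, N2 sigma-visible, N3 delta-dominant, R theta/beta-mixed.
_BAND_WEIGHTS = np.array([
    [0.15, 0.15, 0.30, 0.10, 0.20, 0.10],   # W
    [0.25, 0.35, 0.15, 0.10, 0.10, 0.05],   # N1
    [0.40, 0.25, 0.10, 0.15, 0.07, 0.03],   # N2
    [0.70, 0.15, 0.05, 0.05, 0.03, 0.02],   # N3
    [0.25, 0.30, 0.15, 0.05, 0.17, 0.08],   # R
])


def _profile(group: str, stability: float, pulls: tuple[float, float, float, float],
             rem_scale: float, rem_shape: float, concentration: float,
             age_mean: float, age_sd: float) -> GroupProfile:
    init = np.array([0.10, 0.30, 0.60, 0.0, 0.0])
    return GroupProfile(
        group=group, initial_dist=init,
        quarter_matrices=np.stack([_base_matrix(stability, p) for p in pulls]),
        rem_latency_scale_min=rem_scale, rem_latency_shape=rem_shape,
        band_weights=_BAND_WEIGHTS, hd_concentration=concentration,
        age_mean=age_mean, age_sd=age_sd,
        stability=stability, n1_pulls=pulls,
        stability_sd=0.035, pull_sd=0.05, hd_concentration_sigma=0.4)


def default_profiles(nt1_rem_scale: float = 30.0,
                     control_rem_scale: float = 90.0) -> dict[str, GroupProfile]:
    """The four default group profiles.

    NT1 gets a short REM-latency scale, lower stage persistence (more
    off-diagonal transition mass) and N1 pull that rises across quarters;
    controls/IH get long latency and stable quarters; NT2 is intermediate.
    Between-subject jitter (stability SD 0.035, pull SD 0.05, lognormal
    concentration sigma 0.4) makes group distributions overlap as in real
    cohorts.  Ages follow the reported group means/SDs (37.0±14.5, 30.0±10.8,
    30.3±10.6, 34.4±12.0 years).
    """
    return {
        "NT1": _profile("NT1", 0.87, (0.00, 0.10, 0.20, 0.30),
                        nt1_rem_scale, 1.0, 8.0, 37.0, 14.5),
        "NT2": _profile("NT2", 0.89, (0.00, 0.03, 0.05, 0.08),
                        45.0, 2.0, 12.0, 30.0, 10.8),
        "IH": _profile("IH", 0.92, (0.0, 0.0, 0.0, 0.0),
                       control_rem_scale, 4.0, 16.0, 30.3, 10.6),
        "control": _profile("control", 0.92, (0.0, 0.0, 0.0, 0.0),
                            control_rem_scale, 4.0, 16.0, 34.4, 12.0),
    }


def contrast_profiles(nt1_rem_scale: float = 10.0,
                      control_rem_scale: float = 90.0) -> dict[str, GroupProfile]:
    """NT1 and control profiles for the classification-recovery study
    condition: the groups differ only in REM-latency scale and transition
    instability (elevated off-diagonal mass and rising N1 pull in NT1); the
    hypnodensity concentration, EEG spectra and age distribution are shared,
    so REM timing and sleep fragmentation carry all of the class signal.
    """
    nt1 = _profile("NT1", 0.90, (0.03, 0.08, 0.12, 0.18),
                   nt1_rem_scale, 1.0, 16.0, 37.0, 14.5)
    control = _profile("control", 0.92, (0.0, 0.0, 0.0, 0.0),
                       control_rem_scale, 4.0, 16.0, 37.0, 14.5)
    return {"NT1": nt1, "control": control}


def sample_subject_profile(profile: GroupProfile,
                           rng: np.random.Generator) -> GroupProfile:
    """Draw a subject-level profile around the group profile.

    Stability and quarter N1 pulls get Gaussian jitter; the hypnodensity
    concentration a lognormal factor.  Profiles without template parameters
    (``stability`` unset) are returned unchanged, so directly supplied
    matrices stay exact.
    """
    if profile.stability is None or (profile.stability_sd == 0.0
                                     and profile.pull_sd == 0.0
                                     and profile.hd_concentration_sigma == 0.0):
        return profile
    stab = float(np.clip(rng.normal(profile.stability, profile.stability_sd),
                         0.55, 0.985))
    pulls = tuple(max(0.0, p + rng.normal(0.0, profile.pull_sd))
                  for p in (profile.n1_pulls or (0.0,) * 4))
    conc = float(profile.hd_concentration
                 * np.exp(rng.normal(0.0, profile.hd_concentration_sigma)))
    return replace(
        profile,
        quarter_matrices=np.stack([_base_matrix(stab, p) for p in pulls]),
        hd_concentration=conc, stability=stab, n1_pulls=pulls)


def _suppress_rem(m: np.ndarray) -> np.ndarray:
    """Zero the REM column and renormalize rows (pre-REM-latency dynamics)."""
    out = m.copy()
    out[:, STAGE_TO_CODE["R"]] = 0.0
    return _row_stochastic(out)


def generate_hypnogram(profile: GroupProfile, n_epochs: int = N_EPOCHS_DEFAULT,
                       rng: np.random.Generator | int | None = None) -> Hypnogram:
    """Sample a night from the profile's time-inhomogeneous Markov chain.

    The REM-onset latency (minutes) is drawn from a gamma distribution with
    the profile's shape and mean (shape 1 = exponential, capturing the
    short-latency / sleep-onset-REM mode of NT1; larger shapes concentrate
    the latency away from zero as in intact REM cycling).  REM is suppressed
    (column zeroed, rows renormalized) before the latency epoch; at the first
    sleeping epoch from the latency onwards the chain is placed in REM, so
    the sampled latency is the night's actual REM onset, after which the
    quarter matrices govern unmodified.
    """
    if n_epochs < 40:
        raise ValueError("n_epochs must be at least 40")
    rng = np.random.default_rng(rng)
    latency_min = rng.gamma(profile.rem_latency_shape,
                            profile.rem_latency_scale_min / profile.rem_latency_shape)
    latency_epochs = int(np.ceil(latency_min * 2))
    mats = profile.quarter_matrices
    no_rem = np.stack([_suppress_rem(m) for m in mats])
    init = profile.initial_dist
    if latency_epochs > 0:
        init = init.copy()
        init[STAGE_TO_CODE["R"]] = 0.0
        init = init / init.sum()
    rem_code = STAGE_TO_CODE["R"]
    wake_code = STAGE_TO_CODE["W"]
    codes = np.empty(n_epochs, dtype=np.int8)
    codes[0] = rng.choice(5, p=init)
    rem_started = latency_epochs == 0 and codes[0] == rem_code
    for t in range(1, n_epochs):
        q = min(t * 4 // n_epochs, 3)
        if not rem_started:
            if t >= latency_epochs and codes[t - 1] != wake_code:
                codes[t] = rem_code
                rem_started = True
                continue
            codes[t] = rng.choice(5, p=no_rem[q][codes[t - 1]])
        else:
            codes[t] = rng.choice(5, p=mats[q][codes[t - 1]])
    return Hypnogram(labels=tuple(STAGES[c] for c in codes))


def generate_eeg(h: Hypnogram, profile: GroupProfile, rate: float = EEG_RATE_DEFAULT,
                 rng: np.random.Generator | int | None = None,
                 scheme: BandScheme = DEFAULT_BANDS,
                 artifact_rate: float = 0.0,
                 slice_seconds: float = 2.0) -> EEGRecording:
    """Stage-dependent band-limited noise aligned to the hypnogram.

    Per epoch, white Gaussian noise is shaped in the frequency domain so the
    expected relative power in band b equals the profile's band-weight entry
    for the epoch's stage.  With ``artifact_rate`` > 0, each 2-s slice is
    independently replaced by a flat line with that probability.
    """
    rng = np.random.default_rng(rng)
    n_per_epoch = int(round(h.epoch_seconds * rate))
    freqs = np.fft.rfftfreq(n_per_epoch, d=1.0 / rate)
    # per-stage amplitude envelope over rfft bins: sqrt(weight / bandwidth)
    envelopes = np.zeros((5, freqs.size))
    for si in range(5):
        for bi, (_, lo, hi) in enumerate(scheme.bands):
            sel = (freqs >= lo) & (freqs < hi)
            envelopes[si, sel] = np.sqrt(profile.band_weights[si, bi] / (hi - lo))
    samples = np.empty(len(h) * n_per_epoch)
    for t, code in enumerate(h.codes):
        spec = envelopes[code] * (rng.standard_normal(freqs.size)
                                  + 1j * rng.standard_normal(freqs.size))
        x = np.fft.irfft(spec, n=n_per_epoch)
        samples[t * n_per_epoch:(t + 1) * n_per_epoch] = x * 50.0 / x.std()
    if artifact_rate > 0:
        n_per_slice = int(round(slice_seconds * rate))
        n_slices = len(samples) // n_per_slice
        flat = rng.random(n_slices) < artifact_rate
        for i in np.nonzero(flat)[0]:
            samples[i * n_per_slice:(i + 1) * n_per_slice] = samples[i * n_per_slice]
    lim = float(np.abs(samples).max()) * 2 + 1
    return EEGRecording(samples=samples, rate=rate, clip_min=-lim, clip_max=lim)


def generate_hypnodensity(h: Hypnogram, concentration: float = 10.0,
                          rng: np.random.Generator | int | None = None,
                          epoch_seconds: float = 15.0,
                          base_alpha: float = 0.5) -> Hypnodensity:
    """Dirichlet hypnodensity rows centred on the scored stage.

    alpha_i = base_alpha + concentration * 1{i = stage}; higher concentration
    approaches one-hot rows, low concentration emulates mixed states.  Native
    epoch length 15 s (two rows per scored 30-s epoch) by default.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(rng)
    reps = 2 if epoch_seconds == 15.0 else 1
    alphas = np.full((len(h) * reps, 5), base_alpha)
    stage_rows = np.repeat(h.codes, reps)
    alphas[np.arange(len(stage_rows)), stage_rows] += concentration
    # Dirichlet via normalized gammas (vectorized across rows)
    g = rng.gamma(shape=alphas)
    probs = g / g.sum(axis=1, keepdims=True)
    return Hypnodensity(probs=probs, epoch_seconds=epoch_seconds)


@dataclass
class SubjectRecord:
    """One synthetic subject: identity, diagnosis, age and aligned recordings."""

    subject_id: str
    group: str
    age: float
    seed: int
    hypnogram: Hypnogram
    eeg: EEGRecording | None = None
    hypnodensity: Hypnodensity | None = None


@dataclass
class CohortConfig:
    """Cohort composition and generation switches.

    Default group sizes mirror the reported 114/90/105/41 cohort scaled by
    one fifth.
    """

    n_per_group: dict[str, int] = field(default_factory=lambda: {
        "NT1": 23, "NT2": 18, "IH": 21, "control": 8})
    n_epochs: int = N_EPOCHS_DEFAULT
    eeg_rate: float = EEG_RATE_DEFAULT
    with_eeg: bool = True
    with_hypnodensity: bool = True
    artifact_rate: float = 0.0
    profiles: dict[str, GroupProfile] | None = None


def generate_cohort(config: CohortConfig | None = None,
                    seed: int = 0) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate a full cohort plus a manifest of ids, groups, ages and seeds.

    Each subject gets an independent child seed from the master seed, so any
    subject is bit-reproducible from the manifest alone.
    """
    config = config or CohortConfig()
    profiles = config.profiles or default_profiles()
    master = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    rows = []
    for group, n in config.n_per_group.items():
        if group not in profiles:
            raise ValueError(f"no profile for group {group!r}")
        group_prof = profiles[group]
        for i in range(n):
            sid = f"{group}-{i:03d}"
            child_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(child_seed)
            prof = sample_subject_profile(group_prof, rng)
            age = float(np.clip(rng.normal(prof.age_mean, prof.age_sd), 18.0, 80.0))
            h = generate_hypnogram(prof, config.n_epochs, rng)
            eeg = (generate_eeg(h, prof, config.eeg_rate, rng,
                                artifact_rate=config.artifact_rate)
                   if config.with_eeg else None)
            hd = (generate_hypnodensity(h, prof.hd_concentration, rng)
                  if config.with_hypnodensity else None)
            records.append(SubjectRecord(subject_id=sid, group=group, age=age,
                                         seed=child_seed, hypnogram=h,
                                         eeg=eeg, hypnodensity=hd))
            rows.append({"subject_id": sid, "group": group, "age": age,
                         "seed": child_seed})
    return records, pd.DataFrame(rows)


def write_cohort(records: list[SubjectRecord], manifest: pd.DataFrame,
                 out_dir) -> None:
    """Write per-subject hypnogram CSV, EEG array (.npy) and hypnodensity CSV
    plus manifest.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out / "manifest.csv", index=False)
    for rec in records:
        write_hypnogram_csv(rec.hypnogram, out / f"{rec.subject_id}_hypnogram.csv")
        if rec.eeg is not None:
            np.save(out / f"{rec.subject_id}_eeg.npy", rec.eeg.samples)
        if rec.hypnodensity is not None:
            write_hypnodensity_csv(rec.hypnodensity,
                                   out / f"{rec.subject_id}_hypnodensity.csv")
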