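"""Synthetic nPSG cohort generator with known ground truth.

Each participant gets a hypnogram drawn from a per-group Markov stage
kernel, a single-channel EEG whose per-epoch spectrum realizes a
stage-conditioned band-power profile (sum of band-limited Gaussian noise
components), sigma-band spindle bursts injected during N2 and large slow
oscillations injected during N3 (all injected events recorded as truth),
and a hypnodensity drawn from a Dirichlet centered on the true stage.
Group differences are induced through exactly the levers the downstream
features measure: transition matrices, spectral profiles, spindle
parameters, and hypnodensity sharpness.

The generator emulates staged clinical recordings statistically; it makes
no claim to physiological EEG morphology beyond spectral and event
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .qeeg import BANDS, EEGRecording
from .stages import (
    EPOCH_SECONDS,
    N_STAGES,
    STAGES,
    Hypnogram,
    NoSleepOnsetError,
    detect_night_window,
)

DEFAULT_FS = 128.0
DEFAULT_RMS_UV = 15.0

#: Default per-epoch Markov kernel over (W, N1, N2, N3, R): a sticky chain
#: with clinically plausible routing (W->N1->N2->{N3, R}).
DEFAULT_TRANSITIONS = np.array(
    [
        [0.80, 0.15, 0.05, 0.00, 0.00],
        [0.10, 0.60, 0.28, 0.00, 0.02],
        [0.03, 0.05, 0.82, 0.07, 0.03],
        [0.02, 0.01, 0.10, 0.85, 0.02],
        [0.04, 0.04, 0.05, 0.00, 0.87],
    ]
)

#: Stage-conditioned relative band-power targets (delta..gamma, rows sum
#: to 1).  The sigma shares describe the *non-spindle* background (real N2
#: background sigma is 1-3 uV RMS; discrete spindles are injected on top).
DEFAULT_PROFILES = {
    "W": (0.28, 0.16, 0.30, 0.02, 0.16, 0.08),
    "N1": (0.44, 0.28, 0.14, 0.02, 0.08, 0.04),
    "N2": (0.62, 0.20, 0.08, 0.01, 0.055, 0.035),
    "N3": (0.72, 0.13, 0.05, 0.01, 0.05, 0.04),
    "R": (0.36, 0.26, 0.15, 0.02, 0.14, 0.07),
}


@dataclass(frozen=True)
class GroupSpec:
    """Generating parameters for one diagnosis-like group."""

    label: str = "group"
    n_participants: int = 20
    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy()
    )
    initial_distribution: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    )
    stage_spectral_profiles: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_PROFILES.items()}
    )
    spindle_density: float = 2.0  # events per minute of N2
    spindle_frequency_hz: float = 13.0
    spindle_amplitude_uv: float = 30.0  # peak-to-peak
    spindle_duration_s: float = 1.0
    so_rate: float = 3.0  # events per minute of N3
    so_rate_n2: float = 1.5  # events per minute of N2 (lets spindles couple)
    hypnodensity_concentration: float = 50.0
    missing_rate: float = 0.01
    n_epochs_range: tuple[int, int] = (700, 1100)
    rms_uv: float = DEFAULT_RMS_UV

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (N_STAGES, N_STAGES) or np.any(tm < 0):
            raise ValueError("transition matrix must be 5x5 and nonnegative")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if not (0 <= self.missing_rate <= 0.02):
            raise ValueError("missing_rate must lie in [0, 0.02]")
        if min(self.spindle_density, self.so_rate, self.so_rate_n2) < 0:
            raise ValueError("event rates must be nonnegative")
        object.__setattr__(self, "transition_matrix", tm)
        object.__setattr__(
            self,
            "initial_distribution",
            np.asarray(self.initial_distribution, dtype=float),
        )


@dataclass
class SyntheticTruth:
    """Ground truth for one generated recording."""

    seed: int
    spec: GroupSpec
    hypnogram: Hypnogram | None = None
    spindles: list = field(default_factory=list)  # (start_s, end_s, peak_s)
    slow_oscillations: list = field(default_factory=list)


def generate_hypnogram(spec: GroupSpec, n_epochs: int, seed: int) -> Hypnogram:
    """Draw an n_epochs stage sequence from the group's Markov kernel."""
    if n_epochs < 40:
        raise ValueError("n_epochs must be >= 40")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(spec.transition_matrix, axis=1)
    stages = np.empty(n_epochs, dtype=np.int64)
    stages[0] = rng.choice(N_STAGES, p=spec.initial_distribution)
    draws = rng.random(n_epochs - 1)
    for i in range(1, n_epochs):
        stages[i] = np.searchsorted(cum[stages[i - 1]], draws[i - 1], side="right")
    return Hypnogram(stages)


def _band_noise(n: int, fs: float, lo: float, hi: float, rng) -> np.ndarray:
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _spindle_waveform(fs: float, duration: float, freq: float, ptp: float) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return (ptp / 2.0) * np.hanning(t.size) * np.sin(2 * np.pi * freq * t)


def _so_waveform(fs: float, freq: float = 0.8, ptp: float = 120.0) -> np.ndarray:
    t = np.arange(int(round(fs / freq))) / fs
    return -(ptp / 2.0) * np.sin(2 * np.pi * freq * t)


def generate_eeg(
    hypnogram: Hypnogram, spec: GroupSpec, fs: float = DEFAULT_FS, seed: int = 0
) -> tuple[EEGRecording, SyntheticTruth]:
    """Stage-shaped colored noise plus injected spindle and SO events."""
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    rng = np.random.default_rng(seed)
    spe = int(round(hypnogram.epoch_seconds * fs))
    n = len(hypnogram) * spe

    profiles = np.array(
        [spec.stage_spectral_profiles[s] for s in STAGES], dtype=float
    )
    profiles = profiles / profiles.sum(axis=1, keepdims=True)
    stage_per_sample = np.repeat(hypnogram.stages, spe)
    x = np.zeros(n)
    for b, (_, lo, hi) in enumerate(BANDS):
        gain = spec.rms_uv * np.sqrt(profiles[stage_per_sample, b])
        x += gain * _band_noise(n, fs, lo, hi, rng)

    truth = SyntheticTruth(seed=seed, spec=spec, hypnogram=hypnogram)

    def inject(stage: str, rate_per_min: float, waveform: np.ndarray, record: list):
        epochs = np.flatnonzero(hypnogram.stages == STAGES.index(stage))
        if epochs.size == 0 or rate_per_min <= 0:
            return
        minutes = epochs.size * hypnogram.epoch_seconds / 60.0
        n_events = rng.poisson(rate_per_min * minutes)
        wav_len = waveform.size
        placed: list[tuple[int, int]] = []
        for _ in range(n_events):
            for _attempt in range(20):
                e = rng.choice(epochs)
                offset = rng.integers(0, spe - wav_len)
                start = e * spe + offset
                if all(start >= s1 or start + wav_len <= s0 for s0, s1 in placed):
                    break
            else:
                continue
            placed.append((start, start + wav_len))
            x[start : start + wav_len] += waveform
            peak = (start + wav_len // 2) / fs
            record.append((start / fs, (start + wav_len) / fs, peak))

    inject(
        "N2",
        spec.spindle_density,
        _spindle_waveform(
            fs, spec.spindle_duration_s, spec.spindle_frequency_hz,
            spec.spindle_amplitude_uv,
        ),
        truth.spindles,
    )
    inject("N3", spec.so_rate, _so_waveform(fs), truth.slow_oscillations)
    inject("N2", spec.so_rate_n2, _so_waveform(fs), truth.slow_oscillations)
    return EEGRecording(samples=x, fs=fs), truth


def generate_hypnodensity(
    hypnogram: Hypnogram, concentration: float, seed: int
) -> np.ndarray:
    """Dirichlet rows centered on the true stage (weight ``concentration``
    on the true stage, 1 elsewhere)."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    out = np.empty((len(hypnogram), N_STAGES))
    for i, s in enumerate(hypnogram.stages):
        alpha = np.ones(N_STAGES)
        alpha[s] = concentration
        out[i] = rng.dirichlet(alpha)
    return out


def _analyzable_hypnogram(
    spec: GroupSpec, n_epochs: int, seed: int, max_attempts: int = 100
) -> Hypnogram:
    """Draw hypnograms until one contains a persistent sleep onset.

    Cohort participants without ten minutes of consolidated sleep would be
    excluded from any real analysis, so the generator redraws such nights
    (deterministically, from sub-seeds derived from the participant seed).
    """
    for attempt in range(max_attempts):
        sub_seed = int((seed + 15_485_863 * attempt) % (2**31))
        hyp = generate_hypnogram(spec, n_epochs, sub_seed)
        try:
            detect_night_window(hyp)
        except NoSleepOnsetError:
            continue
        return hyp
    raise NoSleepOnsetError(
        f"no analyzable night in {max_attempts} draws; the group's "
        "transition matrix yields too-fragmented sleep"
    )


@dataclass
class ParticipantRecord:
    """One generated participant: inputs plus ground truth."""

    participant_id: str
    group: str
    hypnogram: Hypnogram
    eeg: EEGRecording
    hypnodensity: np.ndarray
    truth: SyntheticTruth


def _participant_seed(master_seed: int, index: int) -> int:
    return int((master_seed * 100003 + 7919 * index) % (2**31))


def generate_cohort(
    specs: list[GroupSpec], seed: int, fs: float = DEFAULT_FS
) -> tuple[list[ParticipantRecord], pd.DataFrame, dict]:
    """Generate all participants of a multi-group cohort.

    Returns (records, cohort table, truth-by-participant).  Demographic
    columns (age, sex, BMI) are drawn from cohort-like marginals and are
    independent of group by construction.
    """
    if not specs:
        raise ValueError("at least one GroupSpec is required")
    records: list[ParticipantRecord] = []
    rows = []
    truths: dict[str, SyntheticTruth] = {}
    demo_rng = np.random.default_rng(_participant_seed(seed, 999_983))
    idx = 0
    for spec in specs:
        for _ in range(spec.n_participants):
            pseed = _participant_seed(seed, idx)
            pid = f"P{idx:04d}"
            n_epochs = int(
                np.random.default_rng(pseed).integers(*spec.n_epochs_range)
            )
            hyp = _analyzable_hypnogram(spec, n_epochs, pseed)
            eeg, truth = generate_eeg(hyp, spec, fs=fs, seed=pseed + 1)
            hd = generate_hypnodensity(
                hyp, spec.hypnodensity_concentration, pseed + 2
            )
            records.append(
                ParticipantRecord(pid, spec.label, hyp, eeg, hd, truth)
            )
            truths[pid] = truth
            rows.append(
                {
                    "participant_id": pid,
                    "group": spec.label,
                    "age": float(np.clip(demo_rng.normal(33, 13), 18, 80)),
                    "sex": str(demo_rng.choice(["F", "M"])),
                    "bmi": float(np.clip(demo_rng.normal(24, 5), 16, 45)),
                }
            )
            idx += 1
    return records, pd.DataFrame(rows), truths


def inject_missing(
    table: pd.DataFrame, rate: float, seed: int, columns: list[str] | None = None
) -> pd.DataFrame:
    """Blank a random ``rate`` fraction of feature cells (NaN), emulating
    unusable recordings segments; mirrors the <=2% missingness the analysis
    pipeline is designed to absorb."""
    if not (0 <= rate <= 0.02):
        raise ValueError("missing rate must lie in [0, 0.02]")
    out = table.copy()
    cols = columns if columns is not None else list(out.columns)
    rng = np.random.default_rng(seed)
    mask = rng.random((len(out), len(cols))) < rate
    values = out[cols].to_numpy(dtype=float)
    values[mask] = np.nan
    out[cols] = values
    return out


def null_cohort_specs(
    n_per_group: tuple[int, int] = (20, 20),
    labels: tuple[str, str] = ("A", "B"),
    **overrides,
) -> list[GroupSpec]:
    """Two groups with identical generating parameters (exchangeable null)."""
    base = GroupSpec(**overrides)
    return [
        replace(base, label=labels[0], n_participants=n_per_group[0]),
        replace(base, label=labels[1], n_participants=n_per_group[1]),
    ]


def separated_cohort_specs(
    n_per_group: tuple[int, int] = (20, 20),
    labels: tuple[str, str] = ("A", "B"),
    **overrides,
) -> list[GroupSpec]:
    """Two strongly separated groups: distinct stage-transition structure,
    a gamma-power offset in N2/N1, and different spindle densities."""
    base = GroupSpec(**overrides)
    frag = DEFAULT_TRANSITIONS.copy()
    # group B: fragmented sleep - less sticky N2/N3, more wake re-entries
    frag[2] = (0.12, 0.15, 0.60, 0.05, 0.08)
    frag[3] = (0.10, 0.05, 0.25, 0.55, 0.05)
    frag[0] = (0.90, 0.07, 0.03, 0.00, 0.00)
    profiles_b = {k: list(v) for k, v in DEFAULT_PROFILES.items()}
    for s in ("N1", "N2"):
        p = profiles_b[s]
        p[5] *= 3.0  # gamma offset
        total = sum(p)
        profiles_b[s] = tuple(v / total for v in p)
    a = replace(base, label=labels[0], n_participants=n_per_group[0])
    b = replace(
        base,
        label=labels[1],
        n_participants=n_per_group[1],
        transition_matrix=frag,
        stage_spectral_profiles=profiles_b,
        spindle_density=base.spindle_density * 0.25,
        hypnodensity_concentration=base.hypnodensity_concentration / 5.0,
    )
    return [a, b]
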