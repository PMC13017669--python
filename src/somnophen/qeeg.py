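"""Quantitative-EEG band-power features.

The recording (C3, microvolts) is band-pass filtered to 0.5-47 Hz, tiled
into non-overlapping 2-s windows aligned to 30-s epoch starts, screened for
artifacts (flat line, saturation, high slew rate), and each clean window is
reduced to normalized multitaper band powers over six standard bands:
delta 0.5-4, theta 4-8, alpha 8-12, sigma 12-16, beta 16-30, gamma 30-47 Hz.
Features are the mean normalized band powers per (band, stage, quarter):
6 x 5 x 4 = 120 values; (stage, quarter) cells with no clean window are
missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.signal.windows import dpss

from .stages import STAGES, Hypnogram, NightWindow

#: Band edges in Hz, canonical order.
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("sigma", 12.0, 16.0),
    ("beta", 16.0, 30.0),
    ("gamma", 30.0, 47.0),
)
BAND_NAMES = tuple(b[0] for b in BANDS)

ANALYSIS_BAND = (0.5, 47.0)
WINDOW_SECONDS = 2.0

# Artifact screening defaults; the artifact classes are standard, the
# thresholds are implementation defaults (configurable).
FLAT_PTP_UV = 1.0
SATURATION_UV = 500.0
MAX_SLEW_UV = 100.0

# Multitaper setup for 2-s windows: time-bandwidth 2, 3 tapers.
MT_NW = 2.0
MT_N_TAPERS = 3


@dataclass(frozen=True)
class EEGRecording:
    """Single-channel EEG in microvolts with its sampling rate."""

    samples: np.ndarray
    fs: float
    channel_label: str = "C3"

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if self.fs < 100:
            raise ValueError("sampling rate must be >= 100 Hz")
        if not np.all(np.isfinite(arr)):
            raise ValueError("EEG contains non-finite samples")
        object.__setattr__(self, "samples", arr)


def bandpass_filter(
    samples: np.ndarray, fs: float, band: tuple[float, float] = ANALYSIS_BAND
) -> np.ndarray:
    """Zero-phase FIR band-pass, applied once to the whole recording."""
    numtaps = int(3 * fs) | 1  # odd length, ~3 s: resolves the 0.5 Hz edge
    taps = signal.firwin(numtaps, band, pass_zero=False, fs=fs)
    return signal.filtfilt(taps, [1.0], samples)


def screen_window(samples: np.ndarray, fs: float) -> str:
    """Classify one 2-s window: 'flat' | 'saturated' | 'high_slew' | 'clean'.

    Checks run in that order and the first match wins.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size != round(WINDOW_SECONDS * fs):
        raise ValueError("window must contain exactly 2 s of samples")
    if np.ptp(samples) < FLAT_PTP_UV:
        return "flat"
    if np.any(np.abs(samples) >= SATURATION_UV):
        return "saturated"
    if np.any(np.abs(np.diff(samples)) > MAX_SLEW_UV):
        return "high_slew"
    return "clean"


def _multitaper_psd(windows: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper PSD of each row of ``windows``; returns (freqs, psd)."""
    n = windows.shape[-1]
    tapers = dpss(n, MT_NW, MT_N_TAPERS)  # (n_tapers, n)
    # (..., n_tapers, n_freqs)
    spectra = np.fft.rfft(windows[..., None, :] * tapers, axis=-1)
    psd = (np.abs(spectra) ** 2).mean(axis=-2) / fs
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, psd


def multitaper_band_powers(samples: np.ndarray, fs: float) -> np.ndarray:
    """Normalized band powers (6-vector summing to 1) of one clean window."""
    out = _band_powers_batch(np.asarray(samples, float)[None, :], fs)[0]
    if not np.all(np.isfinite(out)):
        raise ValueError("degenerate window: zero total power in 0.5-47 Hz")
    return out


def _band_powers_batch(windows: np.ndarray, fs: float) -> np.ndarray:
    """Normalized band powers for a batch of windows, rows = windows."""
    freqs, psd = _multitaper_psd(windows, fs)
    powers = np.empty((windows.shape[0], len(BANDS)))
    for k, (_, lo, hi) in enumerate(BANDS):
        # half-open bins avoid double counting shared band edges
        sel = (freqs >= lo) & (freqs < hi)
        powers[:, k] = psd[:, sel].sum(axis=1)
    total = powers.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = powers / total
    out[total[:, 0] <= 0] = np.nan
    return out


def qeeg_feature_block(
    eeg: EEGRecording,
    hypnogram: Hypnogram,
    window: NightWindow,
    prefiltered: bool = False,
) -> dict[str, float]:
    """120 features: mean normalized band power per (band, stage, quarter).

    The EEG is assumed time-aligned with the hypnogram from recording start.
    Keys are ``<band>.<stage>.Q<i>``.
    """
    fs = eeg.fs
    samples_per_epoch = int(round(hypnogram.epoch_seconds * fs))
    if eeg.samples.size < (window.final_sleep_epoch + 1) * samples_per_epoch:
        raise ValueError("EEG shorter than the hypnogram span")
    filtered = eeg.samples if prefiltered else bandpass_filter(eeg.samples, fs)

    win_len = int(round(WINDOW_SECONDS * fs))
    per_epoch = samples_per_epoch // win_len  # 15 windows per 30-s epoch

    windows, stage_tags, quarter_tags = [], [], []
    for q, (a, b) in enumerate(window.quarter_bounds):
        for epoch in range(a, b):
            start = epoch * samples_per_epoch
            block = filtered[start : start + per_epoch * win_len]
            windows.append(block.reshape(per_epoch, win_len))
            stage_tags.append(np.full(per_epoch, hypnogram.stages[epoch]))
            quarter_tags.append(np.full(per_epoch, q))
    all_windows = np.concatenate(windows)
    stage_tags = np.concatenate(stage_tags)
    quarter_tags = np.concatenate(quarter_tags)

    clean = np.array(
        [screen_window(w, fs) == "clean" for w in all_windows], dtype=bool
    )
    powers = np.full((all_windows.shape[0], len(BANDS)), np.nan)
    if clean.any():
        powers[clean] = _band_powers_batch(all_windows[clean], fs)
    # windows with zero in-band power behave like artifacts
    clean &= np.all(np.isfinite(powers), axis=1)

    out: dict[str, float] = {}
    for band_idx, band in enumerate(BAND_NAMES):
        for stage_idx, stage in enumerate(STAGES):
            for q in range(4):
                sel = clean & (stage_tags == stage_idx) & (quarter_tags == q)
                value = powers[sel, band_idx].mean() if sel.any() else np.nan
                out[f"{band}.{stage}.Q{q + 1}"] = value
    return out
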