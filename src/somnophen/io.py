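"""File formats: hypnogram CSV, hypnodensity CSV, EEG (CSV or EDF), truth
sidecar, run manifests.

Text dialects
-------------
hypnogram : CSV, header ``epoch,stage``; stages W/N1/N2/N3/R; 0-based epochs.
hypnodensity : CSV, header ``W,N1,N2,N3,R``, one row per 30-s epoch.
EEG : single-column CSV of microvolt samples plus a JSON sidecar
    ``<name>.meta.json`` with ``fs`` and ``channel_label``; EDF input is
    supported when mne is installed (channel selected by label match).
truth : YAML (seed, generator parameters, injected event lists).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .qeeg import EEGRecording
from .stages import Hypnogram
from .synthetic import SyntheticTruth


def write_hypnogram(hypnogram: Hypnogram, path) -> None:
    hypnogram.to_frame().to_csv(path, index=False)


def read_hypnogram(path) -> Hypnogram:
    return Hypnogram.from_frame(pd.read_csv(path))


def write_hypnodensity(matrix: np.ndarray, path) -> None:
    pd.DataFrame(matrix, columns=["W", "N1", "N2", "N3", "R"]).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_hypnodensity(path) -> np.ndarray:
    return pd.read_csv(path)[["W", "N1", "N2", "N3", "R"]].to_numpy(dtype=float)


def write_eeg_csv(eeg: EEGRecording, path) -> None:
    path = Path(path)
    np.savetxt(path, eeg.samples, fmt="%.6g")
    meta = {"fs": eeg.fs, "channel_label": eeg.channel_label, "units": "uV"}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_eeg_csv(path) -> EEGRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    samples = np.loadtxt(path)
    return EEGRecording(samples, fs=meta["fs"], channel_label=meta["channel_label"])


def read_eeg_edf(path, channel: str = "C3") -> EEGRecording:
    """Read one EEG channel from an EDF file (requires mne)."""
    import mne  # optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    matches = [ch for ch in raw.ch_names if channel.lower() in ch.lower()]
    if not matches:
        raise ValueError(f"no channel matching {channel!r} in {path}")
    data = raw.get_data(picks=matches[0])[0] * 1e6  # volts -> microvolts
    return EEGRecording(data, fs=float(raw.info["sfreq"]), channel_label=matches[0])


def read_eeg(path, channel: str = "C3") -> EEGRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_eeg_edf(path, channel)
    return read_eeg_csv(path)


def write_truth(truth: SyntheticTruth, path) -> None:
    spec = dataclasses.asdict(truth.spec)
    spec["transition_matrix"] = np.asarray(spec["transition_matrix"]).tolist()
    spec["initial_distribution"] = np.asarray(spec["initial_distribution"]).tolist()
    spec["stage_spectral_profiles"] = {
        k: list(v) for k, v in spec["stage_spectral_profiles"].items()
    }
    payload = {
        "seed": truth.seed,
        "spec": spec,
        "spindles": [list(map(float, e)) for e in truth.spindles],
        "slow_oscillations": [list(map(float, e)) for e in truth.slow_oscillations],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_truth(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))
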