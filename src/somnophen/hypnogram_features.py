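"""Hypnogram-derived features: whole-night metrics, quarter-night metrics,
and quarter-night stage-transition probabilities.

Whole-night set (8 features): total sleep time (TST, minutes), REM sleep
onset (minutes from persistent sleep onset; missing if no REM), stage shift
index (SSI; stage transitions per hour of the analyzed window), and the
proportion of window time spent in each of the five stages.

Quarter-night set (7 features x 4 quarters): as above without REM onset.

Transition set (25 x 4): per quarter, the row-normalized counts of
consecutive-epoch stage pairs; rows with no observed departures are missing.
"""

from __future__ import annotations

import numpy as np

from .stages import N_STAGES, STAGES, Hypnogram, NightWindow

WHOLE_NIGHT_NAMES = (
    "tst",
    "rem_onset",
    "ssi",
    "prop.W",
    "prop.N1",
    "prop.N2",
    "prop.N3",
    "prop.R",
)

QUARTER_METRIC_NAMES = ("tst", "ssi", "prop.W", "prop.N1", "prop.N2", "prop.N3", "prop.R")


def _segment_metrics(stages: np.ndarray, epoch_seconds: float) -> dict[str, float]:
    """TST, SSI and stage proportions of one contiguous stage segment."""
    n = stages.size
    minutes = epoch_seconds / 60.0
    hours = n * epoch_seconds / 3600.0
    non_wake = int(np.sum(stages != 0))
    shifts = int(np.sum(stages[1:] != stages[:-1])) if n > 1 else 0
    counts = np.bincount(stages, minlength=N_STAGES)
    out = {
        "tst": non_wake * minutes,
        "ssi": shifts / hours,
    }
    for i, s in enumerate(STAGES):
        out[f"prop.{s}"] = counts[i] / n
    return out


def whole_night_features(hypnogram: Hypnogram, window: NightWindow) -> dict[str, float]:
    """Compute the 8 whole-night hypnogram features on the night window."""
    stages = window.slice(hypnogram)
    metrics = _segment_metrics(stages, hypnogram.epoch_seconds)
    rem_idx = np.nonzero(stages == STAGES.index("R"))[0]
    rem_onset = (
        float(rem_idx[0]) * hypnogram.epoch_seconds / 60.0 if rem_idx.size else np.nan
    )
    out = {
        "tst": metrics["tst"],
        "rem_onset": rem_onset,
        "ssi": metrics["ssi"],
    }
    for s in STAGES:
        out[f"prop.{s}"] = metrics[f"prop.{s}"]
    return out


def quarter_hypnogram_features(
    hypnogram: Hypnogram, window: NightWindow
) -> dict[str, float]:
    """7 features per quarter (TST, SSI, 5 stage proportions); 28 total.

    Keys are ``<metric>.Q<i>`` with quarters numbered 1-4.
    """
    out: dict[str, float] = {}
    for q, (a, b) in enumerate(window.quarter_bounds, start=1):
        metrics = _segment_metrics(
            hypnogram.stages[a:b], hypnogram.epoch_seconds
        )
        for name in QUARTER_METRIC_NAMES:
            out[f"{name}.Q{q}"] = metrics[name]
    return out


def transition_matrix(stages: np.ndarray) -> np.ndarray:
    """Row-normalized 5x5 matrix of consecutive-epoch transitions.

    Rows with no observed departures are NaN.
    """
    counts = np.zeros((N_STAGES, N_STAGES), dtype=float)
    if stages.size >= 2:
        np.add.at(counts, (stages[:-1], stages[1:]), 1.0)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / totals
    probs[totals[:, 0] == 0] = np.nan
    return probs


def quarter_transition_matrices(
    hypnogram: Hypnogram, window: NightWindow
) -> dict[str, float]:
    """100 transition-probability features: 25 per quarter.

    Only pairs with both epochs inside the quarter are counted, so quarters
    remain independent summaries.  Keys are ``<from>_to_<to>.Q<i>``.
    """
    out: dict[str, float] = {}
    for q, (a, b) in enumerate(window.quarter_bounds, start=1):
        probs = transition_matrix(hypnogram.stages[a:b])
        for i, si in enumerate(STAGES):
            for j, sj in enumerate(STAGES):
                out[f"{si}_to_{sj}.Q{q}"] = probs[i, j]
    return out
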