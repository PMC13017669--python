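"""Per-participant feature assembly and feature-table I/O.

``extract_all_features`` turns one recording bundle (hypnogram + EEG +
optional hypnodensity) into a single row of 330 named values in catalog
order; features that cannot be computed for a given night (no REM epochs,
insufficient N2, no hypnodensity supplied) are missing, but the schema is
fixed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import FEATURE_NAMES
from .hypnodensity import hypnodensity_feature_block
from .hypnogram_features import (
    quarter_hypnogram_features,
    quarter_transition_matrices,
    whole_night_features,
)
from .qeeg import EEGRecording, qeeg_feature_block
from .spindles import (
    MIN_N2_MINUTES,
    SpindleConfig,
    detect_slow_oscillations,
    detect_spindles,
    sleep_intervals,
    spindle_summary,
    stage_intervals,
)
from .stages import Hypnogram, detect_night_window
from .synthetic import ParticipantRecord, inject_missing


def extract_all_features(
    hypnogram: Hypnogram,
    eeg: EEGRecording,
    hypnodensity: np.ndarray | None = None,
    spindle_config: SpindleConfig = SpindleConfig(),
) -> dict[str, float]:
    """One row of 330 named feature values, catalog order, NaN = missing."""
    window = detect_night_window(hypnogram)
    row: dict[str, float] = dict.fromkeys(FEATURE_NAMES, np.nan)

    for k, v in whole_night_features(hypnogram, window).items():
        row[f"hyp.{k}"] = v
    for k, v in quarter_hypnogram_features(hypnogram, window).items():
        row[f"hypq.{k}"] = v
    for k, v in quarter_transition_matrices(hypnogram, window).items():
        row[f"tp.{k}"] = v
    for k, v in qeeg_feature_block(eeg, hypnogram, window).items():
        row[f"qeeg.{k}"] = v

    n2 = stage_intervals(hypnogram, window, "N2")
    n2_minutes = sum(b - a for a, b in n2) / 60.0
    if n2_minutes >= MIN_N2_MINUTES:
        spindles = detect_spindles(eeg, n2, spindle_config)
        sos = detect_slow_oscillations(eeg, sleep_intervals(hypnogram, window))
        for k, v in spindle_summary(spindles, sos, eeg, n2).items():
            row[f"spindle.{k}"] = v

    if hypnodensity is not None:
        for k, v in hypnodensity_feature_block(hypnodensity, window).items():
            row[f"hd.{k}"] = v
    return row


def extract_cohort_features(
    records: list[ParticipantRecord],
    cohort: pd.DataFrame,
    missing_seed: int | None = None,
) -> pd.DataFrame:
    """Feature table for a generated cohort: id, group, then 330 columns.

    When ``missing_seed`` is given, each group's configured ``missing_rate``
    fraction of feature cells is blanked (the generator's emulation of
    unusable segments in real recordings).
    """
    rows = []
    for rec in records:
        row = {"participant_id": rec.participant_id, "group": rec.group}
        row.update(extract_all_features(rec.hypnogram, rec.eeg, rec.hypnodensity))
        rows.append(row)
    table = pd.DataFrame(rows, columns=["participant_id", "group", *FEATURE_NAMES])
    if missing_seed is not None:
        by_group = []
        for i, (label, part) in enumerate(table.groupby("group", sort=False)):
            rate = next(
                r.truth.spec.missing_rate for r in records if r.group == label
            )
            by_group.append(
                inject_missing(
                    part, rate, missing_seed + i, columns=list(FEATURE_NAMES)
                )
            )
        table = pd.concat(by_group).loc[table.index]
    if not cohort.empty:
        table = cohort.merge(table, on=["participant_id", "group"], how="right")
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write the feature table as CSV; missing values as empty cells."""
    if table["participant_id"].duplicated().any():
        raise ValueError("duplicate participant ids")
    cols = [c for c in table.columns if c not in FEATURE_NAMES]
    table = table[cols + list(FEATURE_NAMES)]
    table.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(FEATURE_NAMES) - set(table.columns)
    if missing:
        raise ValueError(f"feature table lacks {len(missing)} catalog columns")
    return table
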