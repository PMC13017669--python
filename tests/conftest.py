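"""Shared fixtures: synthetic recordings and cohorts generated at test time.

Cohort-level fixtures use 2-2.5 h nights (240-280 epochs) rather than full
clinical nights to keep the suite fast; per-recording fixtures state their
own sizes.  All seeds are fixed.
"""

from __future__ import annotations

import numpy as np
import pytest

import somnophen as sp
from somnophen.features import extract_cohort_features
from somnophen.spindles import stage_intervals
from somnophen.stages import Hypnogram, detect_night_window
from somnophen.synthetic import generate_cohort


@pytest.fixture(scope="session")
def n2_recording():
    """All-N2 240-epoch recording with injected spindles at 2/min + truth."""
    spec = sp.GroupSpec(spindle_density=2.0)
    hyp = Hypnogram(np.full(240, 2))
    eeg, truth = sp.generate_eeg(hyp, spec, seed=21)
    window = detect_night_window(hyp)
    n2 = stage_intervals(hyp, window, "N2")
    return {"spec": spec, "hypnogram": hyp, "eeg": eeg, "truth": truth, "n2": n2}


@pytest.fixture(scope="session")
def background_n2_recording():
    """All-N2 240-epoch recording with NO injected spindles (background)."""
    spec = sp.GroupSpec(spindle_density=0.0, so_rate_n2=0.0)
    hyp = Hypnogram(np.full(240, 2))
    eeg, truth = sp.generate_eeg(hyp, spec, seed=11)
    n2 = stage_intervals(hyp, detect_night_window(hyp), "N2")
    return {"eeg": eeg, "truth": truth, "n2": n2}


@pytest.fixture(scope="session")
def complete_record():
    """One complete participant bundle and its extracted feature row."""
    spec = sp.GroupSpec(n_epochs_range=(280, 300))
    hyp = sp.generate_hypnogram(spec, 290, seed=31)
    eeg, truth = sp.generate_eeg(hyp, spec, seed=32)
    hd = sp.generate_hypnodensity(hyp, spec.hypnodensity_concentration, seed=33)
    row = sp.extract_all_features(hyp, eeg, hd)
    return {"hypnogram": hyp, "eeg": eeg, "hypnodensity": hd, "row": row}


def _cohort_table(specs, seed):
    records, cohort, _ = generate_cohort(specs, seed=seed)
    return extract_cohort_features(records, cohort, missing_seed=seed + 1)


@pytest.fixture(scope="session")
def null_table():
    """Two exchangeable groups (identical generating parameters), 20 + 20."""
    specs = sp.null_cohort_specs(
        n_per_group=(20, 20), n_epochs_range=(240, 280)
    )
    return _cohort_table(specs, seed=101)


@pytest.fixture(scope="session")
def separated_table():
    """Two strongly separated groups, 20 + 20."""
    specs = sp.separated_cohort_specs(
        n_per_group=(20, 20), n_epochs_range=(240, 280)
    )
    return _cohort_table(specs, seed=202)


@pytest.fixture(scope="session")
def fast_eval_config():
    """Single-point grid, 100 trees: exercises the outer loop cheaply."""
    return sp.EvalConfig(
        n_runs=50, grid=({"max_depth": None, "max_features": "sqrt"},),
        n_trees=100, seed=7,
    )
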