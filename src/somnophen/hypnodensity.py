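"""Hypnodensity features.

A hypnodensity is a per-epoch probability distribution over the five sleep
stages, produced upstream by an automated sleep-staging model.  Per quarter
of the night window we compute 16 features: the mean probability of each
stage (5), the mean pairwise-mixture score min(p_a, p_b) for each unordered
stage pair (10), and the mean Shannon entropy (natural log) of the per-epoch
distribution — 64 features over the four quarters.

The mixture score min(p_a, p_b) is bounded by 0.5, zero iff either stage is
excluded, and maximal when the two stages tie, matching the "mix of two
stages" reading; the product p_a*p_b is available as a variant.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .stages import N_STAGES, STAGES, NightWindow

STAGE_PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(STAGES, 2))

ROW_SUM_TOL = 1e-3


def validate_hypnodensity(matrix) -> np.ndarray:
    """Validate and renormalize an epochs x 5 probability matrix.

    Rows whose sum is within 1e-3 of 1 are renormalized exactly; negative
    entries or larger deviations raise ``ValueError``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != N_STAGES:
        raise ValueError("hypnodensity must have 5 columns")
    if np.any(m < 0):
        raise ValueError("hypnodensity contains negative probabilities")
    sums = m.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > ROW_SUM_TOL):
        raise ValueError("hypnodensity rows must sum to 1 (tolerance 1e-3)")
    return m / sums[:, None]


def hypnodensity_feature_block(
    matrix: np.ndarray, window: NightWindow, mixture: str = "min"
) -> dict[str, float]:
    """64 features: per quarter, 5 stage means + 10 mixtures + entropy.

    Keys: ``p.<stage>.Q<i>``, ``mix.<a>_<b>.Q<i>``, ``entropy.Q<i>``.
    """
    m = validate_hypnodensity(matrix)
    if m.shape[0] <= window.final_sleep_epoch:
        raise ValueError("hypnodensity does not cover the night window")
    if mixture not in ("min", "product"):
        raise ValueError("mixture must be 'min' or 'product'")

    out: dict[str, float] = {}
    for q, (a, b) in enumerate(window.quarter_bounds, start=1):
        block = m[a:b]
        for i, s in enumerate(STAGES):
            out[f"p.{s}.Q{q}"] = float(block[:, i].mean())
        for sa, sb in STAGE_PAIRS:
            pa, pb = block[:, STAGES.index(sa)], block[:, STAGES.index(sb)]
            mix = np.minimum(pa, pb) if mixture == "min" else pa * pb
            out[f"mix.{sa}_{sb}.Q{q}"] = float(mix.mean())
        with np.errstate(invalid="ignore", divide="ignore"):
            plogp = np.where(block > 0, block * np.log(block), 0.0)
        out[f"entropy.Q{q}"] = float(-plogp.sum(axis=1).mean())
    return out
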