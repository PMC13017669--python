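"""The feature catalog: the single source of truth for the 330 features.

Six sets partition the catalog:

======================  =====  =============================================
set                     count  naming
======================  =====  =============================================
hypnogram                   8  ``hyp.<metric>`` (whole night)
spindle                    10  ``spindle.<metric>`` (whole night)
quarter_hypnogram          28  ``hypq.<metric>.Q<1-4>``
transition                100  ``tp.<from>_to_<to>.Q<1-4>``
qeeg                      120  ``qeeg.<band>.<stage>.Q<1-4>``
hypnodensity               64  ``hd.p.<stage>|mix.<a>_<b>|entropy.Q<1-4>``
======================  =====  =============================================

Classifier set partitions and clustering inputs are derived from this
catalog; no feature exists outside it.
"""

from __future__ import annotations

from .hypnodensity import STAGE_PAIRS
from .hypnogram_features import QUARTER_METRIC_NAMES, WHOLE_NIGHT_NAMES
from .qeeg import BAND_NAMES
from .spindles import SPINDLE_FEATURE_NAMES
from .stages import STAGES

#: Canonical feature-set order, used for round-robin refills.
SET_ORDER = (
    "hypnogram",
    "spindle",
    "quarter_hypnogram",
    "transition",
    "qeeg",
    "hypnodensity",
)


def _build() -> dict[str, tuple[str, ...]]:
    sets: dict[str, list[str]] = {name: [] for name in SET_ORDER}
    sets["hypnogram"] = [f"hyp.{m}" for m in WHOLE_NIGHT_NAMES]
    sets["spindle"] = [f"spindle.{m}" for m in SPINDLE_FEATURE_NAMES]
    for q in range(1, 5):
        for m in QUARTER_METRIC_NAMES:
            sets["quarter_hypnogram"].append(f"hypq.{m}.Q{q}")
        for si in STAGES:
            for sj in STAGES:
                sets["transition"].append(f"tp.{si}_to_{sj}.Q{q}")
        for band in BAND_NAMES:
            for s in STAGES:
                sets["qeeg"].append(f"qeeg.{band}.{s}.Q{q}")
        for s in STAGES:
            sets["hypnodensity"].append(f"hd.p.{s}.Q{q}")
        for a, b in STAGE_PAIRS:
            sets["hypnodensity"].append(f"hd.mix.{a}_{b}.Q{q}")
        sets["hypnodensity"].append(f"hd.entropy.Q{q}")
    return {k: tuple(v) for k, v in sets.items()}


FEATURE_SETS: dict[str, tuple[str, ...]] = _build()

#: All 330 feature names in catalog order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    name for set_name in SET_ORDER for name in FEATURE_SETS[set_name]
)

SET_OF_FEATURE: dict[str, str] = {
    name: set_name for set_name in SET_ORDER for name in FEATURE_SETS[set_name]
}

EXPECTED_SET_SIZES = {
    "hypnogram": 8,
    "spindle": 10,
    "quarter_hypnogram": 28,
    "transition": 100,
    "qeeg": 120,
    "hypnodensity": 64,
}

assert {k: len(v) for k, v in FEATURE_SETS.items()} == EXPECTED_SET_SIZES
assert len(FEATURE_NAMES) == 330 == len(set(FEATURE_NAMES))
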