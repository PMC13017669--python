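"""Sleep-stage alphabet, hypnograms, and the analyzed night window.

A hypnogram is a sequence of 30-s epochs scored with one of the five AASM
stages W, N1, N2, N3, REM.  All downstream features are computed on the
*night window*: the span from persistent sleep onset (first run of at least
20 consecutive non-wake epochs, i.e. 10 minutes) to the final sleep epoch,
partitioned into four near-equal quarters Q1-Q4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical stage order; indices 0..4 are used everywhere.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}
N_STAGES = 5

#: Scoring epoch length in seconds (AASM standard).
EPOCH_SECONDS = 30.0

#: Persistent sleep onset = first run of this many consecutive non-W epochs.
PERSISTENT_SLEEP_EPOCHS = 20


class NoSleepOnsetError(ValueError):
    """Raised when a hypnogram contains no persistent sleep onset."""


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch stage sequence.

    Parameters
    ----------
    stages
        Integer stage codes in canonical order (0=W, 1=N1, 2=N2, 3=N3, 4=REM).
    epoch_seconds
        Epoch duration in seconds (30 by convention).
    """

    stages: np.ndarray
    epoch_seconds: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        arr = np.asarray(self.stages, dtype=np.int64)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("hypnogram must be a nonempty 1-D sequence")
        if arr.min() < 0 or arr.max() >= N_STAGES:
            raise ValueError("hypnogram contains stage codes outside 0..4")
        object.__setattr__(self, "stages", arr)

    def __len__(self) -> int:
        return self.stages.size

    @property
    def labels(self) -> np.ndarray:
        """Stage labels as strings."""
        return np.asarray(STAGES)[self.stages]

    @classmethod
    def from_labels(cls, labels, epoch_seconds: float = EPOCH_SECONDS) -> "Hypnogram":
        try:
            codes = np.array([STAGE_INDEX[str(s)] for s in labels], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise ValueError(f"unknown stage code {exc.args[0]!r}") from None
        return cls(codes, epoch_seconds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(len(self)), "stage": self.labels})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Hypnogram":
        frame = frame.sort_values("epoch")
        return cls.from_labels(frame["stage"].astype(str).tolist())


@dataclass(frozen=True)
class NightWindow:
    """Analyzed span from persistent sleep onset to final sleep epoch.

    ``quarter_bounds`` are four half-open epoch intervals, absolute indices,
    that exactly partition ``[onset_epoch, final_sleep_epoch + 1)``.
    """

    onset_epoch: int
    final_sleep_epoch: int
    quarter_bounds: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.onset_epoch > self.final_sleep_epoch:
            raise ValueError("onset after final sleep epoch")
        if not self.quarter_bounds:
            object.__setattr__(
                self,
                "quarter_bounds",
                _quarter_bounds(self.onset_epoch, self.final_sleep_epoch),
            )

    @property
    def n_epochs(self) -> int:
        return self.final_sleep_epoch - self.onset_epoch + 1

    def slice(self, hypnogram: Hypnogram) -> np.ndarray:
        return hypnogram.stages[self.onset_epoch : self.final_sleep_epoch + 1]

    def quarter_of_epoch(self, epoch: int) -> int:
        """0-based quarter index of an absolute epoch index, -1 if outside."""
        for q, (a, b) in enumerate(self.quarter_bounds):
            if a <= epoch < b:
                return q
        return -1


def _quarter_bounds(onset: int, final: int) -> tuple[tuple[int, int], ...]:
    n = final - onset + 1
    cuts = [onset + (i * n) // 4 for i in range(5)]
    return tuple((cuts[i], cuts[i + 1]) for i in range(4))


def detect_night_window(
    hypnogram: Hypnogram, persistent_epochs: int = PERSISTENT_SLEEP_EPOCHS
) -> NightWindow:
    """Locate the night window of a hypnogram.

    Persistent sleep onset is the first epoch starting a run of
    ``persistent_epochs`` consecutive non-wake epochs; the window ends at the
    last non-wake epoch of the whole recording.

    Raises
    ------
    NoSleepOnsetError
        If no run of ``persistent_epochs`` consecutive non-W epochs exists.
    """
    asleep = hypnogram.stages != STAGE_INDEX["W"]
    onset = _first_run_start(asleep, persistent_epochs)
    if onset is None:
        raise NoSleepOnsetError(
            f"no run of {persistent_epochs} consecutive non-wake epochs"
        )
    final = int(np.nonzero(asleep)[0][-1])
    return NightWindow(onset_epoch=onset, final_sleep_epoch=final)


def _first_run_start(mask: np.ndarray, run_length: int) -> int | None:
    count = 0
    for i, flag in enumerate(mask):
        count = count + 1 if flag else 0
        if count >= run_length:
            return i - run_length + 1
    return None
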