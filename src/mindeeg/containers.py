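"""In-memory containers: a continuous multichannel recording and an epoched trial set."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .montage import MontageSpec

__all__ = ["State", "Recording", "TrialSet", "STATE_ORDER"]


class State(str, Enum):
    """The four recorded conditions: rest / meditation at training stages 1 and 2."""

    REST1 = "REST1"
    MBSR1 = "MBSR1"
    REST2 = "REST2"
    MBSR2 = "MBSR2"

    @property
    def stage(self) -> int:
        return 1 if self.value.endswith("1") else 2

    @property
    def is_meditation(self) -> bool:
        return self.value.startswith("MBSR")


STATE_ORDER: tuple[State, ...] = (State.REST1, State.MBSR1, State.REST2, State.MBSR2)


@dataclass
class Recording:
    """Continuous EEG: channels x samples in microvolts, plus annotations."""

    data: np.ndarray  # (n_channels, n_samples), µV
    rate: float  # Hz
    montage: MontageSpec
    subject_id: str = "S00"
    state: State = State.REST1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but montage has "
                f"{self.montage.n_channels}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains NaN or Inf samples")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.state = State(self.state)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.rate

    @property
    def stage(self) -> int:
        return self.state.stage


@dataclass
class TrialSet:
    """Epoched EEG: trials x channels x samples with per-trial annotations."""

    trials: np.ndarray  # (n_trials, n_channels, n_samples)
    states: np.ndarray  # (n_trials,) of State values (str)
    subjects: np.ndarray  # (n_trials,) subject ids (str)
    rate: float
    montage: MontageSpec | None = None
    stages: np.ndarray = field(default=None)  # (n_trials,) int, derived if omitted

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials)
        if self.trials.ndim != 3:
            raise ValueError("trials must be 3-D (trials x channels x samples)")
        n = self.trials.shape[0]
        self.states = np.asarray(self.states, dtype=object)
        self.subjects = np.asarray(self.subjects, dtype=object)
        if len(self.states) != n or len(self.subjects) != n:
            raise ValueError("per-trial label arrays must match the trial count")
        if self.stages is None:
            self.stages = np.array([State(s).stage for s in self.states], dtype=int)
        else:
            self.stages = np.asarray(self.stages, dtype=int)
            if len(self.stages) != n:
                raise ValueError("stages must match the trial count")
        if self.montage is not None and self.trials.shape[1] != self.montage.n_channels:
            raise ValueError("trial channel count does not match montage")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    def select(self, mask) -> "TrialSet":
        mask = np.asarray(mask)
        return TrialSet(
            self.trials[mask],
            self.states[mask],
            self.subjects[mask],
            self.rate,
            self.montage,
            self.stages[mask],
        )

    @staticmethod
    def concatenate(parts: list["TrialSet"]) -> "TrialSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        rates = {p.rate for p in parts}
        if len(rates) != 1:
            raise ValueError("trial sets have differing sampling rates")
        return TrialSet(
            np.concatenate([p.trials for p in parts]),
            np.concatenate([p.states for p in parts]),
            np.concatenate([p.subjects for p in parts]),
            parts[0].rate,
            parts[0].montage,
            np.concatenate([p.stages for p in parts]),
        )
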