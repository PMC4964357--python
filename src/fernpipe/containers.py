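"""Core data containers shared across the pipeline.

Conventions: potentials in microvolts, time in seconds (epoch time axes in
milliseconds where noted), sensor/source positions in meters in a head-centered
RAS-like frame (+x right, +y anterior, +z superior).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "ContinuousEEG",
    "EpochSet",
    "EVENT_COLUMNS",
]

#: canonical column order of an event table
EVENT_COLUMNS = ["onset_s", "sample", "trial_index", "condition", "payoff", "correct"]


@dataclass(frozen=True)
class Montage:
    """Sensor layout: named channels with 3-D positions on the scalp.

    ``names`` holds the 128 scalp channels plus the two mastoids; ``Fz`` must be
    among them and is the electrode at which the feedback negativity is scored.
    """

    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), meters
    mastoids: tuple[str, str] = ("M1", "M2")

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.names), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(self.names)} channels"
            )
        object.__setattr__(self, "positions", pos)
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate channel names")
        if "Fz" not in self.names:
            raise ValueError("montage must contain a frontal-midline channel 'Fz'")
        for m in self.mastoids:
            if m not in self.names:
                raise ValueError(f"mastoid channel {m!r} missing from montage")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError as err:
            raise KeyError(f"channel {name!r} not in montage") from err

    @property
    def mastoid_indices(self) -> tuple[int, int]:
        return self.index(self.mastoids[0]), self.index(self.mastoids[1])

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]


def _validate_events(events: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    missing = [c for c in ("sample", "condition") if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks required columns: {missing}")
    s = events["sample"].to_numpy()
    if len(s) and (s.min() < 0 or s.max() >= n_samples):
        raise ValueError("event sample indices fall outside the recording")
    return events.reset_index(drop=True)


@dataclass
class ContinuousEEG:
    """Multichannel continuous recording with an event table.

    data : (n_channels, n_samples) in microvolts
    fs : sampling rate in Hz
    events : DataFrame with at least ``sample`` and ``condition`` columns
        (plus ``onset_s``, ``trial_index``, ``payoff``, ``correct`` when the
        recording comes from a simulated task session).
    """

    data: np.ndarray
    fs: float
    montage: Montage
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{self.data.shape[0]} data channels but montage has "
                f"{self.montage.n_channels}"
            )
        self.events = _validate_events(self.events, self.n_samples)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self, **changes) -> "ContinuousEEG":
        out = ContinuousEEG(
            data=changes.get("data", self.data).copy()
            if "data" not in changes
            else changes["data"],
            fs=changes.get("fs", self.fs),
            montage=changes.get("montage", self.montage),
            events=changes.get("events", self.events.copy()),
        )
        return out


@dataclass
class EpochSet:
    """Feedback-locked epochs: trials x channels x time.

    times : epoch time axis in **milliseconds** relative to feedback onset.
    labels : condition label per epoch.
    rejected : boolean mask, True where the epoch is excluded from averages.
    rejection_reason : per-epoch free-text reason ('' where retained).
    """

    data: np.ndarray  # (n_epochs, n_channels, n_times), microvolts
    times: np.ndarray  # (n_times,), ms
    labels: np.ndarray  # (n_epochs,), str
    montage: Montage
    fs: float
    baseline_applied: bool = False
    rejected: np.ndarray | None = None
    rejection_reason: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (epochs, channels, times)")
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n_ep, n_ch, n_t = self.data.shape
        if n_ch != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        if len(self.times) != n_t:
            raise ValueError("time axis length does not match data")
        if len(self.labels) != n_ep:
            raise ValueError("label count does not match epoch count")
        if self.rejected is None:
            self.rejected = np.zeros(n_ep, dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.rejection_reason is None:
            self.rejection_reason = np.array([""] * n_ep, dtype=object)
        else:
            self.rejection_reason = np.asarray(self.rejection_reason, dtype=object)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def kept(self) -> np.ndarray:
        return ~self.rejected

    def select(self, labels: str | Sequence[str]) -> "EpochSet":
        """Subset of *surviving* epochs whose label is in ``labels``."""
        if isinstance(labels, str):
            labels = [labels]
        mask = np.isin(self.labels, list(labels)) & self.kept
        return EpochSet(
            data=self.data[mask],
            times=self.times,
            labels=self.labels[mask],
            montage=self.montage,
            fs=self.fs,
            baseline_applied=self.baseline_applied,
            rejected=np.zeros(int(mask.sum()), dtype=bool),
            rejection_reason=self.rejection_reason[mask],
        )

    def channel(self, name: str) -> np.ndarray:
        """(n_epochs, n_times) view of one channel."""
        return self.data[:, self.montage.index(name), :]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times=self.times.copy(),
            labels=self.labels.copy(),
            montage=self.montage,
            fs=self.fs,
            baseline_applied=self.baseline_applied,
            rejected=self.rejected.copy(),
            rejection_reason=self.rejection_reason.copy(),
        )
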