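"""Core in-memory containers for multichannel EEG recordings.

All signal data are stored as ``float64`` arrays of shape
``(n_channels, n_samples)`` in microvolts (μV).  Sample indices are 0-based
and intervals are half-open ``[start, end)`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Recording", "Epoch", "TASK_LABELS"]

#: The four motor-task labels: left hand, right hand, tongue, feet.
TASK_LABELS = ("L", "R", "T", "F")


@dataclass
class Recording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in μV.
    srate : float
        Sampling rate in Hz.
    channel_names : list of str
        One identifier per data row.
    positions : ndarray, shape (n_channels, 3)
        3D electrode positions in a head-fixed frame (+x right, +y front,
        +z up; units arbitrary but consistent).
    events : list of (str, int)
        ``(label, onset_sample)`` trial markers.
    bad_channels : set of str
        Channels flagged as non-operating.
    """

    data: np.ndarray
    srate: float
    channel_names: list[str]
    positions: np.ndarray
    events: list[tuple[str, int]] = field(default_factory=list)
    bad_channels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        n = self.data.shape[0]
        if len(self.channel_names) != n or self.positions.shape != (n, 3):
            raise ValueError(
                "channel_names and positions must match the number of data rows"
            )
        if not self.srate > 0:
            raise ValueError("srate must be positive")
        for label, onset in self.events:
            if not (0 <= int(onset) < self.n_samples):
                raise ValueError(
                    f"event {label!r} onset {onset} outside [0, {self.n_samples})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.srate

    def copy(self, data: np.ndarray | None = None) -> "Recording":
        """Deep copy, optionally replacing the signal matrix."""
        return replace(
            self,
            data=self.data.copy() if data is None else np.asarray(data, float),
            channel_names=list(self.channel_names),
            positions=self.positions.copy(),
            events=list(self.events),
            bad_channels=set(self.bad_channels),
        )

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def pick_channels(self, names: list[str]) -> "Recording":
        """Return a recording restricted to ``names`` (in the given order)."""
        idx = [self.channel_index(n) for n in names]
        return replace(
            self,
            data=self.data[idx].copy(),
            channel_names=list(names),
            positions=self.positions[idx].copy(),
            events=list(self.events),
            bad_channels=set(self.bad_channels) & set(names),
        )

    def drop_channels(self, names) -> "Recording":
        """Return a recording without ``names``."""
        names = set(names)
        keep = [n for n in self.channel_names if n not in names]
        return self.pick_channels(keep)


@dataclass
class Epoch:
    """A single task trial cut from a recording."""

    task_label: str
    data: np.ndarray  # (n_channels, n_samples) μV
    trial_index: int
    onset_sample: int = 0

    def __post_init__(self) -> None:
        if self.task_label not in TASK_LABELS:
            raise ValueError(f"unknown task label {self.task_label!r}")
        self.data = np.asarray(self.data, dtype=np.float64)
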