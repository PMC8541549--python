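"""Core in-memory containers: event lists and continuous recordings."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .montage import Montage, canonical_label

logger = logging.getLogger(__name__)

TASKS = ("CHECK", "ASSR", "EOEC")
SYSTEMS = ("dry", "gel")


@dataclass
class EventList:
    """Stimulus events as (onset_sample, label) pairs, sorted by onset."""

    onsets: np.ndarray  # int sample indices, 0-based
    labels: list[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.labels = [str(l) for l in self.labels]
        if self.onsets.ndim != 1 or len(self.labels) != self.onsets.size:
            raise ValueError("onsets and labels must have equal length")
        if any(not l for l in self.labels):
            raise ValueError("event labels must be nonempty")
        if self.onsets.size and np.any(np.diff(self.onsets) < 0):
            logger.warning("event onsets were not sorted; sorting")
            order = np.argsort(self.onsets, kind="stable")
            self.onsets = self.onsets[order]
            self.labels = [self.labels[i] for i in order]

    def __len__(self) -> int:
        return self.onsets.size

    def select(self, label: str) -> np.ndarray:
        """Onset samples of all events carrying `label`."""
        return self.onsets[[i for i, l in enumerate(self.labels) if l == label]]


@dataclass
class Recording:
    """A continuous multichannel EEG recording in microvolts.

    ``data`` is channels x samples; ``events`` indexes into the sample axis.
    """

    data: np.ndarray
    sample_rate: float
    channel_labels: list[str]
    events: EventList = None
    system: str = "dry"
    subject_id: int = 0
    task: str = "CHECK"
    reference_label: str = "M2"
    montage: Montage | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_labels = [canonical_label(l) for l in self.channel_labels]
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown system {self.system!r}")
        if self.events is None:
            self.events = EventList(np.empty(0, dtype=np.int64), [])
        if self.events.onsets.size and (
                self.events.onsets.min() < 0
                or self.events.onsets.max() >= self.n_samples):
            raise ValueError("event onsets outside [0, n_samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(canonical_label(label))

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def pick(self, labels) -> "Recording":
        """Recording restricted to `labels`, in the given order."""
        idx = [self.channel_index(l) for l in labels]
        sub_montage = None
        if self.montage is not None:
            try:
                sub_montage = self.montage.subset(labels)
            except ValueError:
                sub_montage = None
        return replace(self, data=self.data[idx].copy(),
                       channel_labels=[self.channel_labels[i] for i in idx],
                       montage=sub_montage)

    def drop(self, labels) -> "Recording":
        drop = {canonical_label(l) for l in labels}
        keep = [l for l in self.channel_labels if l not in drop]
        return self.pick(keep)

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())

    def crop(self, start_sample: int, stop_sample: int) -> "Recording":
        """Half-open sample slice [start, stop); events re-indexed, out-of-range
        events dropped."""
        start = max(int(start_sample), 0)
        stop = min(int(stop_sample), self.n_samples)
        if stop <= start:
            raise ValueError("empty crop interval")
        inside = (self.events.onsets >= start) & (self.events.onsets < stop)
        ev = EventList(self.events.onsets[inside] - start,
                       [l for l, m in zip(self.events.labels, inside) if m])
        return replace(self, data=self.data[:, start:stop].copy(), events=ev)
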