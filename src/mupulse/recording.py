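"""Continuous multichannel recording container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventTable
from .montage import Montage


@dataclass
class Recording:
    """Channels x samples time series (microvolts) with events and montage.

    ``provenance`` is an ordered log of applied operations; preprocessing
    steps append to it and pipeline-order checks read it.
    """

    data: np.ndarray                 # (n_channels, n_samples), uV
    rate: float                      # Hz
    montage: Montage
    events: EventTable
    provenance: list[dict] = field(default_factory=list)
    ground_truth: dict | None = None  # generator-only; carried for tests

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if len(self.events) and self.events.end_time() > self.duration:
            raise ValueError("events extend beyond the recording duration")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.montage.index(label)]

    def log(self, op: str, **parameters) -> None:
        self.provenance.append({"op": op, **parameters})

    def has_step(self, op: str) -> bool:
        return any(entry["op"] == op for entry in self.provenance)

    def copy_with(self, data: np.ndarray, rate: float | None = None,
                  ground_truth: dict | None = None) -> "Recording":
        return Recording(data=data, rate=self.rate if rate is None else rate,
                         montage=self.montage, events=self.events,
                         provenance=list(self.provenance),
                         ground_truth=(self.ground_truth if ground_truth
                                       is None else ground_truth))
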