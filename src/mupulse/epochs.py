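"""Trial-segmented data (trials x channels x samples)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: history-sorted trial labels: single-after-single, single-after-train,
#: train-after-single, train-after-train, or unsorted/first trial.
HISTORY_LABELS = ("SaS", "SaT", "TaS", "TaT", "none")


@dataclass
class EpochSet:
    """Fixed-window epochs around event onsets.

    ``labels`` carries the pre-trial-history sorting (SaS/SaT/TaS/TaT);
    ``event_index`` maps each epoch back to its row in the source
    :class:`~mupulse.events.EventTable` (-1 for directly simulated epochs).
    """

    data: np.ndarray                  # (n_trials, n_channels, n_samples), uV
    tmin: float                       # s relative to event onset
    tmax: float
    rate: float
    channels: tuple[str, ...]
    labels: np.ndarray                # (n_trials,) str in HISTORY_LABELS
    event_index: np.ndarray = field(default=None)  # (n_trials,) int
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        n_expected = int(round((self.tmax - self.tmin) * self.rate))
        if self.data.shape[2] != n_expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != "
                f"round((tmax-tmin)*rate) = {n_expected}")
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.n_trials:
            raise ValueError("one label per trial required")
        bad = set(self.labels.astype(str)) - set(HISTORY_LABELS)
        if bad:
            raise ValueError(f"unknown history labels: {sorted(bad)}")
        if self.event_index is None:
            self.event_index = np.full(self.n_trials, -1, dtype=int)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.tmin + np.arange(n) / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def label_mask(self, subset) -> np.ndarray:
        """Boolean trial mask for a label, an iterable of labels, or 'all'."""
        if subset == "all" or subset is None:
            return np.ones(self.n_trials, dtype=bool)
        if isinstance(subset, str):
            subset = (subset,)
        return np.isin(self.labels.astype(str), list(subset))

    def time_mask(self, t0: float, t1: float) -> np.ndarray:
        t = self.times
        return (t >= t0) & (t < t1)
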