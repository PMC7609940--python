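"""Stimulation event tables for the subthreshold EEG paradigm.

An :class:`EventTable` lists stimulation events in recording time:
subthreshold single pulses, subthreshold 7 Hz pulse trains (eight pulses,
1 s), and rarely interspersed suprathreshold pulses on either hand.  Each
subthreshold event additionally carries its pre-trial *history* — whether
the immediately preceding subthreshold event was a single pulse or a
train — which downstream analyses use to sort trials (SaS/SaT/TaS/TaT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SUB_KINDS = ("sub_single", "sub_train")
SUPRA_KINDS = ("supra_left", "supra_right")
KINDS = SUB_KINDS + SUPRA_KINDS + ("target",)

TRAIN_RATE_HZ = 7.0
TRAIN_N_PULSES = 8
TRAIN_DURATION_S = 1.0


@dataclass
class EventTable:
    """Ordered stimulation events with block and history bookkeeping."""

    onset: np.ndarray            # (n,) seconds from recording start
    kind: np.ndarray             # (n,) str, one of KINDS
    block: np.ndarray            # (n,) int block index >= 0
    history: np.ndarray          # (n,) str in {none, after_single, after_train}
    train_pulse_onsets: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.onset = np.asarray(self.onset, dtype=float)
        self.kind = np.asarray(self.kind, dtype=object)
        self.block = np.asarray(self.block, dtype=int)
        self.history = np.asarray(self.history, dtype=object)
        if not self.train_pulse_onsets:
            self.train_pulse_onsets = [np.array([]) for _ in self.onset]
        self.validate()

    def validate(self) -> None:
        n = len(self.onset)
        if not (len(self.kind) == len(self.block) == len(self.history)
                == len(self.train_pulse_onsets) == n):
            raise ValueError("event table columns have mismatched lengths")
        if n > 1 and np.any(np.diff(self.onset) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        for k in np.unique(self.kind):
            if k not in KINDS:
                raise ValueError(f"unknown event kind {k!r}")
        for i, k in enumerate(self.kind):
            pulses = np.asarray(self.train_pulse_onsets[i], dtype=float)
            if k == "sub_train":
                if len(pulses) != TRAIN_N_PULSES:
                    raise ValueError(
                        f"sub_train event {i} must carry {TRAIN_N_PULSES} "
                        f"pulse onsets, got {len(pulses)}")
            elif len(pulses) != 0:
                raise ValueError(f"{k} event {i} must not carry pulse onsets")

    def check_history(self) -> None:
        """Verify history labels against a one-pass rescan.

        Valid for complete paradigms only — a selected subset keeps the
        labels of the full sequence it came from.
        """
        expected = recompute_history(self.kind)
        sub = self._sub_mask()
        if not np.array_equal(self.history[sub], expected[sub]):
            raise ValueError("history labels inconsistent with event order")

    def _sub_mask(self) -> np.ndarray:
        return np.isin(self.kind.astype(str), SUB_KINDS)

    def __len__(self) -> int:
        return len(self.onset)

    def select(self, kinds) -> "EventTable":
        """Sub-table of events whose kind is in ``kinds`` (order kept)."""
        mask = np.isin(self.kind.astype(str), list(kinds))
        idx = np.flatnonzero(mask)
        return EventTable(
            onset=self.onset[idx], kind=self.kind[idx],
            block=self.block[idx], history=self.history[idx],
            train_pulse_onsets=[self.train_pulse_onsets[i] for i in idx])

    def counts(self) -> dict[str, int]:
        kinds, n = np.unique(self.kind.astype(str), return_counts=True)
        return dict(zip(kinds.tolist(), n.tolist()))

    def end_time(self) -> float:
        """Time at which the last event (including train tail) ends."""
        ends = self.onset.copy()
        for i, k in enumerate(self.kind):
            if k == "sub_train":
                ends[i] += TRAIN_DURATION_S
        return float(ends.max()) if len(ends) else 0.0

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset_s": self.onset,
            "kind": self.kind.astype(str),
            "block": self.block,
            "history": self.history.astype(str),
            "pulse_onsets": [";".join(f"{p:.6f}" for p in po)
                             for po in self.train_pulse_onsets],
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        pulses = [np.array([float(x) for x in str(s).split(";") if x != ""])
                  for s in df["pulse_onsets"]]
        return cls(onset=df["onset_s"].to_numpy(float),
                   kind=df["kind"].to_numpy(object),
                   block=df["block"].to_numpy(int),
                   history=df["history"].to_numpy(object),
                   train_pulse_onsets=pulses)


def recompute_history(kind: np.ndarray) -> np.ndarray:
    """One-pass recomputation of history labels from the kind sequence.

    Suprathreshold/target events do not alter the subthreshold history
    chain and themselves carry 'none'.
    """
    out = np.empty(len(kind), dtype=object)
    prev = None
    for i, k in enumerate(kind):
        if k in SUB_KINDS:
            out[i] = ("none" if prev is None
                      else "after_single" if prev == "sub_single"
                      else "after_train")
            prev = k
        else:
            out[i] = "none"
    return out


def make_event_sequence(n_single: int, n_train: int, n_supra_per_block: int,
                        n_blocks: int, isi_mean: float, isi_jitter: float,
                        seed: int, start: float = 5.0) -> EventTable:
    """Pseudo-randomized paradigm of single pulses and 7 Hz pulse trains.

    Singles and trains are interleaved in random order, ``n_supra_per_block``
    suprathreshold pulses (alternating left/right) are inserted at random
    positions in each block, and the inter-stimulus interval is drawn
    uniformly from ``isi_mean ± isi_jitter``, measured onset-to-onset but
    from the *end* of a pulse train so trains never overlap the next event.
    """
    for name, count in (("n_single", n_single), ("n_train", n_train)):
        if count % n_blocks:
            raise ValueError(
                f"{name}={count} is not divisible by n_blocks={n_blocks}")
    if isi_jitter >= isi_mean:
        raise ValueError("isi_jitter must be smaller than isi_mean")
    if isi_jitter < 0 or isi_mean <= 0:
        raise ValueError("isi_mean must be > 0 and isi_jitter >= 0")

    rng = np.random.default_rng(seed)
    kinds: list[str] = []
    blocks: list[int] = []
    n_supra_emitted = 0
    for b in range(n_blocks):
        block_kinds = (["sub_single"] * (n_single // n_blocks)
                       + ["sub_train"] * (n_train // n_blocks))
        rng.shuffle(block_kinds)
        for _ in range(n_supra_per_block):
            side = "supra_left" if n_supra_emitted % 2 == 0 else "supra_right"
            pos = rng.integers(0, len(block_kinds) + 1)
            block_kinds.insert(int(pos), side)
            n_supra_emitted += 1
        kinds.extend(block_kinds)
        blocks.extend([b] * len(block_kinds))

    onsets = np.empty(len(kinds))
    pulse_onsets: list[np.ndarray] = []
    t = start
    for i, k in enumerate(kinds):
        if i > 0:
            t = t + rng.uniform(isi_mean - isi_jitter, isi_mean + isi_jitter)
        onsets[i] = t
        if k == "sub_train":
            pulses = t + np.arange(TRAIN_N_PULSES) / TRAIN_RATE_HZ
            pulse_onsets.append(pulses)
            t = t + TRAIN_DURATION_S  # next ISI measured from train end
        else:
            pulse_onsets.append(np.array([]))

    kind_arr = np.array(kinds, dtype=object)
    table = EventTable(onset=onsets, kind=kind_arr,
                       block=np.array(blocks, dtype=int),
                       history=recompute_history(kind_arr),
                       train_pulse_onsets=pulse_onsets)
    table.check_history()
    return table
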