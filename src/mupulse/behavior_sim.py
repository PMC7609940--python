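"""Simulated near-threshold detection sessions.

Each experiment pairs near-threshold target pulses (TPs) with concomitant
subthreshold stimulation at a design-specific delay: single-pulse designs
A1/A2/A3 place the TP 30/60/180 ms after a subthreshold single pulse;
train designs B1/B2 place it 30/60 ms after the fifth pulse of a 1 s
7 Hz subthreshold train, and B3 places it 180 ms after the train's last
pulse.  Per block, each of five TP intensities is presented 32 times
(16 paired with subthreshold stimulation, 16 control) plus 16 catch
trials containing only the subthreshold stimulus.

The simulated observer answers from a logistic psychometric function;
pairing multiplies the detection probability by (1 + effect_shift) for
the design's condition, which is the ground truth that the detection-
rate statistics are meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import SubjectParams

#: design label -> (condition label, delay in ms); delays for B1/B2 are
#: relative to the fifth intra-train pulse, B3 to the final (8th) pulse.
DESIGNS: dict[str, tuple[str | None, int | None]] = {
    "A1": ("single_30ms", 30),
    "A2": ("single_60ms", 60),
    "A3": ("single_180ms", 180),
    "B1": ("train_30ms", 30),
    "B2": ("train_60ms", 60),
    "B3": ("train_180ms", 180),
    "control_only": (None, None),
}

N_LEVELS = 5
N_REPEATS_PER_LEVEL = 32     # per block; half paired, half control
N_CATCH_PER_BLOCK = 16
SUBTHRESHOLD_FACTOR = 0.85   # ~15 % below the absolute detection threshold


def detection_probability(intensity: np.ndarray | float,
                          params: SubjectParams) -> np.ndarray:
    """Logistic psychometric function of the simulated observer."""
    x = params.psychometric_slope * (np.asarray(intensity, float)
                                     - params.psychometric_threshold)
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class PsychSession:
    """One subject's behavioral session (all blocks concatenated)."""

    subject_id: int
    design: str
    block: np.ndarray           # (n_trials,) int
    intensity: np.ndarray       # mA (subthreshold intensity on catch trials)
    level: np.ndarray           # 1..5 intensity level index, 0 for catch
    condition: np.ndarray       # 'control' | 'paired' (catch -> 'control')
    delay_ms: np.ndarray        # design delay on paired trials, -1 otherwise
    is_catch: np.ndarray        # bool
    response: np.ndarray        # bool
    rt: np.ndarray              # s, NaN when no response
    threshold_50: float = float("nan")   # staircase estimate, mA
    sub_intensity: float = float("nan")  # absolute subthreshold ref, mA
    condition_label: str | None = None

    def __len__(self) -> int:
        return len(self.block)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "block": self.block,
            "trial": np.arange(len(self.block)),
            "intensity_mA": self.intensity,
            "condition": self.condition,
            "delay_ms": self.delay_ms,
            "is_catch": self.is_catch.astype(int),
            "response": self.response.astype(int),
            "rt_s": self.rt,
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.4f")


def simulate_behavior_session(design: str, params: SubjectParams,
                              n_blocks: int, seed: int,
                              subject_id: int = 0,
                              threshold_50: float | None = None
                              ) -> PsychSession:
    """Simulate one subject's session for a named experiment design.

    ``threshold_50`` is the 50 %-detection estimate used to place the
    five target intensities (e.g. from a staircase run); it defaults to
    the observer's true psychometric threshold.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; "
                         f"expected one of {sorted(DESIGNS)}")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    condition_label, delay = DESIGNS[design]
    rng = np.random.default_rng(seed)

    theta = (params.psychometric_threshold if threshold_50 is None
             else threshold_50)
    intensities = np.linspace(0.9 * theta, 1.1 * theta, N_LEVELS)
    sub_intensity = SUBTHRESHOLD_FACTOR * theta
    shift = (params.effect_shift.get(condition_label, 0.0)
             if condition_label else 0.0)

    half = N_REPEATS_PER_LEVEL // 2
    cols: dict[str, list[np.ndarray]] = {k: [] for k in (
        "block", "intensity", "level", "condition", "delay", "catch")}
    for b in range(n_blocks):
        n_target = N_LEVELS * N_REPEATS_PER_LEVEL
        level = np.repeat(np.arange(1, N_LEVELS + 1), N_REPEATS_PER_LEVEL)
        inten = np.repeat(intensities, N_REPEATS_PER_LEVEL)
        paired = np.tile(np.r_[np.ones(half, bool), np.zeros(half, bool)],
                         N_LEVELS)
        if condition_label is None:
            paired[:] = False
        catch = np.zeros(n_target + N_CATCH_PER_BLOCK, bool)
        catch[n_target:] = True
        level = np.r_[level, np.zeros(N_CATCH_PER_BLOCK, int)]
        inten = np.r_[inten, np.full(N_CATCH_PER_BLOCK, sub_intensity)]
        paired = np.r_[paired, np.zeros(N_CATCH_PER_BLOCK, bool)]
        order = rng.permutation(len(level))
        cols["block"].append(np.full(len(level), b))
        cols["level"].append(level[order])
        cols["intensity"].append(inten[order])
        cols["condition"].append(np.where(paired[order], "paired", "control"))
        cols["delay"].append(np.where(paired[order], delay or -1, -1))
        cols["catch"].append(catch[order])

    block = np.concatenate(cols["block"])
    level = np.concatenate(cols["level"])
    inten = np.concatenate(cols["intensity"])
    condition = np.concatenate(cols["condition"]).astype(object)
    delay_ms = np.concatenate(cols["delay"])
    is_catch = np.concatenate(cols["catch"])

    p = detection_probability(inten, params)
    p = np.where(condition == "paired",
                 np.clip(p * (1.0 + shift), 0.0, 1.0), p)
    p = np.where(is_catch, params.false_alarm_rate, p)
    response = rng.random(len(p)) < p
    rt = np.where(response, 0.30 + 0.05 * rng.standard_normal(len(p)),
                  np.nan)

    return PsychSession(
        subject_id=subject_id, design=design, block=block, intensity=inten,
        level=level, condition=condition, delay_ms=delay_ms,
        is_catch=is_catch, response=response, rt=rt,
        threshold_50=theta, sub_intensity=sub_intensity,
        condition_label=condition_label)
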