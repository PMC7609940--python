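"""Threshold procedures and detection-rate statistics.

Covers the psychophysical analysis chain: absolute-threshold estimation
by the method of constant stimuli (on 7 Hz trains), 1-up-1-down
staircase estimation of the 50 % detection point, construction of the
five near-threshold target intensities, catch-trial validation
(imperceptibility control), and the group detection-rate comparison
reported as a relative change (rate_paired - rate_control)/rate_control
with a paired two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior_sim import PsychSession


# ------------------------------------------------------------- observers

class LogisticObserver:
    """Stochastic observer with a logistic psychometric function."""

    def __init__(self, threshold: float, slope: float, seed: int = 0):
        self.threshold = threshold
        self.slope = slope
        self._rng = np.random.default_rng(seed)

    def __call__(self, intensity: float) -> bool:
        p = 1.0 / (1.0 + np.exp(-self.slope * (intensity - self.threshold)))
        return bool(self._rng.random() < p)


class DeterministicObserver:
    """Detects if and only if the intensity exceeds a hard threshold."""

    def __init__(self, threshold: float):
        self.threshold = threshold

    def __call__(self, intensity: float) -> bool:
        return intensity > self.threshold


# --------------------------------------------------- threshold procedures

def absolute_threshold(observer, i_start: float, step: float = 0.1,
                       n_repeats: int = 5, max_steps: int = 100,
                       subthreshold_factor: float = 0.85
                       ) -> tuple[float, float]:
    """Absolute detection threshold by the method of constant stimuli.

    Ascends from ``i_start`` in fixed steps, presenting each level
    ``n_repeats`` times; the threshold is the lowest level detected on a
    majority of repeats.  Returns ``(threshold, subthreshold_intensity)``
    where the subthreshold stimulation intensity is set ~15 % below the
    threshold.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    level = i_start
    for _ in range(max_steps):
        hits = sum(observer(level) for _ in range(n_repeats))
        if hits > n_repeats // 2:
            return level, subthreshold_factor * level
        level += step
    raise RuntimeError(
        f"no detection up to {level:.3f} mA after {max_steps} steps")


def staircase_50(observer, i_start: float, step_initial: float,
                 n_reversals: int = 8, step_floor: float = 0.01,
                 max_trials: int = 200) -> float:
    """1-up-1-down staircase converging on the 50 % detection point.

    The step is halved at each reversal down to ``step_floor``; the
    estimate is the mean of the last ``n_reversals`` reversal
    intensities.
    """
    if n_reversals < 4:
        raise ValueError("n_reversals must be >= 4")
    level = i_start
    step = step_initial
    reversals: list[float] = []
    prev_detected: bool | None = None
    for _ in range(max_trials):
        detected = bool(observer(level))
        if prev_detected is not None and detected != prev_detected:
            reversals.append(level)
            step = max(step / 2.0, step_floor)
            if len(reversals) >= n_reversals:
                return float(np.mean(reversals[-n_reversals:]))
        prev_detected = detected
        level = level - step if detected else level + step
        level = max(level, 0.0)
    raise RuntimeError(
        f"staircase did not reach {n_reversals} reversals in "
        f"{max_trials} trials (got {len(reversals)})")


def target_intensities(threshold_50: float, band: tuple[float, float]
                       = (0.90, 1.10), n_levels: int = 5) -> np.ndarray:
    """Five linearly spaced near-threshold intensities around the 50 % point."""
    if threshold_50 <= 0:
        raise ValueError("threshold must be positive")
    lo, hi = band
    if lo == hi:
        import warnings
        warnings.warn("degenerate intensity band: all levels identical")
    return np.linspace(lo * threshold_50, hi * threshold_50, n_levels)


# ------------------------------------------------------ catch validation

def validate_catch_trials(session: PsychSession,
                          max_responses: int = 1) -> dict:
    """Per-block and per-subject imperceptibility verdicts.

    A block is flagged when the subject responded to more than
    ``max_responses`` catch trials; the subject verdict excludes flagged
    blocks (block-level discard).
    """
    blocks = np.unique(session.block)
    per_block = {}
    for b in blocks:
        mask = (session.block == b) & session.is_catch
        n_catch = int(mask.sum())
        if n_catch == 0:
            raise ValueError(f"block {b} contains no catch trials")
        n_resp = int(session.response[mask].sum())
        per_block[int(b)] = {"n_catch": n_catch, "n_responses": n_resp,
                             "valid": n_resp <= max_responses}
    valid_blocks = [b for b, v in per_block.items() if v["valid"]]
    return {"per_block": per_block, "valid_blocks": valid_blocks,
            "subject_valid": len(valid_blocks) > 0}


# ------------------------------------------------------- group statistics

@dataclass
class DetectionStats:
    """Group detection-rate comparison between paired and control trials."""

    rate_control: np.ndarray       # per subject, pooled over intensities
    rate_paired: np.ndarray
    relative_change: np.ndarray    # per subject
    mean_relative_change: float
    t: float
    df: int
    p: float
    n_excluded_blocks: int = 0
    n_excluded_subjects: int = 0


def _session_rates(session: PsychSession,
                   valid_blocks: list[int]) -> tuple[float, float]:
    in_valid = np.isin(session.block, valid_blocks)
    target = in_valid & ~session.is_catch
    ctrl = target & (session.condition == "control")
    pair = target & (session.condition == "paired")
    rate_c = float(session.response[ctrl].mean()) if ctrl.any() else np.nan
    rate_p = float(session.response[pair].mean()) if pair.any() else np.nan
    return rate_c, rate_p


def detection_stats(sessions: list[PsychSession],
                    validate: bool = True) -> DetectionStats:
    """Pooled detection rates, relative change, and the paired t-test.

    Detection rates are pooled over the five target intensities per
    condition.  Subjects with an undefined relative change (control rate
    of zero) are excluded with a logged count.
    """
    if len(sessions) < 2:
        raise ValueError("need at least two subjects")
    rates_c, rates_p = [], []
    n_excl_blocks = 0
    n_excl_subjects = 0
    for s in sessions:
        if validate:
            verdict = validate_catch_trials(s)
            valid = verdict["valid_blocks"]
            n_excl_blocks += len(verdict["per_block"]) - len(valid)
            if not verdict["subject_valid"]:
                n_excl_subjects += 1
                continue
        else:
            valid = list(np.unique(s.block))
        rc, rp = _session_rates(s, valid)
        if not np.isfinite(rp):
            raise ValueError("session has no paired trials; "
                             "detection_stats needs a paired design")
        if rc == 0:
            n_excl_subjects += 1
            continue
        rates_c.append(rc)
        rates_p.append(rp)

    rates_c = np.asarray(rates_c)
    rates_p = np.asarray(rates_p)
    if len(rates_c) < 2:
        raise ValueError("fewer than two valid subjects after exclusion")
    rel = (rates_p - rates_c) / rates_c
    diff = rates_p - rates_c
    if np.allclose(diff.std(ddof=1), 0.0):
        t, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_rel(rates_p, rates_c)
    return DetectionStats(
        rate_control=rates_c, rate_paired=rates_p, relative_change=rel,
        mean_relative_change=float(rel.mean()), t=float(t),
        df=len(rates_c) - 1, p=float(p),
        n_excluded_blocks=n_excl_blocks, n_excluded_subjects=n_excl_subjects)
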