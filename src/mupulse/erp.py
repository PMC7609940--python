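"""Epoch segmentation, history sorting, SEP averaging and P60 statistics.

Somatosensory evoked potentials (SEPs) are trial averages of epochs
around stimulation onsets (default window -200..2400 ms, baseline
-200..0 ms subtracted per epoch).  The P60 test averages the 55-65 ms
window and compares it to baseline (or to a reference window) with a
paired two-tailed t-test across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .epochs import EpochSet
from .recording import Recording

__all__ = ["epoch", "average_sep", "window_ttest",
           "compare_conditions_ttest", "WindowStat"]

#: (event kind, history) -> trial label
_LABEL_MAP = {
    ("sub_single", "after_single"): "SaS",
    ("sub_single", "after_train"): "SaT",
    ("sub_train", "after_single"): "TaS",
    ("sub_train", "after_train"): "TaT",
}


def epoch(rec: Recording, kinds=("sub_single", "sub_train"),
          tmin: float = -0.2, tmax: float = 2.4) -> EpochSet:
    """Cut fixed windows around the selected events.

    History labels are mapped to SaS/SaT/TaS/TaT; epochs that would
    cross a recording boundary are dropped (count logged on the result).
    """
    if tmin >= tmax:
        raise ValueError("tmin must be smaller than tmax")
    sel = rec.events.select(kinds)
    if len(sel) == 0:
        raise ValueError(f"no events of kinds {kinds} in the recording")
    n_len = int(round((tmax - tmin) * rec.rate))
    data, labels, kept = [], [], []
    n_dropped = 0
    for i in range(len(sel)):
        i0 = int(round((sel.onset[i] + tmin) * rec.rate))
        if i0 < 0 or i0 + n_len > rec.n_samples:
            n_dropped += 1
            continue
        data.append(rec.data[:, i0:i0 + n_len])
        labels.append(_LABEL_MAP.get((sel.kind[i], sel.history[i]), "none"))
        kept.append(i)
    if not data:
        raise ValueError("all epochs crossed the recording boundary")
    ep = EpochSet(data=np.stack(data), tmin=tmin, tmax=tmax, rate=rec.rate,
                  channels=tuple(rec.montage.labels),
                  labels=np.array(labels, dtype=object),
                  event_index=np.array(kept, dtype=int),
                  ground_truth=rec.ground_truth)
    ep.n_dropped = n_dropped
    return ep


def _baseline_correct(x: np.ndarray, times: np.ndarray,
                      baseline: tuple[float, float]) -> np.ndarray:
    mask = (times >= baseline[0]) & (times < baseline[1])
    return x - x[..., mask].mean(axis=-1, keepdims=True)


def average_sep(ep: EpochSet, channel: str = "C4", subset="all",
                baseline: tuple[float, float] = (-0.2, 0.0)
                ) -> tuple[np.ndarray, int]:
    """Trial-averaged SEP after per-epoch baseline subtraction.

    Returns ``(waveform, n_trials)``; ``subset`` filters by history
    label ('SaS', 'SaT', ..., or 'all').
    """
    ch = ep.channel_index(channel)
    mask = ep.label_mask(subset)
    if not mask.any():
        raise ValueError(f"no trials match subset {subset!r}")
    x = _baseline_correct(ep.data[mask, ch, :], ep.times, baseline)
    return x.mean(axis=0), int(mask.sum())


@dataclass
class WindowStat:
    """Paired window comparison across subjects."""

    window_means: np.ndarray      # per subject, test window
    ref_means: np.ndarray         # per subject, baseline/reference window
    t: float
    df: int
    p: float
    degenerate: bool = False      # zero-variance differences


def _paired_t(a: np.ndarray, b: np.ndarray) -> WindowStat:
    diff = a - b
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return WindowStat(a, b, 0.0, n - 1, 1.0)
        return WindowStat(a, b, np.inf * np.sign(diff.mean()), n - 1, 0.0,
                          degenerate=True)
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return WindowStat(a, b, float(t), n - 1, float(p))


def window_ttest(seps: np.ndarray, times: np.ndarray,
                 test_window: tuple[float, float] = (0.055, 0.065),
                 ref_window: tuple[float, float] = (-0.2, 0.0)
                 ) -> WindowStat:
    """Paired t-test of window means against a reference window.

    ``seps`` is (n_subjects, n_samples) of per-subject SEP waveforms.
    The default windows are the P60 window (55-65 ms) against the
    prestimulus baseline (-200..0 ms); a precomponent reference window
    (e.g. 38-42 ms) may be passed instead.
    """
    seps = np.atleast_2d(seps)
    if seps.shape[0] < 2:
        raise ValueError("need at least two subjects")
    if max(test_window[0], ref_window[0]) < min(test_window[1],
                                                ref_window[1]):
        raise ValueError("test and reference windows overlap")
    for w in (test_window, ref_window):
        if w[0] < times[0] - 1e-9 or w[1] > times[-1] + 1e-9:
            raise ValueError(f"window {w} outside epoch range")
    tw = (times >= test_window[0]) & (times < test_window[1])
    rw = (times >= ref_window[0]) & (times < ref_window[1])
    return _paired_t(seps[:, tw].mean(axis=1), seps[:, rw].mean(axis=1))


def compare_conditions_ttest(means_a: np.ndarray,
                             means_b: np.ndarray) -> WindowStat:
    """Paired two-tailed t-test between per-subject window means."""
    means_a = np.asarray(means_a, float)
    means_b = np.asarray(means_b, float)
    if means_a.shape != means_b.shape:
        raise ValueError("conditions must cover the same subjects")
    if len(means_a) < 2:
        raise ValueError("need at least two subjects")
    return _paired_t(means_a, means_b)
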