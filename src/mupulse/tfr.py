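"""Single-trial Morlet time-frequency analysis and baseline normalization.

Power is computed by FFT convolution with complex Morlet wavelets of
``n_cycles`` cycles (temporal SD sigma_t = n_cycles / (2 pi f)), unit-
energy normalized, on the 4-30 Hz grid in 1 Hz steps by default.  Edge
samples within one wavelet half-support of an epoch boundary are masked
invalid rather than zero-filled; all downstream statistics respect the
mask.  Baseline normalization is the relative change (P - B) / B with B
the mean baseline power of the trial-averaged map, so normalized values
read directly as fractional ERS (>0) / ERD (<0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSet

__all__ = ["TFRMap", "morlet_power", "baseline_normalize", "average_tfr",
           "default_freqs"]

#: wavelet truncated at this many temporal SDs; also the invalid-edge span
_SUPPORT_SD = 3.0


def default_freqs() -> np.ndarray:
    """The 4-30 Hz, 1 Hz step analysis grid."""
    return np.arange(4.0, 31.0, 1.0)


@dataclass
class TFRMap:
    """Time-frequency power, (trials x) frequencies x times.

    ``state`` is 'raw' (uV^2) or 'relative_change' (dimensionless
    fractional change vs baseline); ``mask`` marks valid samples.
    """

    power: np.ndarray             # (..., n_freqs, n_times)
    freqs: np.ndarray             # Hz
    times: np.ndarray             # s relative to event onset
    state: str = "raw"
    mask: np.ndarray = None       # (n_freqs, n_times) bool, True = valid
    baseline: tuple[float, float] | None = None
    n_trials: int | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, float)
        if self.power.shape[-2:] != (len(self.freqs), len(self.times)):
            raise ValueError("power shape does not match freq/time grids")
        if self.mask is None:
            self.mask = np.ones((len(self.freqs), len(self.times)),
                                dtype=bool)
        if self.state == "raw" and np.nanmin(self.power) < 0:
            raise ValueError("raw power must be non-negative")

    @property
    def per_trial(self) -> bool:
        return self.power.ndim == 3

    def freq_mask(self, fmin: float, fmax: float) -> np.ndarray:
        return (self.freqs >= fmin) & (self.freqs <= fmax)

    def time_mask(self, t0: float, t1: float) -> np.ndarray:
        return (self.times >= t0) & (self.times <= t1)


def _morlet_wavelet(freq: float, rate: float,
                    n_cycles: float) -> np.ndarray:
    sigma_t = n_cycles / (2 * np.pi * freq)
    half = int(np.ceil(_SUPPORT_SD * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    gauss = np.exp(-(t**2) / (2 * sigma_t**2))
    wav = gauss * np.exp(2j * np.pi * freq * t)
    # unit energy in continuous time: integral |psi|^2 dt = 1
    norm = np.sqrt(np.sum(np.abs(wav) ** 2) / rate)
    return wav / norm


def morlet_power(ep: EpochSet, channel: str = "C4",
                 freqs: np.ndarray | None = None, n_cycles: float = 5.0,
                 decim: int = 1) -> TFRMap:
    """Per-trial Morlet power of one channel.

    ``decim`` keeps every ``decim``-th time sample of the power map
    (power varies slowly at these bandwidths); the mask marks samples
    closer than one wavelet half-support to either epoch edge as
    invalid, separately per frequency.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    freqs = default_freqs() if freqs is None else np.asarray(freqs, float)
    ch = ep.channel_index(channel)
    x = ep.data[:, ch, :]
    n_times = x.shape[1]
    fmin = freqs.min()
    support = 2 * int(np.ceil(_SUPPORT_SD * n_cycles
                              / (2 * np.pi * fmin) * ep.rate)) + 1
    if support > n_times:
        raise ValueError(
            f"epoch too short for the wavelet at {fmin:g} Hz "
            f"(support {support} > {n_times} samples)")

    nfft = int(2 ** np.ceil(np.log2(n_times + support)))
    X = np.fft.fft(x, n=nfft, axis=-1)
    keep = np.arange(0, n_times, decim)
    power = np.empty((x.shape[0], len(freqs), len(keep)))
    mask = np.ones((len(freqs), len(keep)), dtype=bool)
    for fi, f in enumerate(freqs):
        wav = _morlet_wavelet(f, ep.rate, n_cycles)
        half = (len(wav) - 1) // 2
        W = np.fft.fft(wav, n=nfft)
        # 1/rate: discrete sum approximating the continuous convolution
        conv = np.fft.ifft(X * W[None, :], axis=-1) / ep.rate
        # 'same' alignment: sample k of the output is the wavelet centred
        # on input sample k
        full = conv[:, half:half + n_times]
        power[:, fi, :] = np.abs(full[:, keep]) ** 2
        edge = (keep < half) | (keep >= n_times - half)
        mask[fi, edge] = False

    return TFRMap(power=power, freqs=freqs, times=ep.times[keep],
                  state="raw", mask=mask, n_trials=x.shape[0],
                  info={"channel": channel, "n_cycles": n_cycles,
                        "rate": ep.rate, "decim": decim,
                        "labels": ep.labels.copy()})


def average_tfr(tfr: TFRMap, labels=None) -> TFRMap:
    """Average a per-trial map over trials (optionally by history label)."""
    if not tfr.per_trial:
        raise ValueError("average_tfr needs a per-trial map")
    if labels is None or labels == "all":
        sel = np.ones(tfr.power.shape[0], dtype=bool)
    else:
        trial_labels = tfr.info.get("labels")
        if trial_labels is None:
            raise ValueError("map carries no trial labels")
        if isinstance(labels, str):
            labels = (labels,)
        sel = np.isin(trial_labels.astype(str), list(labels))
    if not sel.any():
        raise ValueError(f"no trials match labels {labels!r}")
    return TFRMap(power=tfr.power[sel].mean(axis=0), freqs=tfr.freqs,
                  times=tfr.times, state=tfr.state, mask=tfr.mask.copy(),
                  baseline=tfr.baseline, n_trials=int(sel.sum()),
                  info={k: v for k, v in tfr.info.items() if k != "labels"})


def baseline_normalize(tfr: TFRMap, baseline: tuple[float, float]
                       = (-0.2, 0.0)) -> TFRMap:
    """Relative power change (P - B)/B per frequency.

    B is the mean raw power over the baseline window of the trial-
    averaged map (per-trial maps are first averaged for B, then each
    entry is normalized by it), restricted to valid samples.
    """
    if tfr.state != "raw":
        raise ValueError("map is already normalized")
    # half-open [t0, t1): the stimulus-onset sample is post, not baseline
    bmask = (tfr.times >= baseline[0]) & (tfr.times < baseline[1])
    vals = []
    for fi in range(len(tfr.freqs)):
        valid = bmask & tfr.mask[fi]
        if not valid.any():
            raise ValueError(
                f"baseline window has no valid samples at "
                f"{tfr.freqs[fi]:g} Hz")
        avg = tfr.power.mean(axis=0) if tfr.per_trial else tfr.power
        vals.append(avg[fi, valid].mean())
    b = np.asarray(vals)
    if np.any(b == 0):
        bad = tfr.freqs[b == 0]
        raise ValueError(f"zero baseline power at {bad} Hz")
    power = (tfr.power - b[:, None]) / b[:, None]
    return TFRMap(power=power, freqs=tfr.freqs, times=tfr.times,
                  state="relative_change", mask=tfr.mask.copy(),
                  baseline=baseline, n_trials=tfr.n_trials,
                  info=dict(tfr.info))
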