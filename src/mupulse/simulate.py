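"""Forward simulation of subthreshold-stimulation EEG.

Two generators share one source model:

* :func:`simulate_eeg` — a full 32-channel recording: central mu source
  (alpha + beta peaks) with event-dependent power gains, occipital alpha,
  blink artifacts, a P60 evoked component and white + 1/f channel noise,
  mixed through fixed scalp topographies.  Ground-truth source time
  courses and gain profiles are attached for recovery tests.
* :func:`simulate_epochs` — the reduced protocol: C4 epochs are drawn
  directly per trial label (SaS/SaT/train/none) with the same gain
  model.  This is what repeated multi-subject calibration analyses use;
  it skips volume conduction and artifacts, which the full path covers.

Gain semantics are power gains: a gain g scales oscillation amplitude by
sqrt(1+g) so that baseline-normalized power recovers g.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .epochs import EpochSet
from .events import EventTable, SUPRA_KINDS, TRAIN_DURATION_S
from .montage import Montage, gaussian_topography, standard_montage
from .params import SubjectParams
from .recording import Recording

__all__ = ["simulate_eeg", "simulate_epochs", "mu_source_timecourse"]


# --------------------------------------------------------------- primitives

def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                rate: float) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _slow_envelope(rng: np.random.Generator, n: int, rate: float,
                   wander: float, cutoff: float = 0.1) -> np.ndarray:
    """Positive slowly wandering amplitude envelope, mean ~1."""
    if wander == 0 or n < 16:
        return np.ones(n)
    white = rng.standard_normal(n)
    sos = signal.butter(2, cutoff, btype="low", fs=rate, output="sos")
    slow = signal.sosfiltfilt(sos, white)
    sd = slow.std() or 1.0
    return np.clip(1.0 + wander * slow / sd, 0.05, None)


def _add_window(g: np.ndarray, rate: float, t0: float, t1: float,
                amount: float, ramp: float = 0.05) -> None:
    """Add ``amount`` over [t0, t1] with half-cosine edge ramps (in place)."""
    n = len(g)
    i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
    i0c, i1c = max(i0, 0), min(i1, n)
    if i1c <= i0c:
        return
    nr = max(int(round(ramp * rate)), 1)
    win = np.ones(i1 - i0)
    edge = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    m = min(nr, len(win) // 2)
    win[:m] = edge[:m]
    win[len(win) - m:] = edge[:m][::-1]
    g[i0c:i1c] += amount * win[i0c - i0:i1c - i0]


def _add_exp_tail(g: np.ndarray, rate: float, t0: float, amount: float,
                  tau: float, n_tau: float = 5.0) -> None:
    """Add amount * exp(-(t - t0)/tau) for t >= t0 (in place)."""
    n = len(g)
    i0 = int(round(t0 * rate))
    i1 = min(int(round((t0 + n_tau * tau) * rate)), n)
    if i1 <= max(i0, 0):
        return
    idx = np.arange(max(i0, 0), i1)
    g[idx] += amount * np.exp(-(idx / rate - t0) / tau)


def _gauss_pulse(n: int, rate: float, onset: float, latency: float,
                 amp: float, fwhm: float, out: np.ndarray) -> None:
    """Add a Gaussian deflection peaking at onset+latency (in place)."""
    sigma = fwhm / 2.3548200450309493
    t_peak = onset + latency
    i0 = max(int((t_peak - 4 * sigma) * rate), 0)
    i1 = min(int((t_peak + 4 * sigma) * rate) + 1, n)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / rate
    out[i0:i1] += amp * np.exp(-0.5 * ((t - t_peak) / sigma) ** 2)


def _reinduced_erd(params: SubjectParams, dt_since_train_end: float) -> float:
    """Desynchronization re-induced by a single pulse following a train.

    A train shifts the network into a desynchronization-prone state that
    decays with ``hysteresis_decay``; a subsequent single pulse does not
    produce an ERS (the synchronization is absent after trains) but
    instead re-induces an ERD proportional to the remaining after-effect.
    """
    return params.erd_gain * np.exp(-max(dt_since_train_end, 0.0)
                                    / params.hysteresis_decay)


#: window (s post onset) of the re-induced desynchronization on SaT trials
_REINDUCE_WINDOW = (0.10, 0.50)


# --------------------------------------------------------- gain timecourses

def _event_gain_timecourses(events: EventTable, params: SubjectParams,
                            n: int, rate: float) -> tuple[np.ndarray,
                                                          np.ndarray]:
    """Alpha- and beta-band power-gain profiles over the whole recording."""
    g_a = np.zeros(n)
    g_b = np.zeros(n)
    prev_train_end: float | None = None
    for i in range(len(events)):
        kind = events.kind[i]
        onset = float(events.onset[i])
        if kind == "sub_single":
            if events.history[i] == "after_train":
                # no ERS after a train; the pulse re-induces an ERD
                dt = (onset - prev_train_end
                      if prev_train_end is not None else np.inf)
                _add_window(g_a, rate, onset + _REINDUCE_WINDOW[0],
                            onset + _REINDUCE_WINDOW[1],
                            _reinduced_erd(params, dt))
            else:
                _add_window(g_a, rate, onset + params.ers_window[0],
                            onset + params.ers_window[1], params.ers_gain)
        elif kind == "sub_train":
            w0, w1 = params.erd_window
            _add_window(g_a, rate, onset + w0, onset + w1, params.erd_gain)
            _add_exp_tail(g_a, rate, onset + w1, params.erd_gain,
                          params.hysteresis_decay)
            # brief accompanying beta desynchronization during the train
            _add_window(g_b, rate, onset + w0, onset + TRAIN_DURATION_S,
                        0.5 * params.erd_gain)
            prev_train_end = onset + TRAIN_DURATION_S
        elif kind in SUPRA_KINDS:
            s0, s1 = params.supra_erd_window
            _add_window(g_a, rate, onset + s0, onset + s1,
                        params.supra_erd_gain)
            _add_window(g_b, rate, onset + s0, onset + s1,
                        params.supra_erd_gain)
    np.clip(g_a, -0.95, None, out=g_a)
    np.clip(g_b, -0.95, None, out=g_b)
    return g_a, g_b


def mu_source_timecourse(events: EventTable, params: SubjectParams,
                         n: int, rate: float,
                         rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Mu source with event-dependent power gains; returns parts for tests."""
    t = np.arange(n) / rate
    g_a, g_b = _event_gain_timecourses(events, params, n, rate)
    env = _slow_envelope(rng, n, rate, params.env_wander)
    phase_a, phase_b = rng.uniform(0, 2 * np.pi, size=2)
    alpha = (params.mu_base_amp * env * np.sqrt(1.0 + g_a)
             * np.sin(2 * np.pi * params.mu_alpha_freq * t + phase_a))
    beta = (params.mu_base_amp * params.mu_beta_rel * env
            * np.sqrt(1.0 + g_b)
            * np.sin(2 * np.pi * params.mu_beta_freq * t + phase_b))
    return {"mu": alpha + beta, "mu_alpha": alpha, "mu_beta": beta,
            "gain_alpha": g_a, "gain_beta": g_b, "envelope": env}


def _evoked_source(events: EventTable, params: SubjectParams, n: int,
                   rate: float) -> np.ndarray:
    """P60 deflections for every subthreshold pulse; biphasic supra response."""
    out = np.zeros(n)
    for i in range(len(events)):
        kind = events.kind[i]
        onset = float(events.onset[i])
        if kind == "sub_single":
            _gauss_pulse(n, rate, onset, params.p60_latency, params.p60_amp,
                         params.p60_width, out)
        elif kind == "sub_train":
            for p in events.train_pulse_onsets[i]:
                _gauss_pulse(n, rate, float(p), params.p60_latency,
                             params.p60_amp, params.p60_width, out)
        elif kind in SUPRA_KINDS:
            _gauss_pulse(n, rate, onset, 0.050, 10 * params.p60_amp,
                         0.012, out)
            _gauss_pulse(n, rate, onset, 0.095, -6 * params.p60_amp,
                         0.020, out)
    return out


def _blink_source(params: SubjectParams, n: int, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n)
    duration = n / rate
    n_blinks = rng.poisson(params.blink_rate * duration)
    onsets = np.sort(rng.uniform(0, duration, size=n_blinks))
    for onset in onsets:
        _gauss_pulse(n, rate, float(onset), 0.0, params.blink_amp, 0.25, out)
    return out


# ------------------------------------------------------------ full forward

def simulate_eeg(events: EventTable, params: SubjectParams,
                 montage: Montage | None = None, rate: float = 1000.0,
                 seed: int = 0, pad: float = 3.0) -> Recording:
    """Simulate a full multichannel recording for one subject.

    The recording is a linear mixture of four sources (central mu,
    occipital alpha, blinks, evoked P60) through Gaussian scalp
    topographies, plus per-channel white + 1/f noise.  Ground-truth
    source time courses, gain profiles and topographies are attached to
    ``Recording.ground_truth``.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    montage = montage or standard_montage()
    rng = np.random.default_rng(seed)
    duration = events.end_time() + pad if len(events) else pad
    if len(events) and events.onset[0] < 0:
        raise ValueError("events must start at or after time zero")
    n = int(round(duration * rate))

    mu = mu_source_timecourse(events, params, n, rate, rng)
    t = np.arange(n) / rate
    occ_env = _slow_envelope(rng, n, rate, params.env_wander)
    occ = (params.occ_alpha_amp * occ_env
           * np.sin(2 * np.pi * params.occ_alpha_freq * t
                    + rng.uniform(0, 2 * np.pi)))
    blink = _blink_source(params, n, rate, rng)
    evoked = _evoked_source(events, params, n, rate)

    topo = {
        "mu": gaussian_topography(montage, "C4", 0.35),
        "occ": gaussian_topography(montage, np.array([0.0, -0.97]), 0.40),
        "blink": gaussian_topography(montage, np.array([0.0, 1.05]), 0.40),
        "evoked": gaussian_topography(montage, "C4", 0.35),
    }
    data = (np.outer(topo["mu"], mu["mu"]) + np.outer(topo["occ"], occ)
            + np.outer(topo["blink"], blink)
            + np.outer(topo["evoked"], evoked))
    if params.noise_sd > 0:
        white = rng.standard_normal((montage.n_channels, n))
        pink = _pink_noise(rng, (montage.n_channels, n), rate)
        data = data + params.noise_sd * np.sqrt(0.5) * (white + pink)

    rec = Recording(
        data=data, rate=rate, montage=montage, events=events,
        ground_truth={"sources": {"mu": mu["mu"], "occ": occ,
                                  "blink": blink, "evoked": evoked},
                      "mu_parts": mu, "topographies": topo,
                      "params": params, "seed": seed})
    rec.log("simulate_eeg", rate=rate, seed=seed)
    return rec


# -------------------------------------------------------- reduced protocol

def _epoch_gain_profiles(label: str, params: SubjectParams,
                         times: np.ndarray, rate: float,
                         gap: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alpha/beta power-gain profiles for one trial label.

    ``gap`` (per trial) is the interval between the preceding train's end
    and this trial's onset; it only matters for SaT trials, whose epochs
    carry the decaying residual ERD of that train plus a hysteresis-
    suppressed ERS.
    """
    n = len(times)
    base_a = np.zeros(n)
    base_b = np.zeros(n)
    if label in ("SaS", "single"):
        _add_window(base_a, rate, params.ers_window[0] - times[0],
                    params.ers_window[1] - times[0], params.ers_gain)
        g_a = np.broadcast_to(base_a, (len(gap), n)).copy()
        g_b = np.broadcast_to(base_b, (len(gap), n)).copy()
    elif label == "SaT":
        g_a = np.zeros((len(gap), n))
        g_b = np.zeros((len(gap), n))
        # ERS is absent after a train; the pulse re-induces an ERD
        # proportional to the decayed train after-effect
        for i, gp in enumerate(gap):
            _add_window(g_a[i], rate, _REINDUCE_WINDOW[0] - times[0],
                        _REINDUCE_WINDOW[1] - times[0],
                        _reinduced_erd(params, float(gp)))
        # residual ERD of the preceding train, still decaying through
        # the baseline and this trial (times are relative to this onset;
        # the preceding train ended `gap` seconds before it)
        since_train_end = np.clip(gap[:, None] + times[None, :], 0.0, None)
        g_a += params.erd_gain * np.exp(-since_train_end
                                        / params.hysteresis_decay)
    elif label in ("train", "TaS", "TaT"):
        w0, w1 = params.erd_window
        _add_window(base_a, rate, w0 - times[0], w1 - times[0],
                    params.erd_gain)
        _add_exp_tail(base_a, rate, w1 - times[0], params.erd_gain,
                      params.hysteresis_decay)
        _add_window(base_b, rate, w0 - times[0],
                    TRAIN_DURATION_S - times[0], 0.5 * params.erd_gain)
        g_a = np.broadcast_to(base_a, (len(gap), n)).copy()
        g_b = np.broadcast_to(base_b, (len(gap), n)).copy()
        if label == "TaT":  # residual ERD of the preceding train
            since_train_end = np.clip(gap[:, None] + times[None, :],
                                      0.0, None)
            g_a = g_a + params.erd_gain * np.exp(-since_train_end
                                                 / params.hysteresis_decay)
    elif label == "none":
        g_a = np.zeros((len(gap), n))
        g_b = np.zeros((len(gap), n))
    else:
        raise ValueError(f"unknown epoch label {label!r}")
    np.clip(g_a, -0.95, None, out=g_a)
    np.clip(g_b, -0.95, None, out=g_b)
    return g_a, g_b


def simulate_epochs(label_counts: dict[str, int], params: SubjectParams,
                    rate: float = 500.0, tmin: float = -0.2,
                    tmax: float = 2.4, seed: int = 0,
                    isi_mean: float = 2.0,
                    isi_jitter: float = 0.3) -> EpochSet:
    """Directly simulate labelled C4 epochs (reduced single-channel protocol).

    ``label_counts`` maps trial labels ({'SaS', 'SaT', 'train', 'none'})
    to trial counts.  Each epoch contains the mu source (alpha + beta
    with random phase, slow amplitude wandering and the label's power-
    gain profile), the P60 evoked component (eight pulses for trains)
    and white + 1/f noise.  Ground-truth gain profiles are attached.
    """
    rng = np.random.default_rng(seed)
    n = int(round((tmax - tmin) * rate))
    times = tmin + np.arange(n) / rate
    canonical = {"single": "SaS", "train": "TaS"}

    blocks: list[np.ndarray] = []
    labels: list[str] = []
    truths: dict[str, np.ndarray] = {}
    for label, count in label_counts.items():
        if count <= 0:
            continue
        # gap between the previous train's end and this onset (SaT only):
        # onset-to-onset ISI is measured from the train end, so the gap is
        # the drawn ISI itself.
        gap = rng.uniform(isi_mean - isi_jitter, isi_mean + isi_jitter,
                          size=count)
        g_a, g_b = _epoch_gain_profiles(label, params, times, rate, gap)
        truths[canonical.get(label, label)] = g_a.mean(axis=0)

        amp = (params.mu_base_amp
               * np.clip(1.0 + params.env_wander
                         * rng.standard_normal(count), 0.05, None))
        ph_a = rng.uniform(0, 2 * np.pi, size=count)[:, None]
        ph_b = rng.uniform(0, 2 * np.pi, size=count)[:, None]
        alpha = (amp[:, None] * np.sqrt(1.0 + g_a)
                 * np.sin(2 * np.pi * params.mu_alpha_freq * times + ph_a))
        beta = (amp[:, None] * params.mu_beta_rel * np.sqrt(1.0 + g_b)
                * np.sin(2 * np.pi * params.mu_beta_freq * times + ph_b))
        data = alpha + beta

        evoked = np.zeros(n)
        if label in ("SaS", "SaT", "single", "none"):
            _gauss_pulse(n, rate, -tmin, params.p60_latency,
                         params.p60_amp, params.p60_width, evoked)
        elif label in ("train", "TaS", "TaT"):
            for k in range(8):
                _gauss_pulse(n, rate, k / 7.0 - tmin, params.p60_latency,
                             params.p60_amp, params.p60_width, evoked)
        data = data + evoked

        if params.noise_sd > 0:
            white = rng.standard_normal((count, n))
            pink = _pink_noise(rng, (count, n), rate)
            data = data + params.noise_sd * np.sqrt(0.5) * (white + pink)

        blocks.append(data)
        labels.extend([canonical.get(label, label)] * count)

    if not blocks:
        raise ValueError("label_counts requested zero epochs")
    data = np.concatenate(blocks, axis=0)[:, None, :]
    return EpochSet(data=data, tmin=tmin, tmax=tmax, rate=rate,
                    channels=("C4",), labels=np.array(labels, dtype=object),
                    ground_truth={"gain_alpha": truths, "params": params,
                                  "seed": seed})
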