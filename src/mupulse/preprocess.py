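"""Filtering, resampling, ICA and Rolandic-component selection.

The preprocessing chain mirrors standard practice for mu-rhythm EEG:
zero-phase third-order Butterworth band-pass (1-45 Hz), downsampling to
500 Hz, ICA decomposition, removal of ocular components, operational
selection of Rolandic components (central topography, alpha + beta
spectral peaks above the 1/f background, desynchronization after
suprathreshold stimulation), and back-projection of the selected
components to electrode space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA

from .events import EventTable, SUPRA_KINDS
from .montage import FRONTAL_ROWS, Montage, ROWS
from .recording import Recording

__all__ = ["bandpass_filter", "resample", "run_ica",
           "flag_ocular_components", "select_rolandic_components",
           "backproject", "ComponentSet"]


# ----------------------------------------------------------------- filters

def bandpass_filter(rec: Recording, low: float = 1.0, high: float = 45.0,
                    order: int = 3) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    nyq = rec.rate / 2.0
    if not 0 < low < high:
        raise ValueError(f"invalid band: low={low}, high={high}")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="band", fs=rec.rate,
                        output="sos")
    out = rec.copy_with(signal.sosfiltfilt(sos, rec.data, axis=-1))
    out.log("bandpass_filter", low=low, high=high, order=order)
    return out


def resample(rec: Recording, new_rate: float) -> Recording:
    """Polyphase downsampling; event onsets (in seconds) are unchanged."""
    if new_rate > rec.rate:
        raise ValueError("upsampling is out of scope")
    if new_rate == rec.rate:
        out = rec.copy_with(rec.data.copy())
        out.log("resample", new_rate=new_rate)
        return out
    from fractions import Fraction
    frac = Fraction(new_rate / rec.rate).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                axis=-1)
    n_target = int(round(rec.duration * new_rate))
    data = data[:, :n_target]
    out = rec.copy_with(data, rate=new_rate)
    out.log("resample", new_rate=new_rate)
    return out


# --------------------------------------------------------------------- ICA

@dataclass
class ComponentSet:
    """ICA decomposition with per-component annotations.

    ``mixing @ sources + mean`` reconstructs the input recording when all
    components are kept.
    """

    unmixing: np.ndarray          # (n_components, n_channels)
    mixing: np.ndarray            # (n_channels, n_components)
    sources: np.ndarray           # (n_components, n_samples)
    mean: np.ndarray              # (n_channels,) channel means
    rate: float
    montage: Montage
    events: EventTable
    provenance: list[dict] = field(default_factory=list)
    ocular: np.ndarray = None     # (n_components,) bool
    rolandic: np.ndarray = None   # (n_components,) bool
    diagnostics: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_components > self.montage.n_channels:
            raise ValueError("more components than channels")
        if self.ocular is None:
            self.ocular = np.zeros(self.n_components, dtype=bool)
        if self.rolandic is None:
            self.rolandic = np.zeros(self.n_components, dtype=bool)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def topography(self, comp: int) -> np.ndarray:
        """Scalp map (mixing column) of one component."""
        return self.mixing[:, comp]

    def reconstruct(self, keep=None) -> np.ndarray:
        if keep is None:
            keep = np.arange(self.n_components)
        keep = np.asarray(keep, dtype=int)
        return self.mixing[:, keep] @ self.sources[keep] + self.mean[:, None]


def run_ica(rec: Recording, n_components: int | None = None, seed: int = 0,
            enforce_order: bool = True, max_iter: int = 1000) -> ComponentSet:
    """ICA decomposition of a filtered, downsampled recording.

    The algorithm is pluggable in principle; the default backend is
    fixed-point FastICA, deterministic for a given ``seed``.  Callers are
    expected to filter and downsample first; set ``enforce_order=False``
    to bypass the provenance check.
    """
    n_components = n_components or rec.n_channels
    if n_components > rec.n_channels:
        raise ValueError("n_components exceeds channel count")
    if enforce_order and not (rec.has_step("bandpass_filter")
                              and rec.has_step("resample")):
        raise ValueError("recording should be filtered and resampled "
                         "before ICA (pass enforce_order=False to override)")
    X = rec.data
    rank = np.linalg.matrix_rank(np.cov(X))
    if rank < n_components:
        raise ValueError(
            f"data rank {rank} below requested {n_components} components")
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=max_iter, tol=1e-5)
    sources = ica.fit_transform(X.T).T
    cs = ComponentSet(unmixing=ica.components_, mixing=ica.mixing_,
                      sources=sources, mean=ica.mean_, rate=rec.rate,
                      montage=rec.montage, events=rec.events,
                      provenance=list(rec.provenance))
    cs.provenance.append({"op": "run_ica", "n_components": n_components,
                          "seed": seed})
    return cs


# ----------------------------------------------------- component criteria

def _component_psd(cs: ComponentSet, comp: int,
                   nperseg: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    f, p = signal.welch(cs.sources[comp], fs=cs.rate,
                        nperseg=int(nperseg * cs.rate))
    return f, p


def _bandpower(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    mask = (f >= lo) & (f < hi)
    return float(np.trapezoid(p[mask], f[mask])) if mask.any() else 0.0


def flag_ocular_components(cs: ComponentSet, frontal_ratio: float = 2.0,
                           lowfreq_ratio: float = 3.0) -> ComponentSet:
    """Flag blink/ocular components.

    A component is ocular when its topography mass is frontally dominant
    (mean |weight| over the frontopolar/frontal rows exceeds
    ``frontal_ratio`` x the mean elsewhere) AND its power below 4 Hz
    exceeds ``lowfreq_ratio`` x its alpha-band (8-13 Hz) power.
    """
    frontal_idx = sorted({i for row in FRONTAL_ROWS
                          for i in cs.montage.row_indices(row)})
    other_idx = [i for i in range(cs.montage.n_channels)
                 if i not in frontal_idx]
    for comp in range(cs.n_components):
        w = np.abs(cs.topography(comp))
        topo_ratio = w[frontal_idx].mean() / max(w[other_idx].mean(), 1e-12)
        f, p = _component_psd(cs, comp)
        power_ratio = (_bandpower(f, p, 0.5, 4.0)
                       / max(_bandpower(f, p, 8.0, 13.0), 1e-12))
        is_ocular = bool(topo_ratio > frontal_ratio
                         and power_ratio > lowfreq_ratio)
        cs.ocular[comp] = is_ocular
        cs.diagnostics.append({"component": comp, "check": "ocular",
                               "frontal_ratio": topo_ratio,
                               "lowfreq_ratio": power_ratio,
                               "flagged": is_ocular})
    cs.provenance.append({"op": "flag_ocular_components",
                          "frontal_ratio": frontal_ratio,
                          "lowfreq_ratio": lowfreq_ratio})
    return cs


#: rows forming the "central" region (C3/Cz/C4 and their neighbours)
_CENTRAL_REGION = ("frontocentral", "central", "centroparietal")


def _central_topography(cs: ComponentSet, comp: int) -> tuple[bool, dict]:
    """Peak |weight| channel must lie over the central region."""
    w = np.abs(cs.topography(comp))
    peak_label = cs.montage.labels[int(np.argmax(w))]
    central_labels = {cs.montage.labels[i] for row in _CENTRAL_REGION
                      for i in cs.montage.row_indices(row)}
    row_means = {row: w[cs.montage.row_indices(row)].mean()
                 for row in ROWS if cs.montage.row_indices(row)}
    return peak_label in central_labels, {
        "peak_channel": peak_label, "row_means": row_means}


def _spectral_peaks(cs: ComponentSet, comp: int,
                    prominence_frac: float = 0.2,
                    alpha_floor: float = 0.5) -> tuple[bool, dict]:
    """Alpha and beta local maxima above a log-log 1/f fit.

    Prominence is the relative excess over the fitted 1/f background,
    (P - fit)/fit at a local maximum; the alpha peak must exceed
    ``alpha_floor`` and the beta peak ``prominence_frac`` of the alpha
    prominence.
    """
    f, p = _component_psd(cs, comp)
    fit_mask = (f >= 2.0) & (f <= 40.0) & (p > 0)
    logf, logp = np.log10(f[fit_mask]), np.log10(p[fit_mask])
    slope, intercept = np.polyfit(logf, logp, 1)
    fit = np.full_like(p, np.nan)
    fit[fit_mask] = 10 ** (intercept + slope * logf)

    def band_peak(lo: float, hi: float) -> float:
        best = 0.0
        for i in np.flatnonzero((f >= lo) & (f <= hi)):
            if (0 < i < len(p) - 1 and p[i] >= p[i - 1]
                    and p[i] >= p[i + 1] and np.isfinite(fit[i])):
                best = max(best, (p[i] - fit[i]) / fit[i])
        return best

    alpha_prom = band_peak(7.0, 14.0)
    beta_prom = band_peak(15.0, 29.0)
    ok = bool(alpha_prom > alpha_floor
              and beta_prom > prominence_frac * alpha_prom)
    return ok, {"alpha_prominence": alpha_prom, "beta_prominence": beta_prom}


def _post_supra_erd(cs: ComponentSet, comp: int, supra: EventTable,
                    delta: float = 0.1,
                    window: tuple[float, float] = (0.1, 0.6),
                    baseline: tuple[float, float] = (-0.2, 0.0)
                    ) -> tuple[bool, dict]:
    """Alpha-band (8-13 Hz) power drop after suprathreshold pulses."""
    sos = signal.butter(3, [8.0, 13.0], btype="band", fs=cs.rate,
                        output="sos")
    env2 = np.abs(signal.hilbert(
        signal.sosfiltfilt(sos, cs.sources[comp]))) ** 2
    n = len(env2)
    post_vals, base_vals = [], []
    for onset in supra.onset:
        i_w0 = int((onset + window[0]) * cs.rate)
        i_w1 = int((onset + window[1]) * cs.rate)
        i_b0 = int((onset + baseline[0]) * cs.rate)
        i_b1 = int((onset + baseline[1]) * cs.rate)
        if i_b0 < 0 or i_w1 > n:
            continue
        post_vals.append(env2[i_w0:i_w1].mean())
        base_vals.append(env2[i_b0:i_b1].mean())
    if not post_vals:
        return False, {"rel_change": np.nan}
    post, base = np.mean(post_vals), np.mean(base_vals)
    rel = (post - base) / base
    return bool(rel < -delta), {"rel_change": float(rel)}


def select_rolandic_components(cs: ComponentSet,
                               supra_events: EventTable | None = None,
                               prominence_frac: float = 0.2,
                               erd_delta: float = 0.1) -> ComponentSet:
    """Flag Rolandic components by the three operational criteria.

    (1) central topography: the central electrode row carries the
    largest mean |weight|; (2) alpha (7-14 Hz) and beta (15-29 Hz) local
    spectral maxima above a log-log 1/f fit, the beta prominence at
    least ``prominence_frac`` of the alpha prominence; (3) alpha-band
    desynchronization (relative change < -``erd_delta``) in 0.1-0.6 s
    after suprathreshold stimulation.  Ocular components are ineligible.
    """
    supra = (supra_events if supra_events is not None
             else cs.events.select(SUPRA_KINDS))
    if len(supra) == 0:
        raise ValueError("no suprathreshold events: the post-supra "
                         "desynchronization criterion is untestable")
    for comp in range(cs.n_components):
        if cs.ocular[comp]:
            cs.rolandic[comp] = False
            continue
        c1, d1 = _central_topography(cs, comp)
        c2, d2 = _spectral_peaks(cs, comp, prominence_frac)
        c3, d3 = _post_supra_erd(cs, comp, supra, erd_delta)
        cs.rolandic[comp] = bool(c1 and c2 and c3)
        cs.diagnostics.append({"component": comp, "check": "rolandic",
                               "central_topography": c1,
                               "spectral_peaks": c2, "post_supra_erd": c3,
                               **d1, **d2, **d3,
                               "flagged": bool(cs.rolandic[comp])})
    cs.provenance.append({"op": "select_rolandic_components",
                          "prominence_frac": prominence_frac,
                          "erd_delta": erd_delta})
    return cs


def backproject(cs: ComponentSet, keep) -> Recording:
    """Reconstruct a Recording from a subset of components."""
    keep = np.asarray(list(keep) if not isinstance(keep, np.ndarray)
                      else keep, dtype=int)
    if keep.size == 0:
        raise ValueError("keep must contain at least one component")
    if keep.min() < 0 or keep.max() >= cs.n_components:
        raise ValueError("component index out of range")
    rec = Recording(data=cs.reconstruct(keep), rate=cs.rate,
                    montage=cs.montage, events=cs.events,
                    provenance=list(cs.provenance))
    rec.log("backproject", keep=keep.tolist())
    return rec
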