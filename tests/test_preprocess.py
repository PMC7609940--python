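"""Filtering, resampling, ICA contract, component selection."""

import numpy as np
import pytest
from scipy import signal

from mupulse import preprocess as pp
from mupulse.events import make_event_sequence
from mupulse.montage import standard_montage
from mupulse.params import SubjectParams
from mupulse.recording import Recording
from mupulse.simulate import simulate_eeg


def _sine_recording(freq, rate=1000.0, duration=20.0, amp=1.0):
    t = np.arange(int(duration * rate)) / rate
    data = np.tile(amp * np.sin(2 * np.pi * freq * t),
                   (32, 1))
    from mupulse.events import EventTable
    events = EventTable(onset=np.array([duration / 2]),
                        kind=np.array(["sub_single"], object),
                        block=np.array([0]),
                        history=np.array(["none"], object))
    return Recording(data=data, rate=rate, montage=standard_montage(),
                     events=events)


class TestBandpass:
    def test_passband_identity(self):
        rec = _sine_recording(10.0)
        out = pp.bandpass_filter(rec, 1.0, 45.0, 3)
        trim = slice(2000, -2000)
        ratio = (np.abs(out.channel("C4")[trim]).max()
                 / np.abs(rec.channel("C4")[trim]).max())
        assert ratio > 0.99

    def test_stopband_attenuation_matches_butterworth_magnitude(self):
        """Forward-backward filtering squares the magnitude response."""
        rec = _sine_recording(0.1, duration=60.0)
        out = pp.bandpass_filter(rec, 1.0, 45.0, 3)
        sos = signal.butter(3, [1.0, 45.0], btype="band", fs=rec.rate,
                            output="sos")
        _, h = signal.sosfreqz(sos, worN=[0.1], fs=rec.rate)
        expected = np.abs(h[0]) ** 2
        trim = slice(20000, -20000)
        measured = (np.abs(out.channel("C4")[trim]).max()
                    / np.abs(rec.channel("C4")[trim]).max())
        assert measured <= expected * 1.5
        assert measured < 0.01  # deep stop-band either way

    def test_zero_phase(self):
        """Cross-correlation peak lag between input and output is zero."""
        rng = np.random.default_rng(1)
        rec = _sine_recording(10.0)
        rec.data += rng.standard_normal(rec.data.shape) * 0.1
        out = pp.bandpass_filter(rec, 5.0, 15.0, 3)
        x = rec.channel("C4")[3000:-3000]
        y = out.channel("C4")[3000:-3000]
        lags = signal.correlation_lags(len(x), len(y))
        xc = signal.correlate(x - x.mean(), y - y.mean())
        assert lags[np.argmax(xc)] == 0

    def test_invalid_band_rejected(self):
        rec = _sine_recording(10.0)
        with pytest.raises(ValueError):
            pp.bandpass_filter(rec, 50.0, 45.0, 3)
        with pytest.raises(ValueError, match="Nyquist"):
            pp.bandpass_filter(rec, 1.0, 600.0, 3)


class TestResample:
    def test_downsampled_sine_matches_ideal(self):
        rec = _sine_recording(10.0)
        out = pp.resample(rec, 500.0)
        t = np.arange(out.n_samples) / out.rate
        ideal = np.sin(2 * np.pi * 10.0 * t)
        trim = slice(500, -500)
        r = np.corrcoef(out.channel("C4")[trim], ideal[trim])[0, 1]
        assert r > 0.999
        assert out.n_samples == round(rec.duration * 500.0)

    def test_identity_when_rate_unchanged(self):
        rec = _sine_recording(10.0)
        out = pp.resample(rec, rec.rate)
        assert np.allclose(out.data, rec.data, rtol=1e-12)

    def test_upsampling_rejected(self):
        rec = _sine_recording(10.0)
        with pytest.raises(ValueError):
            pp.resample(rec, 2000.0)


class TestICA:
    def _mixture(self, seed=0, n=20000):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / 500.0
        sources = np.vstack([
            np.sign(np.sin(2 * np.pi * 3.1 * t)),        # square wave
            signal.sawtooth(2 * np.pi * 7.3 * t),        # sawtooth
            rng.laplace(size=n),                         # heavy-tailed noise
        ])
        montage = standard_montage()
        mixing = rng.standard_normal((montage.n_channels, 3))
        from mupulse.events import EventTable
        events = EventTable(onset=np.array([1.0]),
                            kind=np.array(["sub_single"], object),
                            block=np.array([0]),
                            history=np.array(["none"], object))
        rec = Recording(data=mixing @ sources, rate=500.0,
                        montage=montage, events=events)
        return rec, sources

    def test_three_source_recovery(self):
        rec, sources = self._mixture()
        cs = pp.run_ica(rec, n_components=3, seed=0, enforce_order=False)
        matched = set()
        for k in range(3):
            cors = [abs(np.corrcoef(cs.sources[k], s)[0, 1])
                    for s in sources]
            best = int(np.argmax(cors))
            assert max(cors) > 0.95
            matched.add(best)
        assert matched == {0, 1, 2}  # one-to-one matching

    def test_reconstruction_invariant(self):
        rec, _ = self._mixture(seed=1)
        cs = pp.run_ica(rec, n_components=3, seed=0, enforce_order=False)
        recon = cs.reconstruct()
        err = (np.linalg.norm(recon - rec.data)
               / np.linalg.norm(rec.data))
        assert err < 1e-6

    def test_determinism(self):
        rec, _ = self._mixture(seed=2)
        a = pp.run_ica(rec, n_components=3, seed=5, enforce_order=False)
        b = pp.run_ica(rec, n_components=3, seed=5, enforce_order=False)
        assert np.allclose(a.unmixing, b.unmixing)
        assert np.allclose(a.sources, b.sources)

    def test_too_many_components_rejected(self):
        rec, _ = self._mixture()
        with pytest.raises(ValueError):
            pp.run_ica(rec, n_components=64, enforce_order=False)

    def test_rank_deficiency_reported(self):
        rec, _ = self._mixture()
        with pytest.raises(ValueError, match="rank"):
            pp.run_ica(rec, n_components=10, enforce_order=False)


@pytest.fixture(scope="module")
def clean_componentset():
    """ICA on a noise-free mu + occipital + blink recording."""
    events = make_event_sequence(24, 24, 4, 2, 2.0, 0.3, seed=3)
    p = SubjectParams(noise_sd=0.0, p60_amp=0.0)
    rec = simulate_eeg(events, p, seed=11)
    rec = pp.bandpass_filter(rec)
    rec = pp.resample(rec, 500.0)
    cs = pp.run_ica(rec, n_components=3, seed=0)
    cs.ground_truth = rec.ground_truth
    cs.source_rate_factor = 2  # ground truth sampled at 1 kHz
    return cs


def _best_match(cs, name):
    from scipy.signal import resample_poly
    gt = resample_poly(cs.ground_truth["sources"][name], 1,
                       cs.source_rate_factor)[:cs.sources.shape[1]]
    cors = [abs(np.corrcoef(cs.sources[i], gt)[0, 1])
            for i in range(cs.n_components)]
    return int(np.argmax(cors)), max(cors)


class TestComponentSelection:
    def test_blink_component_flagged_ocular(self, clean_componentset):
        cs = pp.flag_ocular_components(clean_componentset)
        blink_comp, _ = _best_match(cs, "blink")
        assert cs.ocular[blink_comp]

    def test_unreachable_threshold_flags_nothing(self, clean_componentset):
        cs = pp.flag_ocular_components(clean_componentset,
                                       frontal_ratio=np.inf)
        assert not cs.ocular.any()
        cs.ocular[:] = False

    def test_no_blinks_no_flags(self, small_events):
        p = SubjectParams(noise_sd=1.0, blink_rate=0.0)
        rec = simulate_eeg(small_events, p, seed=21)
        rec = pp.resample(pp.bandpass_filter(rec), 500.0)
        cs = pp.run_ica(rec, n_components=4, seed=0)
        cs = pp.flag_ocular_components(cs)
        assert not cs.ocular.any()

    def test_mu_selected_occipital_rejected(self, clean_componentset):
        cs = pp.flag_ocular_components(clean_componentset)
        cs = pp.select_rolandic_components(cs)
        mu_comp, mu_r = _best_match(cs, "mu")
        occ_comp, occ_r = _best_match(cs, "occ")
        assert mu_r > 0.9 and occ_r > 0.9
        assert cs.rolandic[mu_comp]
        assert not cs.rolandic[occ_comp]

    def test_white_noise_component_fails_spectral_criterion(self):
        rng = np.random.default_rng(3)
        montage = standard_montage()
        from mupulse.events import EventTable
        events = EventTable(onset=np.array([5.0]),
                            kind=np.array(["supra_left"], object),
                            block=np.array([0]),
                            history=np.array(["none"], object))
        cs = pp.ComponentSet(
            unmixing=np.eye(1, montage.n_channels),
            mixing=np.eye(montage.n_channels, 1),
            sources=rng.standard_normal((1, 10000)),
            mean=np.zeros(montage.n_channels), rate=500.0,
            montage=montage, events=events)
        ok, _ = pp._spectral_peaks(cs, 0)
        assert not ok

    def test_selection_monotone_in_thresholds(self, clean_componentset):
        cs = pp.flag_ocular_components(clean_componentset)
        counts = []
        for delta, prom in [(0.05, 0.1), (0.1, 0.2), (0.3, 0.6)]:
            cs.rolandic[:] = False
            cs = pp.select_rolandic_components(cs, prominence_frac=prom,
                                               erd_delta=delta)
            counts.append(int(cs.rolandic.sum()))
        assert counts == sorted(counts, reverse=True)

    def test_no_supra_events_rejected(self, clean_componentset):
        from mupulse.events import EventTable
        empty = EventTable(onset=np.array([]), kind=np.array([], object),
                           block=np.array([], int),
                           history=np.array([], object))
        with pytest.raises(ValueError, match="suprathreshold"):
            pp.select_rolandic_components(clean_componentset,
                                          supra_events=empty)


class TestBackprojection:
    def test_keep_all_is_identity(self, clean_componentset):
        cs = clean_componentset
        rec = pp.backproject(cs, range(cs.n_components))
        recon = cs.reconstruct()
        assert np.allclose(rec.data, recon)

    def test_rolandic_backprojection_recovers_mu_at_c4(
            self, clean_componentset):
        cs = pp.flag_ocular_components(clean_componentset)
        cs = pp.select_rolandic_components(cs)
        keep = np.flatnonzero(cs.rolandic)
        rec = pp.backproject(cs, keep)
        from scipy.signal import resample_poly
        gt = resample_poly(cs.ground_truth["sources"]["mu"], 1,
                           2)[:rec.n_samples]
        r = abs(np.corrcoef(rec.channel("C4"), gt)[0, 1])
        assert r > 0.9

    def test_empty_keep_rejected(self, clean_componentset):
        with pytest.raises(ValueError):
            pp.backproject(clean_componentset, [])

    def test_removing_ocular_never_increases_channel_variance(
            self, clean_componentset):
        cs = pp.flag_ocular_components(clean_componentset)
        if not cs.ocular.any():
            pytest.skip("no ocular component in this decomposition")
        all_idx = np.arange(cs.n_components)
        clean = pp.backproject(cs, all_idx[~cs.ocular])
        full = cs.reconstruct()
        v_full = full.var(axis=1)
        v_clean = clean.data.var(axis=1)
        assert np.all(v_clean <= v_full * (1 + 1e-8))
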