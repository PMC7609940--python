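"""Morlet wavelet analytics, baseline normalization, averaging."""

import numpy as np
import pytest

from mupulse.epochs import EpochSet
from mupulse.params import SubjectParams
from mupulse.simulate import simulate_epochs
from mupulse.tfr import (TFRMap, average_tfr, baseline_normalize,
                         morlet_power)


def _epochs_from(data, rate=500.0, tmin=-0.5, labels=None):
    data = np.atleast_2d(data)
    n_tr = data.shape[0]
    tmax = tmin + data.shape[1] / rate
    labels = (np.array(["none"] * n_tr, object) if labels is None
              else np.asarray(labels, object))
    return EpochSet(data=data[:, None, :], tmin=tmin, tmax=tmax, rate=rate,
                    channels=("C4",), labels=labels)


def _analytic_power(f_wavelet, f_signal, n_cycles=5.0, amp=1.0):
    """Closed-form Morlet power response to a pure sinusoid."""
    sigma = n_cycles / (2 * np.pi * f_wavelet)
    return (amp**2 * sigma * np.sqrt(np.pi) / 2
            * np.exp(-4 * np.pi**2 * sigma**2 * (f_signal - f_wavelet)**2))


class TestMorletAnalytics:
    def test_frequency_response_matches_closed_form(self):
        rate = 500.0
        t = np.arange(int(2.0 * rate)) / rate
        ep = _epochs_from(np.sin(2 * np.pi * 10 * t), rate)
        m = morlet_power(ep, "C4", np.array([10.0, 15.0]))
        p10 = m.power[0, 0, m.mask[1]].mean()
        p15 = m.power[0, 1, m.mask[1]].mean()
        assert p10 == pytest.approx(_analytic_power(10, 10), rel=0.05)
        assert (p15 / p10 == pytest.approx(
            _analytic_power(15, 10) / _analytic_power(10, 10), rel=0.05))
        assert int(np.argmax([p10, p15])) == 0

    def test_impulse_envelope_fwhm_matches_closed_form(self):
        rate = 500.0
        x = np.zeros(int(2.0 * rate))
        x[len(x) // 2] = 1.0
        ep = _epochs_from(x, rate)
        m = morlet_power(ep, "C4", np.array([10.0]))
        amp = np.sqrt(m.power[0, 0])
        fwhm = np.sum(amp >= amp.max() / 2) / rate
        sigma_t = 5.0 / (2 * np.pi * 10.0)
        assert fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma_t,
                                     rel=0.05)

    def test_zero_signal_gives_zero_power(self):
        ep = _epochs_from(np.zeros(1000))
        m = morlet_power(ep, "C4", np.array([10.0]))
        assert np.allclose(m.power, 0.0)

    def test_too_short_epoch_names_limiting_frequency(self):
        ep = _epochs_from(np.zeros(100))
        with pytest.raises(ValueError, match="4"):
            morlet_power(ep, "C4", np.array([4.0, 10.0]))

    def test_shift_equivariance(self):
        rate = 500.0
        rng = np.random.default_rng(0)
        burst = np.zeros(int(3.0 * rate))
        t = np.arange(200) / rate
        burst[500:700] = np.sin(2 * np.pi * 10 * t) * np.hanning(200)
        shift = 150
        shifted = np.roll(burst, shift)
        m0 = morlet_power(_epochs_from(burst, rate), "C4",
                          np.array([10.0]))
        m1 = morlet_power(_epochs_from(shifted, rate), "C4",
                          np.array([10.0]))
        i0 = int(np.argmax(m0.power[0, 0]))
        i1 = int(np.argmax(m1.power[0, 0]))
        assert i1 - i0 == shift

    def test_power_additivity_for_independent_noise(self):
        rng = np.random.default_rng(1)
        n, rate = 1000, 500.0
        a = rng.standard_normal((200, n))
        b = rng.standard_normal((200, n))
        pa = morlet_power(_epochs_from(a, rate), "C4", np.array([10.0]))
        pb = morlet_power(_epochs_from(b, rate), "C4", np.array([10.0]))
        pab = morlet_power(_epochs_from(a + b, rate), "C4",
                           np.array([10.0]))
        va = pa.power[:, 0, pa.mask[0]].mean()
        vb = pb.power[:, 0, pb.mask[0]].mean()
        vab = pab.power[:, 0, pab.mask[0]].mean()
        assert vab == pytest.approx(va + vb, rel=0.1)

    def test_band_power_tracks_squared_envelope(self):
        """Summed 4-30 Hz power correlates with the bandpassed envelope."""
        from scipy import signal as sps
        rate = 500.0
        rng = np.random.default_rng(2)
        env = 1.0 + 0.8 * np.sin(2 * np.pi * 0.5
                                 * np.arange(int(6 * rate)) / rate)
        x = env * np.sin(2 * np.pi * 11 * np.arange(int(6 * rate)) / rate)
        ep = _epochs_from(x, rate)
        m = morlet_power(ep, "C4")
        valid = m.mask.all(axis=0)
        total = m.power[0][:, valid].sum(axis=0)
        sos = sps.butter(3, [4, 30], btype="band", fs=rate, output="sos")
        env2 = np.abs(sps.hilbert(sps.sosfiltfilt(sos, x))) ** 2
        r = np.corrcoef(total, env2[valid])[0, 1]
        assert r > 0.95

    def test_matches_reference_morlet_implementation(self):
        """Cross-check against an established TFR implementation."""
        mne = pytest.importorskip("mne")
        rate = 500.0
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, int(2.0 * rate)))
        freqs = np.array([8.0, 13.0, 21.0])
        ep = _epochs_from(x, rate)
        ours = morlet_power(ep, "C4", freqs)
        ref = mne.time_frequency.tfr_array_morlet(
            x[:, None, :], rate, freqs, n_cycles=5.0, output="power",
            zero_mean=False)
        valid = ours.mask.all(axis=0)
        for fi in range(len(freqs)):
            a = ours.power[:, fi, valid]
            b = ref[:, 0, fi, valid]
            r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
            assert r > 0.999


class TestBaselineNormalize:
    def _flat_map(self, value, baseline_value):
        freqs = np.array([10.0])
        times = np.linspace(-0.2, 0.8, 101)
        power = np.full((1, len(times)), float(value))
        power[0, times < 0] = baseline_value
        return TFRMap(power=power, freqs=freqs, times=times)

    def test_null_change_is_zero(self):
        m = baseline_normalize(self._flat_map(2.0, 2.0), (-0.2, 0.0))
        assert np.allclose(m.power, 0.0)
        assert m.state == "relative_change"

    def test_doubling_gives_plus_one(self):
        m = baseline_normalize(self._flat_map(4.0, 2.0), (-0.2, 0.0))
        assert np.allclose(m.power[0, m.times >= 0], 1.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="zero baseline"):
            baseline_normalize(self._flat_map(1.0, 0.0), (-0.2, 0.0))

    def test_injected_erd_recovered_across_subjects(self):
        """Normalized alpha power in the ERD window ~ erd_gain."""
        vals = []
        for s in range(40):
            p = SubjectParams(erd_gain=-0.3, noise_sd=2.0)
            ep = simulate_epochs({"train": 20}, p, rate=250, tmin=-0.9,
                                 tmax=3.0, seed=100 + s)
            m = morlet_power(ep, "C4", np.arange(8.0, 13.0), decim=5)
            avg = average_tfr(m, "TaS")
            norm = baseline_normalize(avg, (-0.2, 0.0))
            sel = norm.time_mask(0.3, 1.9) & norm.mask.all(axis=0)
            vals.append(norm.power[:, sel].mean())
        assert np.mean(vals) == pytest.approx(-0.3, abs=0.05)


class TestAverageTfr:
    def _trial_map(self, values, labels):
        n = len(values)
        power = np.ones((n, 2, 10)) * np.asarray(values)[:, None, None]
        return TFRMap(power=power, freqs=np.array([10.0, 11.0]),
                      times=np.linspace(0, 1, 10),
                      info={"labels": np.asarray(labels, object)})

    def test_identical_trials_identity(self):
        m = self._trial_map([3.0, 3.0], ["SaS", "SaS"])
        avg = average_tfr(m)
        assert np.allclose(avg.power, 3.0)
        assert avg.n_trials == 2

    def test_all_equals_count_weighted_label_averages(self):
        m = self._trial_map([1.0, 2.0, 6.0], ["SaS", "SaS", "SaT"])
        avg_all = average_tfr(m, "all")
        avg_sas = average_tfr(m, "SaS")
        avg_sat = average_tfr(m, "SaT")
        weighted = (avg_sas.power * 2 + avg_sat.power * 1) / 3
        assert np.allclose(avg_all.power, weighted)

    def test_opposite_gains_give_opposite_sign_changes(self):
        """SaS vs SaT alpha change differs in sign around 0.15-0.35 s."""
        p = SubjectParams(noise_sd=1.0)
        signs = []
        for lbl in ("SaS", "SaT"):
            vals = []
            for s in range(10):
                ep = simulate_epochs({lbl: 40}, p, rate=250, tmin=-0.6,
                                     tmax=1.0, seed=17 + s)
                m = morlet_power(ep, "C4", np.arange(8.0, 13.0), decim=5)
                norm = baseline_normalize(average_tfr(m, lbl), (-0.2, 0.0))
                sel = norm.time_mask(0.15, 0.35) & norm.mask.all(axis=0)
                vals.append(norm.power[:, sel].mean())
            signs.append(np.sign(np.mean(vals)))
        assert signs[0] > 0 > signs[1]

    def test_empty_selection_rejected(self):
        m = self._trial_map([1.0], ["SaS"])
        with pytest.raises(ValueError):
            average_tfr(m, "TaT")
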