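import numpy as np
import pandas as pd
import pytest

from audiencesync import (GroupRecording, Recording, band, instantaneous_phase,
                          plv_pairwise, power_outlier_filter, section_plv,
                          welch_band_power)
from audiencesync.preprocess import bandpass_filter


def sine_rec(freq=2.0, dur=20.0, rate=250.0, n_ch=1, amp=1.0):
    t = np.arange(0, dur, 1 / rate)
    x = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return Recording("S0", [f"ch{i}" for i in range(n_ch)], rate, x)


class TestInstantaneousPhase:
    def test_phase_advances_at_signal_frequency(self):
        rec = sine_rec(freq=2.0)
        theta = np.unwrap(instantaneous_phase(rec)[0])
        core = slice(500, -500)
        slope = np.polyfit(np.arange(len(theta))[core] / 250.0,
                           theta[core], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 2.0, rel=0.01)

    def test_cos_leads_sin_by_quarter_cycle(self):
        t = np.arange(0, 20, 1 / 250)
        rec = Recording("S0", ["sin", "cos"], 250.0,
                        np.stack([np.sin(2 * np.pi * 2 * t),
                                  np.cos(2 * np.pi * 2 * t)]))
        th = instantaneous_phase(rec)
        diff = np.angle(np.exp(1j * (th[1] - th[0])))[500:-500]
        assert np.allclose(diff, np.pi / 2, atol=0.01)

    def test_amplitude_invariance(self):
        th1 = instantaneous_phase(sine_rec(amp=1.0))
        th2 = instantaneous_phase(sine_rec(amp=37.0))
        assert np.allclose(th1, th2, atol=1e-9)

    def test_broadband_input_warns(self):
        rng = np.random.default_rng(0)
        rec = Recording("S0", ["a"], 250.0, rng.standard_normal((1, 5000)))
        with pytest.warns(UserWarning, match="broadband"):
            instantaneous_phase(rec)


class TestPLV:
    def test_identical_phases_unit(self):
        th = 2 * np.pi * 2 * np.arange(2500) / 250
        _, plv = plv_pairwise(th, th, 250.0)
        assert np.allclose(plv, 1.0, atol=1e-12)

    def test_constant_offset_unit(self):
        th = 2 * np.pi * 2 * np.arange(2500) / 250
        _, plv = plv_pairwise(th, th + 1.234, 250.0)
        assert np.allclose(plv, 1.0, atol=1e-12)

    def test_roots_of_unity_vanish(self):
        T = 1250  # one 5 s window at 250 Hz
        diff = 2 * np.pi * np.arange(T) / T
        _, plv = plv_pairwise(diff, np.zeros(T), 250.0)
        assert plv[0] == pytest.approx(0.0, abs=1e-12)

    def test_random_phases_rayleigh_mean(self):
        rng = np.random.default_rng(1)
        T = 1250
        vals = [plv_pairwise(rng.uniform(-np.pi, np.pi, T), np.zeros(T),
                             250.0)[1][0] for _ in range(300)]
        expected = np.sqrt(np.pi) / (2 * np.sqrt(T))
        assert np.mean(vals) == pytest.approx(expected, rel=0.1)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(-np.pi, np.pi, 5000)
        b = rng.uniform(-np.pi, np.pi, 5000)
        _, p1 = plv_pairwise(a, b, 250.0)
        _, p2 = plv_pairwise(b, a, 250.0)
        assert np.allclose(p1, p2)
        assert ((p1 >= 0) & (p1 <= 1)).all()

    def test_masked_window_missing(self):
        th = np.zeros(2500)
        mask = np.zeros(2500, dtype=bool)
        mask[:1000] = True
        _, plv = plv_pairwise(th, th, 250.0, mask_j=mask)
        assert np.isnan(plv[0])
        assert plv[-1] == pytest.approx(1.0)

    def test_window_grid_count(self):
        th = np.zeros(250 * 60)
        times, plv = plv_pairwise(th, th, 250.0, window=5.0, hop=1.0)
        assert len(plv) == 56


class TestSectionPLV:
    @pytest.mark.parametrize("n_subjects,n_pairs", [(20, 190), (18, 153),
                                                    (21, 210)])
    def test_audience_pair_counts(self, n_subjects, n_pairs):
        rng = np.random.default_rng(3)
        t = np.arange(0, 12, 1 / 250)
        recs = []
        for i in range(n_subjects):
            x = np.sin(2 * np.pi * 2 * t + rng.uniform(0, 2 * np.pi))
            recs.append(Recording(f"S{i}", ["C3"], 250.0, x[None, :]))
        group = GroupRecording(recs, aligned=True)
        df = section_plv(group, {"sec": (0.0, 12.0)}, electrodes=("C3",))
        assert df["pair"].nunique() == n_pairs

    def test_unknown_electrode_rejected(self):
        g = GroupRecording([sine_rec(), sine_rec()], aligned=True)
        with pytest.raises(ValueError):
            section_plv(g, {"s": (0.0, 5.0)}, electrodes=("Oz",))

    def test_short_section_empty(self):
        recs = [sine_rec(n_ch=1), sine_rec(n_ch=1)]
        for r in recs:
            r.channel_labels = ["C3"]
        g = GroupRecording(recs, aligned=True)
        df = section_plv(g, {"tiny": (0.0, 2.0)}, electrodes=("C3",))
        assert df.empty


class TestWelchPower:
    def test_matches_manual_four_segment_welch(self):
        # a 4 s section at 250 Hz holds exactly 4 overlapping 1 s segments;
        # reproduce Welch by hand from those segments
        rng = np.random.default_rng(8)
        x = rng.standard_normal(1000)
        rec = Recording("S0", ["a"], 250.0, x[None, :])
        from scipy.signal import get_window, welch
        w = get_window("hann", 250)
        scale = 1.0 / (250.0 * (w * w).sum())
        psds = []
        for k in range(4):
            seg = x[k * 200:k * 200 + 250]
            seg = (seg - seg.mean()) * w
            spec = np.abs(np.fft.rfft(seg)) ** 2 * scale
            spec[1:-1] *= 2
            psds.append(spec)
        manual = np.mean(psds, axis=0)
        f, ref = welch(x, fs=250.0, window="hann", nperseg=250, noverlap=50)
        assert np.allclose(manual, ref, rtol=1e-8)
        b = band("alpha")
        sel = (f >= b.low) & (f <= b.high)
        assert welch_band_power(rec, b) == pytest.approx(manual[sel].mean())

    def test_white_noise_psd_integrates_to_variance(self):
        rng = np.random.default_rng(4)
        from scipy.signal import welch
        f, psd = welch(rng.standard_normal(50000), fs=250.0, window="hann",
                       nperseg=250, noverlap=50)
        assert np.trapezoid(psd, f) == pytest.approx(1.0, rel=0.05)

    def test_alpha_sine_concentrates_in_alpha(self):
        rec = sine_rec(freq=10.0, dur=60.0)
        alpha = welch_band_power(rec, band("alpha"))
        delta = welch_band_power(rec, band("delta"))
        assert alpha / delta > 100

    def test_short_section_rejected(self):
        with pytest.raises(ValueError):
            welch_band_power(sine_rec(), band("alpha"), section=(0.0, 0.5))


class TestPowerOutlierFilter:
    def test_homogeneous_keeps_all(self):
        df = pd.DataFrame({"power": np.random.default_rng(5).uniform(1, 2, 20)})
        out, dropped = power_outlier_filter(df)
        assert dropped == 0
        assert len(out) == 20

    def test_extreme_row_dropped(self):
        p = np.concatenate([np.random.default_rng(6).normal(1.0, 0.05, 30),
                            [50.0]])
        out, dropped = power_outlier_filter(pd.DataFrame({"power": p}))
        assert dropped == 1
        assert out["power"].max() < 10

    def test_idempotent(self):
        p = np.concatenate([np.random.default_rng(7).normal(1.0, 0.05, 30),
                            [50.0]])
        once, _ = power_outlier_filter(pd.DataFrame({"power": p}))
        twice, dropped = power_outlier_filter(once)
        assert dropped == 0
        pd.testing.assert_frame_equal(once, twice)
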