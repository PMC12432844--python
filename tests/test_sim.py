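import collections

import numpy as np
import pytest

from audiencesync import (SimConfig, WindowGrid, fit_cca, granger_scan,
                          isc_timecourse, pooled_covariances,
                          simulate_audience, simulate_coupled_series,
                          simulate_features, simulate_photoresistor,
                          simulate_respiration)
from audiencesync.align import detect_light_onset


class TestConfigValidation:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_subjects=1)
        with pytest.raises(ValueError):
            SimConfig(duration=-5.0)
        with pytest.raises(ValueError):
            SimConfig(snr=-1.0)
        with pytest.raises(ValueError):
            SimConfig(sample_rate=6.0)  # delta band reaches Nyquist
        with pytest.raises(ValueError):
            SimConfig(duration=10.33)  # non-integer sample count
        with pytest.raises(ValueError):
            SimConfig(n_subjects=3, device_offsets=[0.0, 0.1])


class TestDeterminism:
    def test_fixed_seed_bit_identical(self):
        cfg = dict(n_subjects=3, n_channels=4, sample_rate=100.0,
                   duration=30.0, seed=5)
        g1, t1 = simulate_audience(SimConfig(**cfg))
        g2, t2 = simulate_audience(SimConfig(**cfg))
        for a, b in zip(g1.recordings, g2.recordings):
            assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(t1.gain, t2.gain)
        assert np.array_equal(t1.mixing, t2.mixing)
        f1 = simulate_features(SimConfig(**cfg), t1)
        f2 = simulate_features(SimConfig(**cfg), t2)
        assert np.array_equal(f1["coupled"].values, f2["coupled"].values)

    def test_different_seeds_differ(self):
        g1, _ = simulate_audience(SimConfig(n_subjects=2, n_channels=2,
                                            duration=10.0, seed=1))
        g2, _ = simulate_audience(SimConfig(n_subjects=2, n_channels=2,
                                            duration=10.0, seed=2))
        assert not np.allclose(g1.recordings[0].samples,
                               g2.recordings[0].samples)


class TestSignalStructure:
    def test_noise_only_variance_matches_configuration(self):
        # snr = 0 leaves pure spatially correlated noise of unit variance
        cfg = SimConfig(n_subjects=2, n_channels=8, sample_rate=250.0,
                        duration=600.0, snr=0.0, artifact_rate=0.0, seed=3)
        group, _ = simulate_audience(cfg)
        var = group.recordings[0].samples.var(axis=1)
        assert np.allclose(var, 1.0, rtol=0.05)

    def test_noise_spatial_correlation_near_target(self):
        cfg = SimConfig(n_subjects=2, n_channels=8, sample_rate=250.0,
                        duration=300.0, snr=0.0, artifact_rate=0.0, seed=4)
        group, _ = simulate_audience(cfg)
        c = np.corrcoef(group.recordings[0].samples)
        off = c[~np.eye(8, dtype=bool)]
        assert off.mean() == pytest.approx(0.3, abs=0.05)

    def test_mixing_rows_unit_norm(self):
        _, truth = simulate_audience(SimConfig(n_subjects=4, n_channels=6,
                                               duration=10.0, seed=6))
        assert np.allclose(np.linalg.norm(truth.mixing, axis=1), 1.0)

    def test_identical_subjects_limit(self):
        cfg = SimConfig(n_subjects=3, n_channels=4, sample_rate=100.0,
                        duration=150.0, noise_scale=0.0, mixing_jitter=0.0,
                        gain_profile="constant", artifact_rate=0.0, seed=7)
        group, _ = simulate_audience(cfg)
        a = group.recordings[0].samples
        for r in group.recordings[1:]:
            assert np.allclose(r.samples, a)
        # noise-free identical subjects leave Rw rank-1, so the fit needs
        # shrinkage; the ISC value itself uses the raw covariances
        Rw, Rb = pooled_covariances(group)
        model = fit_cca(Rw, Rb, 3, reg=0.1)
        s = isc_timecourse(group, model, WindowGrid(), band="delta")[0]
        assert np.allclose(s.values, 1.0, atol=1e-9)

    def test_artifacts_land_where_reported(self):
        cfg = SimConfig(n_subjects=2, n_channels=4, sample_rate=250.0,
                        duration=60.0, snr=0.0, artifact_rate=10.0,
                        artifact_scale=8.0, seed=8)
        group, truth = simulate_audience(cfg)
        assert truth.artifact_times, "expected artifact events"
        k, t0 = truth.artifact_times[0]
        x = group.recordings[k].samples
        i0 = int(round(t0 * 250))
        assert np.abs(x[:, i0:i0 + 50]).max() > 4 * x.std()

    def test_snr_increases_subject_correlation(self):
        def mean_cross_corr(snr, seed):
            cfg = SimConfig(n_subjects=3, n_channels=4, sample_rate=100.0,
                            duration=120.0, snr=snr, gain_profile="constant",
                            artifact_rate=0.0, seed=seed)
            g, truth = simulate_audience(cfg)
            y = [truth.mixing[k] @ g.recordings[k].samples for k in range(3)]
            cs = [abs(np.corrcoef(y[a], y[b])[0, 1])
                  for a in range(3) for b in range(a + 1, 3)]
            return np.mean(cs)

        levels = [np.mean([mean_cross_corr(s, seed) for seed in range(3)])
                  for s in (0.0, 0.5, 1.0, 2.0)]
        assert all(np.diff(levels) > 0)


class TestFeatures:
    def test_coupled_feature_leads_gain(self):
        # a gain with structure at the few-second scale makes the planted
        # lag identifiable by cross-correlation (the slow default is too
        # smooth to distinguish neighbouring shifts)
        gain = lambda t: 0.5 + 0.5 * np.sin(2 * np.pi * t / 40.0)
        cfg = SimConfig(n_subjects=2, n_channels=2, duration=600.0,
                        gain_profile=gain,
                        coupling_lag=3.0, coupling_beta=1.0, seed=9)
        _, truth = simulate_audience(cfg)
        feats = simulate_features(cfg, truth, n_independent=2)
        f = feats["coupled"].values
        g = truth.gain
        # gain(t) ~ beta * f(t - lag): aligning f back by 3 s maximises r
        def corr_at(shift):
            return np.corrcoef(g[shift:], f[:len(f) - shift])[0, 1]

        corrs = {s: corr_at(s) for s in range(0, 7)}
        assert max(corrs, key=corrs.get) == 3
        assert corrs[3] > 0.9
        assert len(feats) == 3

    def test_lag_must_fit_duration(self):
        cfg = SimConfig(n_subjects=2, n_channels=2, duration=10.0,
                        coupling_lag=20.0, seed=0)
        _, truth = simulate_audience(cfg)
        with pytest.raises(ValueError):
            simulate_features(cfg, truth)

    def test_planted_lag_recovered_modally(self):
        # over 20 seeds with randomly drawn planted lags, the modal minimal
        # significant Granger lag equals the planted one
        rng = np.random.default_rng(0)
        results = []
        for s in range(20):
            lag = int(rng.integers(2, 9))
            outcome, preds = simulate_coupled_series(n=600, lag=lag, beta=1.0,
                                                     seed=100 + s)
            scan = granger_scan(outcome, preds)
            found = scan.min_significant_lag("x1")
            results.append(found == lag)
        assert sum(results) >= 15
        mode = collections.Counter(results).most_common(1)[0][0]
        assert mode is True


class TestPhotoresistorAndRespiration:
    def test_blackout_onset_recovered(self):
        cfg = SimConfig(n_subjects=3, n_channels=2, sample_rate=250.0,
                        duration=60.0, device_offsets=[0.0, 0.2, -0.1],
                        seed=10)
        traces = simulate_photoresistor(cfg)
        onsets = [detect_light_onset(t, 250.0).time for t in traces]
        expected = [15.0, 15.2, 14.9]
        # kink localisation under sensor noise carries a few samples of spread
        assert np.allclose(onsets, expected, atol=4 / 250)

    def test_zero_noise_zero_offsets_exact(self):
        cfg = SimConfig(n_subjects=2, n_channels=2, sample_rate=250.0,
                        duration=60.0, seed=11)
        traces = simulate_photoresistor(cfg, noise_sd=0.0)
        onsets = [detect_light_onset(t, 250.0).time for t in traces]
        assert onsets[0] == pytest.approx(onsets[1], abs=1e-12)
        assert onsets[0] == pytest.approx(15.0, abs=1 / 250)

    def test_respiration_shares_common_rhythm(self):
        cfg = SimConfig(n_subjects=4, n_channels=2, duration=120.0, seed=12)
        traces = simulate_respiration(cfg, rate=500.0)
        c = np.corrcoef(np.stack(traces))
        off = c[~np.eye(4, dtype=bool)]
        assert off.mean() > 0.3
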