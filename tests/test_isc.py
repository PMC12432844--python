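import numpy as np
import pytest

from audiencesync import (GroupRecording, Recording, SimConfig, WindowGrid,
                          explained_covariance, fit_cca, isc_timecourse,
                          pooled_covariances, simulate_audience)
from conftest import make_identical_group, make_independent_group


def brute_force_isc1(Rw, Rb, n_subjects, step_deg=1.0):
    """Grid maximisation of the between/within ratio over 2-D unit vectors."""
    th = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    vs = np.stack([np.cos(th), np.sin(th)])
    num = np.einsum("ct,cd,dt->t", vs, Rb, vs)
    den = (n_subjects - 1) * np.einsum("ct,cd,dt->t", vs, Rw, vs)
    return (num / den).max()


class TestPooledCovariances:
    def test_identical_subjects_between_equals_scaled_within(self):
        g = make_identical_group(n_subjects=5)
        Rw, Rb = pooled_covariances(g)
        assert np.allclose(Rb, (5 - 1) * Rw)

    def test_two_subjects_between_is_cross_term(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.standard_normal((2, 3, 2000))
        labels = ["a", "b", "c"]
        g = GroupRecording([Recording("S1", labels, 250.0, x1),
                            Recording("S2", labels, 250.0, x2)], aligned=True)
        Rw, Rb = pooled_covariances(g)
        c1 = (x1 - x1.mean(1, keepdims=True))
        c2 = (x2 - x2.mean(1, keepdims=True))
        r12 = c1 @ c2.T / (2000 - 1)
        assert np.allclose(Rb, ((r12 + r12.T) + (r12 + r12.T).T) / 2)
        assert np.allclose(Rw, (c1 @ c1.T + c2 @ c2.T) / (2000 - 1))

    def test_independent_subjects_between_vanishes(self):
        g = make_independent_group(n_subjects=6, n_samples=60000)
        Rw, Rb = pooled_covariances(g)
        assert np.linalg.norm(Rb) / np.linalg.norm(Rw) < 0.05

    def test_masked_and_unmasked_paths_agree(self):
        g = make_independent_group(n_subjects=3, n_samples=4000)
        Rw0, Rb0 = pooled_covariances(g)
        # an all-false mask must not change the result
        for r in g.recordings:
            r.mask = np.zeros_like(r.samples, dtype=bool)
        g.recordings[0].mask[0, 5] = True  # force the masked code path
        Rw1, Rb1 = pooled_covariances(g)
        # the paths differ only in mean convention (global vs pairwise),
        # which perturbs entries at the 1e-3 level here
        assert np.allclose(Rw0, Rw1, rtol=1e-2, atol=2e-3)
        assert np.abs(Rb0 - Rb1).max() < 0.01

    def test_empty_span_rejected(self):
        g = make_identical_group()
        with pytest.raises(ValueError):
            pooled_covariances(g, span=(100.0, 200.0))


class TestFitCCA:
    def test_identical_subjects_unit_isc(self):
        g = make_identical_group(n_subjects=5)
        Rw, Rb = pooled_covariances(g)
        model = fit_cca(Rw, Rb, 5, reg=0.0)
        assert model.isc[0] == pytest.approx(1.0, abs=1e-9)

    def test_independent_subjects_low_isc(self):
        g = make_independent_group(n_subjects=6, n_samples=150000)
        Rw, Rb = pooled_covariances(g)
        model = fit_cca(Rw, Rb, 6, reg=0.0)
        assert model.isc[0] <= 0.05

    def test_matches_brute_force_on_two_channels(self):
        Rw = np.array([[2.0, 0.3], [0.3, 1.0]])
        Rb = np.array([[1.0, 0.5], [0.5, 0.8]])
        model = fit_cca(Rw, Rb, 10, reg=0.0)
        assert model.isc[0] == pytest.approx(
            brute_force_isc1(Rw, Rb, 10), abs=1e-4)

    def test_dominates_random_weight_vectors(self):
        g = make_independent_group(n_subjects=4, n_samples=20000)
        Rw, Rb = pooled_covariances(g)
        model = fit_cca(Rw, Rb, 4, reg=0.0)
        rng = np.random.default_rng(9)
        v = rng.standard_normal((4, 1000))
        v /= np.linalg.norm(v, axis=0)
        ratios = np.einsum("ct,cd,dt->t", v, Rb, v) / (
            3 * np.einsum("ct,cd,dt->t", v, Rw, v))
        assert model.isc[0] >= ratios.max() - 1e-9

    def test_isc_invariant_to_common_scaling(self):
        g = make_independent_group(n_subjects=4, n_samples=10000)
        Rw, Rb = pooled_covariances(g)
        m1 = fit_cca(Rw, Rb, 4, reg=0.0)
        scale = np.diag([2.0, 0.5, 3.0, 1.0])
        m2 = fit_cca(scale @ Rw @ scale, scale @ Rb @ scale, 4, reg=0.0)
        assert np.allclose(m1.isc, m2.isc, atol=1e-9)

    def test_invalid_inputs_rejected(self):
        Rw = np.eye(2)
        with pytest.raises(ValueError):
            fit_cca(Rw, np.array([[np.nan, 0], [0, 1.0]]), 3)
        with pytest.raises(ValueError):
            fit_cca(Rw, Rw, 3, reg=-0.1)
        with pytest.raises(ValueError):
            fit_cca(-np.eye(2), Rw, 3)


class TestTimecourse:
    def test_window_count_arithmetic(self):
        grid = WindowGrid(length=5.0, hop=1.0)
        assert grid.n_windows(60.0) == 56

    def test_identical_subjects_unit_everywhere(self):
        g = make_identical_group(n_subjects=4, n_samples=5000)
        Rw, Rb = pooled_covariances(g)
        model = fit_cca(Rw, Rb, 4, reg=0.0)
        s = isc_timecourse(g, model, WindowGrid(), band="delta")[0]
        assert np.allclose(s.values, 1.0, atol=1e-9)
        assert s.name == "C1_delta"

    def test_masked_window_missing(self):
        g = make_identical_group(n_subjects=4, n_samples=5000, rate=250.0)
        for r in g.recordings:
            r.mask = np.zeros_like(r.samples, dtype=bool)
        g.recordings[0].mask[:, :1000] = True  # first 4 s fully masked
        Rw, Rb = pooled_covariances(g)
        model = fit_cca(Rw, Rb, 4, reg=0.0)
        s = isc_timecourse(g, model, WindowGrid(), band="delta")[0]
        assert np.isnan(s.values[0])          # window 0: 80 % masked
        assert np.isfinite(s.values[5:]).all()

    def test_gain_step_raises_second_half(self):
        def step(t):
            return np.where(t < 100.0, 0.0, 1.0)

        wins = []
        for seed in range(5):
            cfg = SimConfig(n_subjects=5, n_channels=4, sample_rate=100.0,
                            duration=200.0, snr=1.5, gain_profile=step,
                            artifact_rate=0.0, seed=seed)
            g, _ = simulate_audience(cfg)
            Rw, Rb = pooled_covariances(g)
            model = fit_cca(Rw, Rb, 5)
            s = isc_timecourse(g, model, WindowGrid(), band="delta")[0]
            half = len(s.values) // 2
            wins.append(np.median(s.values[half:]) > np.median(s.values[:half]))
        assert all(wins)

    def test_window_aggregate_consistent_with_full_span(self):
        # with no masking, sample-weighted window variances of the projected
        # series reconstruct the full-span statistics up to window-mean terms
        g = make_independent_group(n_subjects=4, n_samples=50000)
        Rw, Rb = pooled_covariances(g)
        model = fit_cca(Rw, Rb, 4, reg=0.0)
        v = model.weights[:, 0]
        grid = WindowGrid(length=5.0, hop=5.0)
        X = g.data()
        y = np.einsum("c,kct->kt", v, X)
        win_vars = []
        for sl in grid.sample_slices(g.duration, g.sample_rate):
            w = y[:, sl]
            win_vars.append(w.var(axis=1, ddof=1).sum())
        assert np.mean(win_vars) == pytest.approx(
            float(v @ Rw @ v), rel=0.02)


class TestExplainedCovariance:
    def test_degenerate_and_uniform_cases(self):
        from audiencesync.isc import CCAModel
        base = dict(weights=np.eye(4), forward_models=np.eye(4),
                    Rw=np.eye(4), Rb=np.eye(4), n_subjects=5)
        single = CCAModel(isc=np.array([0.4, 0.0, 0.0, 0.0]), **base)
        assert explained_covariance(single)[0] == pytest.approx(100.0)
        equal = CCAModel(isc=np.full(4, 0.2), **base)
        assert np.allclose(explained_covariance(equal), 25.0)
        mixed = CCAModel(isc=np.array([0.5, 0.3, -0.2, 0.1]), **base)
        assert explained_covariance(mixed).sum() == pytest.approx(100.0)
        with pytest.raises(ValueError):
            explained_covariance(CCAModel(isc=np.array([-1.0, -2, -3, -4]),
                                          **base))
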