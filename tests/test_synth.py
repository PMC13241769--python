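"""Synthetic cohort generator: signal primitives and ground-truth structure."""

import numpy as np
import pytest
from scipy.signal import hilbert

from netsig import connectivity, io, spectral, synth
from netsig.errors import ParameterError


def _fit_exponent(x, fs=256.0):
    rec = io.Recording(np.vstack([x, np.zeros_like(x) + 1e-6]), fs,
                       ["a", "b"])
    spec = spectral.welch_psd(rec)
    return spectral.fit_aperiodic(spec).exponent[0]


class TestAperiodicNoise:
    def test_white_noise_flat_slope(self):
        x = synth.gen_aperiodic_noise(0.0, 0.0, 120.0, 256.0, seed=0)
        assert abs(_fit_exponent(x)) < 0.1

    def test_steep_slope_recovered(self):
        errs = [_fit_exponent(
            synth.gen_aperiodic_noise(-2.0, -0.5, 120.0, 256.0, seed=s)) + 2.0
            for s in range(8)]
        assert abs(np.mean(errs)) < 0.15

    def test_offset_sets_absolute_level(self):
        x = synth.gen_aperiodic_noise(-1.0, 0.5, 120.0, 256.0, seed=1)
        rec = io.Recording(np.vstack([x, x]), 256.0, ["a", "b"])
        fit = spectral.fit_aperiodic(spectral.welch_psd(rec))
        assert abs(fit.offset[0] - 0.5) < 0.1

    def test_seed_reproducibility(self):
        a = synth.gen_aperiodic_noise(-1.5, 0.0, 10.0, 256.0, seed=3)
        b = synth.gen_aperiodic_noise(-1.5, 0.0, 10.0, 256.0, seed=3)
        assert np.array_equal(a, b)

    def test_positive_exponent_rejected(self):
        with pytest.raises(ParameterError):
            synth.gen_aperiodic_noise(0.5, 0.0, 1.0, 256.0)


class TestOscillation:
    def test_power_concentrated_in_band(self):
        x = synth.gen_oscillation(10.0, 2.0, 1.0, 120.0, 256.0, seed=0)
        rec = io.Recording(np.vstack([x, x]), 256.0, ["a", "b"])
        spec = spectral.welch_psd(rec)
        total = np.trapezoid(spec.psd[0], spec.freqs)
        sel = (spec.freqs >= 8) & (spec.freqs <= 12)
        inband = np.trapezoid(spec.psd[0, sel], spec.freqs[sel])
        assert inband / total >= 0.90

    def test_target_rms_amplitude(self):
        x = synth.gen_oscillation(10.0, 2.0, 5.0, 60.0, 256.0, seed=1)
        assert np.sqrt(np.mean(x ** 2)) == pytest.approx(5.0, rel=1e-9)

    def test_zero_amplitude_zero_series(self):
        x = synth.gen_oscillation(10.0, 2.0, 0.0, 5.0, 256.0, seed=0)
        assert np.all(x == 0)

    def test_phase_offset_constant_lag(self):
        x = synth.gen_oscillation(10.0, 2.0, 1.0, 120.0, 256.0, seed=4)
        xr = synth.gen_oscillation(10.0, 2.0, 1.0, 120.0, 256.0, seed=4,
                                   phase_offset=np.pi / 4)
        dp = np.angle(hilbert(x) * np.conj(hilbert(xr)))
        mean_lag = np.angle(np.mean(np.exp(1j * dp)))
        assert abs(mean_lag - np.pi / 4) < 0.05


class TestZeroLagMixing:
    def test_identity_unchanged(self, rng):
        data = rng.normal(0, 1, (3, 100))
        assert np.array_equal(synth.mix_zero_lag(data, np.eye(3)), data)

    def test_permutation_relabels(self, rng):
        data = rng.normal(0, 1, (3, 100))
        P = np.eye(3)[[2, 0, 1]]
        assert np.array_equal(synth.mix_zero_lag(data, P), data[[2, 0, 1]])

    def test_singular_matrix_rejected(self, rng):
        data = rng.normal(0, 1, (2, 50))
        with pytest.raises(ParameterError):
            synth.mix_zero_lag(data, np.ones((2, 2)))

    def test_mixing_creates_amplitude_not_phase_coupling(self):
        u = np.array([
            synth.gen_oscillation(10, 2, 1.0, 180.0, 256.0, seed=20),
            synth.gen_oscillation(10, 2, 1.0, 180.0, 256.0, seed=21)])
        m = synth.mix_zero_lag(u, np.array([[1.0, 0.5], [0.5, 1.0]]))
        rec = io.Recording(m, 256.0, ["a", "b"])
        cm = connectivity.wpli(connectivity.cross_spectra(rec), (8, 12))
        assert cm.matrix[0, 1] <= 0.1


class TestCoupling:
    def _coupled_recording(self, strength, lag, duration=180.0):
        spec = synth.CouplingSpec(band=(8.0, 12.0), edges=[(0, 1)],
                                  lags={(0, 1): lag}, strength=strength)
        rng = np.random.default_rng(9)
        sig = synth._coupled_band_signals(spec, 4, duration, 256.0, rng)
        return io.Recording(5.0 * sig, 256.0, ["a", "b", "c", "d"])

    def test_full_strength_pair_saturates_wpli(self):
        rec = self._coupled_recording(1.0, np.pi / 4)
        cm = connectivity.wpli(connectivity.cross_spectra(rec), (8, 12))
        assert cm.matrix[0, 1] >= 0.95

    def test_strong_coupling_detectable_others_floor(self):
        rec = self._coupled_recording(0.8, np.pi / 3)
        cm = connectivity.wpli(connectivity.cross_spectra(rec), (8, 12))
        assert cm.matrix[0, 1] >= 0.6
        others = [cm.matrix[i, j] for i in range(4) for j in range(i + 1, 4)
                  if (i, j) != (0, 1)]
        assert max(others) <= 0.2

    def test_simple_graph_invariants(self):
        with pytest.raises(ParameterError):
            synth.CouplingSpec(band=(2, 4), edges=[(0, 0)], lags={},
                               strength=0.5)
        with pytest.raises(ParameterError):
            synth.CouplingSpec(band=(2, 4), edges=[(0, 1), (1, 0)],
                               lags={}, strength=0.5)

    def test_degree_balanced_weights_equalize_edges(self):
        edges = [(0, 1), (0, 2), (0, 3), (0, 4), (4, 5)]
        w = synth._edge_source_weights(edges, 6)
        amps = [w[i][(i, j)] * w[j][(i, j)] for i, j in edges]
        assert np.ptp(amps) < 0.02
        for c, ws in w.items():
            assert sum(v ** 2 for v in ws.values()) <= 1.0 + 1e-9


class TestCohort:
    def test_fixed_seed_bitwise_reproducible(self):
        cfg = synth.CohortConfig(n_per_group=2, duration=8.0, seed=5)
        r1, c1, t1 = synth.gen_cohort(cfg)
        r2, c2, t2 = synth.gen_cohort(cfg)
        assert all(np.array_equal(a.data, b.data) for a, b in zip(r1, r2))
        assert c1.equals(c2)

    def test_cohort_extensible_without_reshuffling(self):
        small = synth.CohortConfig(n_per_group=2, duration=8.0, seed=5)
        big = synth.CohortConfig(n_per_group=3, duration=8.0, seed=5)
        r1, c1, _ = synth.gen_cohort(small)
        r2, c2, _ = synth.gen_cohort(big)
        assert np.array_equal(r1[0].data, r2[0].data)          # group A
        assert np.array_equal(r1[2].data, r2[3].data)          # group B

    def test_ground_truth_covers_all_subjects(self, mini_cohort):
        cfg, recordings, clinical, truth = mini_cohort
        assert len(truth) == len(recordings) == 2 * cfg.n_per_group
        assert set(truth["subject_id"]) == set(clinical["subject_id"])
        assert clinical["outcome"].sum() == cfg.n_per_group

    def test_exponent_delta_recovered_without_oscillations(self):
        # spectral-only cohort: oscillation amplitudes zero, so the
        # generative exponent contrast is recovered by the fit
        ga = synth.GroupSpec(exponent=-1.9, offset=0.0, amp_delta=0.0,
                             amp_alpha=0.0, amp_theta=0.0, topology="lattice")
        gb = synth.GroupSpec(exponent=-1.5, offset=0.0, amp_delta=0.0,
                             amp_alpha=0.0, amp_theta=0.0,
                             topology="integrated")
        cfg = synth.CohortConfig(n_per_group=8, duration=60.0, seed=2,
                                 group_a=ga, group_b=gb, coupling_fraction=0.2,
                                 mixing_spread=0.0, exponent_sd=0.02)
        recs, clin, truth = synth.gen_cohort(cfg)
        fitted = []
        for rec in recs:
            spec = spectral.welch_psd(rec)
            fitted.append(spectral.fit_aperiodic(spec).exponent_global)
        fitted = np.array(fitted)
        delta = fitted[:8].mean() - fitted[8:].mean()
        assert delta == pytest.approx(-0.4, abs=0.1)

    def test_null_cohort_groups_indistinguishable(self):
        # identical group specs: spectral features must not separate the
        # groups more often than chance
        from netsig import stats

        g = synth.GroupSpec(exponent=-1.6, offset=0.4, amp_delta=3.0,
                            amp_alpha=5.0, amp_theta=2.0, topology="lattice")
        hits = 0
        runs = 20
        for s in range(runs):
            cfg = synth.CohortConfig(n_per_group=5, duration=20.0, seed=100 + s,
                                     group_a=g, group_b=g)
            recs, clin, truth = synth.gen_cohort(cfg)
            vals = []
            for rec in recs:
                spec = spectral.welch_psd(rec)
                bp = spectral.band_relative_power(spec)
                vals.append(bp.global_["delta"])
            p = stats.permutation_test(vals[:5], vals[5:], n_perm=500,
                                       seed=s).p
            hits += p <= 0.05
        assert hits <= 2  # >= 90% of null runs non-significant
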