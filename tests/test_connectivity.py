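import numpy as np
import pytest

from pecnet.connectivity import (PecMatrix, analytic_signal, features_table,
                                 log_power_envelope, orthogonalize,
                                 pec_matrix, pec_pair,
                                 raw_envelope_correlation, roi_aggregate)

FS = 256.0


class TestAnalyticSignal:
    def test_unit_tone_has_unit_envelope(self):
        t = np.arange(4096) / FS
        z = analytic_signal(np.cos(2 * np.pi * 10 * t))
        interior = slice(64, -64)
        assert np.allclose(np.abs(z)[interior], 1.0, atol=0.01)

    def test_hilbert_pair_cos_to_sin(self):
        t = np.arange(4096) / FS
        z = analytic_signal(np.cos(2 * np.pi * 10 * t))
        interior = slice(64, -64)
        assert np.max(np.abs(z.imag - np.sin(2 * np.pi * 10 * t))[interior]) < 0.01

    def test_am_tone_recovers_modulator(self):
        t = np.arange(8192) / FS
        a = 1.5 + np.sin(2 * np.pi * 0.5 * t)  # slow positive modulator
        z = analytic_signal(a * np.cos(2 * np.pi * 20 * t))
        interior = slice(256, -256)
        rel = np.abs(np.abs(z)[interior] - a[interior]) / a[interior]
        assert np.max(rel) < 0.02

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            analytic_signal(np.zeros(16))


class TestOrthogonalize:
    def test_real_multiple_gives_zero(self, rng):
        x = rng.standard_normal(100) + 1j * rng.standard_normal(100)
        assert np.allclose(orthogonalize(2.5 * x, x), 0.0, atol=1e-12)

    def test_quadrature_gives_magnitude(self, rng):
        x = rng.standard_normal(100) + 1j * rng.standard_normal(100)
        assert np.allclose(orthogonalize(1j * x, x), np.abs(x))

    def test_unit_reference_extracts_imaginary_part(self, rng):
        a, b = rng.standard_normal((2, 50))
        y = a + 1j * b
        x = np.ones(50, dtype=complex)
        assert np.allclose(orthogonalize(y, x), b)


class TestLogPowerEnvelope:
    def test_unit_magnitude_gives_zero(self):
        z = np.exp(1j * np.linspace(0, 10, 500))
        assert np.max(np.abs(log_power_envelope(z))) < 1e-6

    def test_magnitude_e_gives_two(self):
        z = np.e * np.exp(1j * np.linspace(0, 10, 500))
        assert np.allclose(log_power_envelope(z), 2.0, atol=1e-6)

    def test_scaling_shifts_by_2log(self, rng):
        z = rng.standard_normal(300) + 1j * rng.standard_normal(300)
        shift = log_power_envelope(7.0 * z) - log_power_envelope(z)
        assert np.allclose(shift, 2 * np.log(7.0), atol=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            log_power_envelope(np.zeros(100, dtype=complex))


class TestPecPair:
    def test_planted_rho_recovered(self, coupled_pair_factory):
        vals = []
        for seed in range(8):
            src, _ = coupled_pair_factory(0.5, seed)
            z = analytic_signal(src, axis=-1)
            vals.append(pec_pair(z[0], z[1], FS))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_zero_lag_duplicate_suppressed(self, coupled_pair_factory):
        """A gain-scaled duplicate (pure volume conduction) has PEC 0 while
        its raw envelope correlation is 1."""
        src, _ = coupled_pair_factory(0.0, 3, duration=20.0)
        z = analytic_signal(src[0], axis=-1)
        assert pec_pair(z, 3.0 * z, FS) == 0.0
        assert raw_envelope_correlation(z, 3.0 * z, FS) == pytest.approx(1.0)

    def test_independent_nodes_near_zero(self, coupled_pair_factory):
        vals = []
        for seed in range(6):
            src, _ = coupled_pair_factory(0.0, 50 + seed)
            z = analytic_signal(src, axis=-1)
            vals.append(pec_pair(z[0], z[1], FS))
        assert abs(np.mean(vals)) < 0.05

    def test_constant_envelope_reference_gives_nan(self):
        t = np.arange(2048) / FS
        z_const = analytic_signal(np.cos(2 * np.pi * 10 * t))
        rng = np.random.default_rng(0)
        z_noise = analytic_signal(rng.standard_normal(2048))
        out = pec_pair(z_const, z_noise, FS, env_lowpass=None)
        # tone envelope is (numerically) constant: correlation undefined
        assert np.isnan(out) or abs(out) < 0.2


def test_common_source_leakage_suppression(coupled_pair_factory):
    """Two noisy views of one source: per-sample PEC stays below 0.1 on
    average while the raw envelope correlation stays high; the smoothed
    estimator retains a bounded residual bias (see methods note)."""
    from pecnet.preprocess import bandpass
    pec_raw_sm, pec_raw_ps, raws = [], [], []
    for seed in range(10):
        src, _ = coupled_pair_factory(0.0, 80 + seed, duration=40.0)
        x = src[0]
        noise = np.random.default_rng(seed).standard_normal((2, x.size))
        noise *= np.sqrt(np.mean(x ** 2) / 10 / np.mean(noise ** 2, axis=1,
                                                        keepdims=True))
        pair = bandpass(np.vstack([x, x]) + noise, FS, 13, 30)
        z = analytic_signal(pair, axis=-1)
        pec_raw_ps.append(abs(pec_pair(z[0], z[1], FS, env_lowpass=None)))
        pec_raw_sm.append(abs(pec_pair(z[0], z[1], FS)))
        raws.append(raw_envelope_correlation(z[0], z[1], FS))
    assert np.mean(pec_raw_ps) < 0.1
    assert np.mean(pec_raw_sm) < 0.45
    assert np.mean(raws) > 0.8


def test_monotone_recovery_in_rho(coupled_pair_factory):
    means = []
    for rho in (0.2, 0.5, 0.8):
        vals = []
        for seed in range(6):
            src, _ = coupled_pair_factory(rho, 200 + seed)
            z = analytic_signal(src, axis=-1)
            vals.append(pec_pair(z[0], z[1], FS))
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


class TestRoiAggregate:
    def test_one_dipole_per_roi_is_identity(self, rng):
        m = rng.uniform(-1, 1, (5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        out = roi_aggregate(m, np.arange(5))
        assert np.allclose(out.matrix, m)

    def test_constant_values_average_to_constant(self):
        n_dip = 6
        m = np.full((n_dip, n_dip), 0.3)
        np.fill_diagonal(m, 0.0)
        out = roi_aggregate(m, np.repeat([0, 1, 2], 2))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(out.matrix[off], 0.3)

    def test_68_rois_give_2278_features(self, rng):
        m = rng.uniform(0, 1, (68, 68))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        out = roi_aggregate(m, np.arange(68))
        assert out.upper_tri.shape == (2278,)

    def test_empty_roi_rejected(self, rng):
        m = np.zeros((4, 4))
        with pytest.raises(ValueError, match="3"):
            roi_aggregate(m, np.array([0, 0, 1, 1]), band="beta", n_rois=4)


def test_pec_matrix_symmetry_and_vectorized_consistency(coupled_pair_factory):
    """The all-pairs path agrees with pairwise pec_pair and is symmetric."""
    from pecnet.synthetic import SimulationConfig, generate_source_signals
    cfg = SimulationConfig(n_rois=4, dipoles_per_roi=1, n_sensors=8,
                           coupling_spec=((0, 1, 0.6),), dipole_noise=0.0)
    src, _, _ = generate_source_signals(cfg, 5, duration=20.0)
    z = analytic_signal(src, axis=-1)
    m = pec_matrix(z, FS)
    assert np.array_equal(m, m.T)
    assert np.allclose(np.diag(m), 0.0)
    # floors are relative to the data each call sees, so agreement is to the
    # floor scale rather than machine precision
    for a, b in [(0, 1), (1, 3)]:
        assert m[a, b] == pytest.approx(pec_pair(z[a], z[b], FS), abs=2e-4)


def test_features_table_stacks_upper_triangles(rng):
    mats = []
    for _ in range(3):
        m = rng.uniform(0, 1, (6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        mats.append(PecMatrix(matrix=m))
    table = features_table(mats)
    assert table.shape == (3, 15)
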