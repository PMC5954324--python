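"""NNLS spectrum fitting: optimality, recovery, regularization, maps."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mwfpipe import (
    AcquisitionProtocol,
    FitConfig,
    PhantomSpec,
    PoolSet,
    T2Grid,
    T2Spectrum,
    build_decay_basis,
    compute_mwf,
    fit_mwf_map,
    fit_nnls,
    fit_nnls_regularized,
    make_phantom,
    pool_signal,
    spectrum_fraction,
)


def brute_force_nnls_residual(A: np.ndarray, y: np.ndarray) -> float:
    """Exhaustive active-set enumeration oracle for small systems.

    The NNLS optimum lies on some face of the non-negative orthant; on that
    face it coincides with the unconstrained least-squares solution over
    the active columns.  Enumerating every column subset and keeping the
    feasible (non-negative) candidates therefore brackets the true optimum.
    """
    m, n = A.shape
    best = float(np.linalg.norm(y))  # the all-zero spectrum
    for k in range(1, n + 1):
        for cols in itertools.combinations(range(n), k):
            sub = A[:, cols]
            coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.all(coef >= -1e-13):
                r = float(np.linalg.norm(sub @ np.clip(coef, 0, None) - y))
                best = min(best, r)
    return best


class TestDecayBasis:
    def test_closed_form_entries(self):
        proto = AcquisitionProtocol(echo_times=[10.0, 320.0])
        grid = T2Grid([10.0, 15.0, 1e12])
        basis = build_decay_basis(proto, grid)
        assert basis.matrix[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-12)
        assert basis.matrix[0, 2] == pytest.approx(1.0, abs=1e-9)
        # deep decay: exp(-320/15) ~ 5.4e-10
        assert basis.matrix[1, 1] == pytest.approx(np.exp(-320.0 / 15.0), rel=1e-12)
        assert basis.matrix[1, 1] == pytest.approx(5.43e-10, rel=1e-2)

    def test_entries_in_unit_interval(self, default_basis):
        assert np.all(default_basis.matrix > 0)
        assert np.all(default_basis.matrix <= 1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            T2Grid([])


class TestFitNNLS:
    def test_single_column_recovery(self, default_basis):
        j = 10
        signal = default_basis.matrix[:, j]
        spec = fit_nnls(signal, default_basis)
        assert spec.residual_norm < 1e-10
        t2 = default_basis.grid.t2_values
        # all amplitude mass within one grid step of the true T2
        near = np.abs(np.arange(t2.size) - j) <= 1
        assert spec.amplitudes[~near].sum() < 1e-8
        assert spec.amplitudes.sum() == pytest.approx(1.0, abs=1e-6)

    def test_ongrid_biexponential_recovery(self, protocol):
        grid = T2Grid(np.unique(np.r_[np.geomspace(15.0, 2000.0, 40), 20.0, 80.0]))
        basis = build_decay_basis(protocol, grid)
        i20 = int(np.argmin(np.abs(grid.t2_values - 20.0)))
        i80 = int(np.argmin(np.abs(grid.t2_values - 80.0)))
        signal = 0.1 * basis.matrix[:, i20] + 0.9 * basis.matrix[:, i80]
        spec = fit_nnls(signal, basis)
        assert spec.residual_norm < 1e-8
        assert spec.amplitudes[i20] == pytest.approx(0.1, abs=1e-6)
        assert spec.amplitudes[i80] == pytest.approx(0.9, abs=1e-6)

    def test_never_beaten_by_random_candidates(self):
        # brute-force oracle: 10^4 random non-negative spectra never fit better
        rng = np.random.default_rng(0)
        proto = AcquisitionProtocol(echo_times=[10, 40, 90, 160, 250])
        grid = T2Grid([20.0, 80.0, 400.0, 1500.0])
        basis = build_decay_basis(proto, grid)
        y = pool_signal(PoolSet([0.3, 0.7], [30.0, 200.0]), proto)
        y = y + rng.normal(0, 0.02, y.size)
        spec = fit_nnls(y, basis)
        candidates = rng.gamma(1.0, 0.5, size=(10_000, 4))
        residuals = np.linalg.norm(candidates @ basis.matrix.T - y, axis=1)
        assert residuals.min() >= spec.residual_norm - 1e-12

    def test_nan_signal_rejected(self, default_basis):
        bad = np.full(32, np.nan)
        with pytest.raises(ValueError):
            fit_nnls(bad, default_basis)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_nonnegativity_fuzz(self, default_basis, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0.5, 0.3, 32)
        spec = fit_nnls(y, default_basis)
        assert np.all(spec.amplitudes >= 0)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(c=st.floats(1e-3, 1e3), seed=st.integers(0, 1000))
    def test_scale_equivariance(self, default_basis, c, seed):
        rng = np.random.default_rng(seed)
        y = np.abs(rng.normal(0.5, 0.3, 32))
        a = fit_nnls(y, default_basis)
        b = fit_nnls(c * y, default_basis)
        np.testing.assert_allclose(b.amplitudes, c * a.amplitudes,
                                   rtol=1e-6, atol=1e-9 * c)
        if a.amplitudes.sum() > 0:
            assert compute_mwf(b) == pytest.approx(compute_mwf(a), abs=1e-12)


class TestExhaustiveOracle:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_on_small_systems(self, seed):
        rng = np.random.default_rng(seed)
        n_echo = int(rng.integers(3, 6))
        n_grid = int(rng.integers(2, 5))
        te = np.sort(rng.uniform(5, 300, n_echo))
        t2 = np.sort(rng.uniform(10, 1500, n_grid))
        proto = AcquisitionProtocol(echo_times=te)
        basis = build_decay_basis(proto, T2Grid(t2))
        y = rng.normal(0.3, 0.4, n_echo)
        spec = fit_nnls(y, basis)
        oracle = brute_force_nnls_residual(basis.matrix, y)
        assert spec.residual_norm == pytest.approx(oracle, abs=1e-10)


class TestRegularized:
    def test_factor_one_reproduces_plain_fit(self, default_basis, nawm_pool):
        y = pool_signal(nawm_pool, default_basis.protocol)
        y = y + np.random.default_rng(0).normal(0, 0.01, y.size)
        plain = fit_nnls(y, default_basis)
        reg = fit_nnls_regularized(y, default_basis, chi2_factor=1.0)
        assert reg.residual_norm == pytest.approx(plain.residual_norm, abs=1e-6)
        assert compute_mwf(reg) == pytest.approx(compute_mwf(plain), abs=1e-6)

    def test_misfit_inflates_by_requested_factor(self, default_basis):
        # off-grid biexponential: a small but nonzero minimum misfit
        y = pool_signal(PoolSet([0.1, 0.9], [25.0, 90.0]),
                        default_basis.protocol)
        plain = fit_nnls(y, default_basis)
        reg = fit_nnls_regularized(y, default_basis, chi2_factor=1.02)
        ratio = reg.residual_norm**2 / plain.residual_norm**2
        assert ratio == pytest.approx(1.02, abs=1e-3)

    def test_regularization_reduces_variance(self, default_basis):
        # noisy biexponential at SNR 100, planted MWF 0.10, 200 repeats
        pool = PoolSet([0.10, 0.88, 0.02], [20.0, 80.0, 2000.0])
        clean = pool_signal(pool, default_basis.protocol)
        rng = np.random.default_rng(42)
        plain, reg = [], []
        for _ in range(200):
            y = clean + rng.normal(0, 0.01, clean.size)
            plain.append(compute_mwf(fit_nnls(y, default_basis)))
            reg.append(compute_mwf(fit_nnls_regularized(y, default_basis, 1.02)))
        assert np.std(reg) <= np.std(plain)


class TestWindowFractions:
    def _spectrum(self, grid, amp):
        return T2Spectrum(grid=grid, amplitudes=np.asarray(amp, float),
                          residual_norm=0.0)

    def test_all_mass_inside_window(self):
        grid = T2Grid([20.0, 30.0])
        assert spectrum_fraction(self._spectrum(grid, [0.4, 0.6]),
                                 (15.0, 40.0)) == 1.0

    def test_no_mass_inside_window(self):
        grid = T2Grid([20.0, 80.0])
        assert spectrum_fraction(self._spectrum(grid, [0.0, 1.0]),
                                 (15.0, 40.0)) == 0.0

    def test_constructed_fraction(self):
        grid = T2Grid([20.0, 80.0])
        spec = self._spectrum(grid, [0.1, 0.9])
        assert spectrum_fraction(spec, (15.0, 40.0)) == pytest.approx(0.1)
        assert compute_mwf(spec) == pytest.approx(0.1)

    def test_half_open_boundary(self):
        # the 40 ms edge belongs to medium, not short
        grid = T2Grid([20.0, 40.0, 80.0])
        spec = self._spectrum(grid, [0.1, 0.2, 0.7])
        assert spectrum_fraction(spec, (15.0, 40.0)) == pytest.approx(0.1)
        assert spectrum_fraction(spec, (40.0, 200.0)) == pytest.approx(0.9)

    def test_compute_mwf_examples(self):
        grid = T2Grid([20.0, 80.0])
        assert compute_mwf(self._spectrum(grid, [1.0, 0.0])) == 1.0
        assert compute_mwf(
            self._spectrum(grid, [0.08, 0.92])) == pytest.approx(0.08)
        assert np.isnan(compute_mwf(self._spectrum(grid, [0.0, 0.0])))

    def test_empty_window_rejected(self):
        grid = T2Grid([80.0, 200.0])
        with pytest.raises(ValueError):
            spectrum_fraction(self._spectrum(grid, [0.5, 0.5]), (15.0, 40.0))


class TestMWFMap:
    def test_noisefree_phantom_exact(self, noisefree_phantom, ongrid_config):
        ph = noisefree_phantom
        mask = ph.nawm_mask + ph.lesion_mask
        mwf = fit_mwf_map(ph.volume, mask, ph.protocol, ongrid_config)
        assert np.all(np.isfinite(mwf[mask == 1]))
        np.testing.assert_allclose(mwf[ph.nawm_mask == 1], 0.0999, atol=1e-6)
        np.testing.assert_allclose(mwf[ph.lesion_mask == 1], 0.080, atol=1e-6)

    def test_empty_mask_all_undefined(self, noisefree_phantom):
        ph = noisefree_phantom
        mwf = fit_mwf_map(ph.volume, np.zeros_like(ph.nawm_mask), ph.protocol)
        assert np.all(np.isnan(mwf))

    def test_shape_mismatch_rejected(self, noisefree_phantom):
        ph = noisefree_phantom
        with pytest.raises(ValueError, match="mask shape"):
            fit_mwf_map(ph.volume, np.zeros((2, 2, 2)), ph.protocol)

    def test_echo_count_mismatch_rejected(self, noisefree_phantom):
        ph = noisefree_phantom
        with pytest.raises(ValueError, match="echoes"):
            fit_mwf_map(ph.volume[..., :30], ph.nawm_mask, ph.protocol)

    def test_monotone_degradation_with_noise(self, protocol):
        # mean absolute MWF error is non-decreasing in noise (common seed)
        import dataclasses

        base = PhantomSpec(grid_shape=(10, 10, 6),
                           lesion_geometry=(((4, 4, 2), 2.5),))
        errors = []
        for sigma in (0.0, 0.005, 0.01, 0.02):
            spec = dataclasses.replace(base, noise_sigma=sigma)
            ph = make_phantom(spec, protocol, seed=5)
            mask = ph.nawm_mask + ph.lesion_mask
            mwf = fit_mwf_map(ph.volume, mask, protocol)
            errors.append(float(np.nanmean(np.abs(mwf - ph.truth_mwf))))
        assert all(a <= b + 1e-12 for a, b in zip(errors, errors[1:]))
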