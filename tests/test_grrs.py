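"""Global-regression estimators: design, GLM, lag search, map recovery."""

import numpy as np
import pytest

from hemomap.core import BoldSeries, ConfigurationError, MotionTrace
from hemomap.grrs import (RS_BAT_RANGE, DesignMatrix, bat_shift_search,
                          build_design, fit_glm, grrs_bat, grrs_cvr,
                          shift_search_map)
from hemomap.preprocess import detrend_bandpass, zscore_map
from hemomap.synth import simulate_bold, simulate_etco2


def _reference(n=150, tr=2.0, seed=0):
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, tr)
    amp = np.where((freqs > 0) & (freqs < 0.1), np.exp(-freqs / 0.02), 0)
    spec = (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)) * amp
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


class TestBuildDesign:
    def test_fourteen_columns_with_motion(self, rng):
        ref = _reference()
        motion = MotionTrace(rng.normal(size=(150, 6)))
        d = build_design(ref, motion, tr=2.0)
        assert d.n_columns == 14
        assert d.names[:2] == ["intercept", "reference"]

    def test_reference_column_is_stored_reference(self, rng):
        ref = _reference()
        d = build_design(ref, MotionTrace(rng.normal(size=(150, 6))), tr=2.0)
        np.testing.assert_array_equal(d.matrix[:, 1], ref)

    def test_motion_squared_after_filtering(self, rng):
        motion = MotionTrace(rng.normal(size=(150, 6)))
        d = build_design(_reference(), motion, tr=2.0)
        mf = detrend_bandpass(motion.values, tr=2.0, axis=0)
        np.testing.assert_allclose(d.matrix[:, 8:14], mf ** 2, atol=1e-12)

    def test_zero_motion_pseudo_inverse_fallback(self):
        """An all-zero (rank-deficient) motion block must not break the fit."""
        ref = _reference()
        d = build_design(ref, MotionTrace(np.zeros((150, 6))), tr=2.0)
        y = 1.5 + 0.3 * ref
        res = fit_glm(y, d)
        assert res.beta0 == pytest.approx(1.5, abs=1e-8)
        assert res.beta1 == pytest.approx(0.3, abs=1e-8)

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ConfigurationError):
            build_design(_reference(100), MotionTrace(rng.normal(size=(80, 6))))


class TestFitGlm:
    def test_exact_linear_relation(self):
        ref = _reference()
        d = build_design(ref, None)
        res = fit_glm(2.0 + 0.5 * ref, d)
        assert res.beta0 == pytest.approx(2.0, abs=1e-10)
        assert res.beta1 == pytest.approx(0.5, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_voxel_zero_beta1(self):
        ref = _reference()
        y = np.ones_like(ref)  # constant: orthogonal to demeaned reference
        d = build_design(ref - ref.mean(), None)
        res = fit_glm(y, d)
        assert res.beta1 == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        """Coefficients agree with explicit (X'X)^-1 X'y to 1e-8."""
        for _ in range(5):
            y = rng.normal(size=40)
            ref = rng.normal(size=40)
            motion = MotionTrace(rng.normal(size=(40, 6)))
            d = build_design(ref, motion, tr=2.0)
            res = fit_glm(y, d)
            X = d.matrix
            beta_oracle = np.linalg.inv(X.T @ X) @ X.T @ y
            assert res.beta0 == pytest.approx(beta_oracle[0], abs=1e-8)
            assert res.beta1 == pytest.approx(beta_oracle[1], abs=1e-8)
            np.testing.assert_allclose(res.covariate_betas, beta_oracle[2:],
                                       atol=1e-8)
            np.testing.assert_allclose(res.residual, y - X @ beta_oracle,
                                       atol=1e-8)

    def test_too_few_timepoints_raise(self, rng):
        d = build_design(_reference(10), MotionTrace(rng.normal(size=(10, 6))))
        with pytest.raises(ConfigurationError):
            fit_glm(np.zeros(10), d)

    def test_residual_orthogonal_to_design(self, rng):
        y = rng.normal(size=60)
        d = build_design(rng.normal(size=60), MotionTrace(rng.normal(size=(60, 6))))
        res = fit_glm(y, d)
        np.testing.assert_allclose(d.matrix.T @ res.residual,
                                   np.zeros(14), atol=1e-8)


def _brute_force_search(y, ref, covs, tr, range_s, step_s):
    """Independent exhaustive oracle: explicit loop, lstsq R^2, identical
    tie-break rule (smallest |shift|, then more negative)."""
    from scipy.interpolate import CubicSpline

    times = np.arange(len(ref)) * tr
    spline = CubicSpline(times, ref)
    n = int(round((range_s[1] - range_s[0]) / step_s))
    shifts = np.round(range_s[0] + step_s * np.arange(n + 1), 6)
    best_shift, best_r2 = None, -np.inf
    for s in sorted(shifts, key=lambda v: (abs(v), v)):
        tt = times - s
        valid = (tt >= -1e-9) & (tt <= times[-1] + 1e-9)
        if valid.sum() <= 3:
            continue
        cols = [np.ones(valid.sum()), spline(tt[valid])]
        if covs is not None:
            cols.extend(np.atleast_2d(covs.T)[:, valid])
        X = np.column_stack(cols)
        yv = y[valid]
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        ssr = np.sum((yv - X @ beta) ** 2)
        sst = np.sum((yv - yv.mean()) ** 2)
        r2 = 1 - ssr / sst if sst > 0 else 0.0
        if r2 > best_r2:
            best_shift, best_r2 = s, r2
    return best_shift


class TestBatShiftSearch:
    def test_recovers_known_delay(self):
        ref = _reference()
        from scipy.interpolate import CubicSpline

        times = np.arange(150) * 2.0
        y = CubicSpline(times, ref)(np.clip(times - 1.2, 0, times[-1]))
        shift, profile = bat_shift_search(y, ref, None, tr=2.0)
        assert shift == pytest.approx(1.2, abs=0.1)
        assert profile.size == 181

    def test_identical_series_zero_shift(self):
        ref = _reference()
        shift, _ = bat_shift_search(ref, ref, None, tr=2.0)
        assert shift == 0.0

    def test_out_of_window_delay_clamps_to_boundary(self):
        ref = _reference()
        from scipy.interpolate import CubicSpline

        times = np.arange(150) * 2.0
        y = CubicSpline(times, ref)(np.clip(times - 12.0, 0, times[-1]))
        opt, boundary, _ = shift_search_map(y, ref, None, 2.0, RS_BAT_RANGE)
        assert opt[0] == 9.0
        assert boundary[0]

    def test_matches_brute_force_oracle_on_random_voxels(self, rng):
        """Implementation and independent exhaustive-grid oracle agree on
        argmax (ties included) for >= 100 random voxels."""
        ref = _reference(80)
        covs = rng.normal(size=(80, 2))
        Y = rng.normal(size=(100, 80)) + rng.normal(size=(100, 1)) * ref
        opt, _, _ = shift_search_map(Y, ref, covs, 2.0, (-6.0, 6.0), 0.5)
        for i in range(100):
            oracle = _brute_force_search(Y[i], ref, covs, 2.0, (-6.0, 6.0), 0.5)
            assert opt[i] == oracle, f"voxel {i}"

    def test_nonfinite_input_raises(self):
        ref = _reference()
        bad = ref.copy()
        bad[3] = np.nan
        with pytest.raises(ConfigurationError):
            bat_shift_search(bad, ref, None, tr=2.0)


class TestGrrsMaps:
    def test_cvr_recovery_noiseless(self, noiseless_subject, grrs_noiseless):
        """Spatial correlation of the estimated CVR-Z map with the Z-scored
        true CVR field reaches 0.99 without noise."""
        t = noiseless_subject.truth
        truth_z = zscore_map(t.cvr_true, t.brain_mask)
        cc = np.corrcoef(grrs_noiseless.cvr_z.values[t.brain_mask],
                         truth_z.values[t.brain_mask])[0, 1]
        assert cc >= 0.99

    def test_bat_recovery_noiseless(self, noiseless_subject, grrs_noiseless):
        t = noiseless_subject.truth
        err = np.abs(grrs_noiseless.bat_seconds.values[t.brain_mask]
                     - t.bat_true.values[t.brain_mask])
        assert (err <= 0.2).mean() >= 0.95

    def test_bat_bounded_by_search_window(self, grrs_noiseless,
                                          noiseless_subject):
        m = noiseless_subject.truth.brain_mask
        assert np.abs(grrs_noiseless.bat_seconds.values[m]).max() <= 9.0

    def test_residual_uncorrelated_with_reference(self, grrs_noiseless,
                                                  noiseless_subject):
        m = noiseless_subject.truth.brain_mask
        resid = grrs_noiseless.residual_series.values[m]
        ref = grrs_noiseless.reference_tc
        rc = resid - resid.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(rc, axis=1)
        keep = norms > 1e-6  # exclude numerically zero residuals
        refc = ref - ref.mean()
        corr = (rc[keep] @ refc) / (norms[keep] * np.linalg.norm(refc))
        assert np.abs(corr).max() < 1e-6

    def test_beta0_guard_zeroes_low_intercept_voxels(self, noisy_subject):
        t = noisy_subject.truth
        bold = noisy_subject.rest_bold
        vals = bold.values.copy()
        idx = tuple(np.argwhere(t.brain_mask & ~t.cerebellum_mask)[0])
        vals[idx] *= 1e-4  # crush the baseline signal of one voxel
        crushed = BoldSeries(vals, tr=bold.tr)
        out = grrs_cvr(crushed, t.cerebellum_mask, t.brain_mask,
                       noisy_subject.rest_motion)
        clean = grrs_cvr(bold, t.cerebellum_mask, t.brain_mask,
                         noisy_subject.rest_motion)
        assert out.cvr_z.meta["n_beta0_guarded"] >= 1
        assert clean.cvr_z.meta["n_beta0_guarded"] == 0
        assert np.all(np.isfinite(out.cvr_z.values))

    def test_degenerate_phantom_all_reference(self, noiseless_subject):
        """Every voxel equal to the reference: BAT 0 everywhere, Z-map
        degenerates to zeros with a warning."""
        t = noiseless_subject.truth
        T = 60
        tc = _reference(T)
        vals = np.zeros(t.brain_mask.shape + (T,))
        vals[t.brain_mask] = 100.0 + tc
        phantom = BoldSeries(vals, tr=2.0)
        with pytest.warns(RuntimeWarning, match="zero variance"):
            bat_s, bat_z = grrs_bat(phantom, t.cerebellum_mask, t.brain_mask)
        assert np.all(bat_s.values == 0.0)
        assert np.all(bat_z.values == 0.0)

    def test_empty_cerebellum_raises(self, noiseless_subject):
        t = noiseless_subject.truth
        with pytest.raises(ConfigurationError):
            grrs_cvr(noiseless_subject.rest_bold,
                     np.zeros_like(t.cerebellum_mask), t.brain_mask)
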