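"""Assessment metrics: similarity, reliability, contrast, multiplicity."""

import inspect

import numpy as np
import pytest

from hemomap.core import ConfigurationError, VolumeMap
from hemomap.evaluation import (IccResult, bland_altman, bootstrap_r2,
                                cohens_d, compare_maps, dice, fdr_bh, icc,
                                lesion_contrast, mirror_mask,
                                regional_covariate_effects, ssim_image)


def _vol(arr):
    return VolumeMap(np.asarray(arr, dtype=float))


def _ssim_loop_oracle(a, b, data_range, win=7):
    """Naive textbook SSIM: explicit loop over all fully valid windows."""
    c1, c2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
    vals = []
    for i in range(a.shape[0] - win + 1):
        for j in range(a.shape[1] - win + 1):
            wa = a[i:i + win, j:j + win].ravel()
            wb = b[i:i + win, j:j + win].ravel()
            ma, mb = wa.mean(), wb.mean()
            va = wa.var(ddof=1)
            vb = wb.var(ddof=1)
            cab = np.sum((wa - ma) * (wb - mb)) / (wa.size - 1)
            vals.append(((2 * ma * mb + c1) * (2 * cab + c2))
                        / ((ma ** 2 + mb ** 2 + c1) * (va + vb + c2)))
    return float(np.mean(vals))


class TestCompareMaps:
    def test_identity(self, rng):
        vol = _vol(rng.normal(size=(10, 10, 8)))
        mask = np.ones((10, 10, 8), bool)
        rep = compare_maps(vol, vol, mask)
        assert rep.pearson_cc == pytest.approx(1.0)
        assert rep.ssim == pytest.approx(1.0)
        assert rep.rmse == 0.0
        assert np.isinf(rep.psnr)

    def test_constant_shift(self, rng):
        base = rng.normal(size=(10, 10, 8))
        base = (base - base.mean()) / base.std()
        mask = np.ones(base.shape, bool)
        rep = compare_maps(_vol(base + 1.0), _vol(base), mask)
        assert rep.pearson_cc == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(1.0)

    def test_ssim_matches_loop_oracle(self, rng):
        a = rng.normal(size=(8, 8))
        b = rng.normal(size=(8, 8))
        dr = max(a.max(), b.max()) - min(a.min(), b.min())
        assert ssim_image(a, b, data_range=dr) == pytest.approx(
            _ssim_loop_oracle(a, b, dr), abs=1e-8)

    def test_ssim_matches_skimage(self, rng):
        from skimage.metrics import structural_similarity

        a = rng.normal(size=(16, 16))
        b = a + 0.3 * rng.normal(size=(16, 16))
        dr = max(a.max(), b.max()) - min(a.min(), b.min())
        ours = ssim_image(a, b, data_range=dr)
        theirs = structural_similarity(a, b, win_size=7, data_range=dr,
                                       gaussian_weights=False)
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_psnr_and_rmse_match_formula_oracle(self, rng):
        p = rng.normal(size=(9, 9, 9))
        r = rng.normal(size=(9, 9, 9))
        mask = np.ones(p.shape, bool)
        rep = compare_maps(_vol(p), _vol(r), mask)
        mse = np.mean((p - r) ** 2)
        assert rep.rmse == pytest.approx(np.sqrt(mse), abs=1e-12)
        assert rep.psnr == pytest.approx(10 * np.log10(p.max() ** 2 / mse),
                                         abs=1e-10)

    def test_psnr_asymmetric_cc_rmse_symmetric(self, rng):
        p = rng.normal(size=(9, 9, 9)) + 2
        r = 0.5 * rng.normal(size=(9, 9, 9))
        mask = np.ones(p.shape, bool)
        ab = compare_maps(_vol(p), _vol(r), mask)
        ba = compare_maps(_vol(r), _vol(p), mask)
        assert ab.pearson_cc == pytest.approx(ba.pearson_cc, abs=1e-12)
        assert ab.rmse == pytest.approx(ba.rmse, abs=1e-12)
        assert ab.psnr != pytest.approx(ba.psnr, abs=1e-6)

    def test_zero_variance_warns_nan_cc(self):
        mask = np.ones((8, 8, 8), bool)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            rep = compare_maps(_vol(np.ones((8, 8, 8))),
                               _vol(np.random.default_rng(0).normal(size=(8, 8, 8))),
                               mask)
        assert np.isnan(rep.pearson_cc)


def _icc_anova_oracle(data):
    """Closed-form ICC(2,1) from two-way ANOVA mean squares."""
    n, k = data.shape
    grand = data.mean()
    msr = k * np.sum((data.mean(1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((data.mean(0) - grand) ** 2) / (k - 1)
    sse = np.sum((data - data.mean(1, keepdims=True)
                  - data.mean(0, keepdims=True) + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_duplicated_measurements_give_one(self):
        data = np.column_stack([np.arange(10.0), np.arange(10.0)])
        res = icc(data)
        assert res.icc == pytest.approx(1.0, abs=1e-9)

    def test_matches_anova_oracle(self, rng):
        data = rng.normal(size=(30, 2)) + 2 * rng.normal(size=(30, 1))
        res = icc(data)
        assert res.icc == pytest.approx(_icc_anova_oracle(data), abs=1e-9)
        assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_independent_pairs_near_zero(self, rng):
        data = rng.normal(size=(1000, 2))
        assert -0.1 <= icc(data).icc <= 0.1

    def test_variance_components_recover_known_ratio(self, rng):
        """Unit variance 3, error variance 1: expected ICC = 3/4."""
        n = 2000
        unit = rng.normal(scale=np.sqrt(3), size=(n, 1))
        data = unit + rng.normal(size=(n, 2))
        res = icc(data)
        assert 0.70 <= res.icc <= 0.80

    def test_affine_invariance(self, rng):
        data = rng.normal(size=(50, 2)) + rng.normal(size=(50, 1))
        a = icc(data).icc
        b = icc(3.2 * data - 7.0).icc
        assert a == pytest.approx(b, abs=1e-9)

    def test_too_few_units_raise(self):
        with pytest.raises(ConfigurationError):
            icc(np.zeros((2, 2)))


class TestDice:
    def test_identical(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0], b[3] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10, 2), bool)
        b = np.zeros((10, 10, 2), bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert dice(a, b) == 0.5

    def test_both_empty_defined_as_one_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert dice(np.zeros((3, 3, 3), bool),
                        np.zeros((3, 3, 3), bool)) == 1.0


class TestLesionContrast:
    def test_effect_size_against_closed_form(self, rng):
        x = rng.normal(0.0, 1.0, size=4000)
        y = rng.normal(1.0, 1.0, size=4000)
        assert cohens_d(x, y) == pytest.approx(-1.0, abs=0.1)

    def test_identical_distributions_near_zero(self, rng):
        x = rng.normal(size=5000)
        y = rng.normal(size=5000)
        assert abs(cohens_d(x, y)) < 0.1

    def test_mirror_rule_flips_x(self):
        lesion = np.zeros((10, 6, 4), bool)
        lesion[2, 3, 1] = True
        mirrored = mirror_mask(lesion)
        assert mirrored[7, 3, 1] and mirrored.sum() == 1

    def test_mirror_leaving_brain_intersected_with_warning(self):
        lesion = np.zeros((10, 6, 4), bool)
        lesion[2, 3, 1] = True
        brain = np.ones((10, 6, 4), bool)
        brain[7, 3, 1] = False
        with pytest.warns(RuntimeWarning, match="intersecting"):
            m = mirror_mask(lesion, brain)
        assert m.sum() == 0

    def test_simulated_lesion_directions(self, rng):
        """Lower CVR and later BAT inside the lesion than in the mirrored
        control region, across subjects."""
        lesion = np.zeros((12, 8, 4), bool)
        lesion[2:4, 3:5, 1:3] = True
        control = lesion[::-1]
        cvr_maps, bat_maps = [], []
        for _ in range(8):
            cvr = rng.normal(loc=1.0, scale=0.05, size=(12, 8, 4))
            cvr[lesion] *= 0.3
            bat = rng.normal(loc=0.0, scale=0.1, size=(12, 8, 4))
            bat[lesion] += 2.0
            cvr_maps.append(_vol(cvr))
            bat_maps.append(_vol(bat))
        cvr_stats = lesion_contrast(cvr_maps, lesion)
        bat_stats = lesion_contrast(bat_maps, lesion)
        assert cvr_stats["lesion_mean"] < cvr_stats["control_mean"]
        assert cvr_stats["effect_size_d"] < -2
        assert bat_stats["lesion_mean"] > bat_stats["control_mean"]


class TestBlandAltman:
    def test_constant_offset(self, rng):
        a = rng.normal(size=50)
        res = bland_altman(a, a + 2.0)
        assert res["bias"] == pytest.approx(2.0, abs=1e-12)
        assert res["loa_high"] - res["loa_low"] == pytest.approx(0.0,
                                                                 abs=1e-9)

    def test_identical_series_zero_bias(self, rng):
        a = rng.normal(size=50)
        assert bland_altman(a, a)["bias"] == 0.0

    def test_loa_half_width_matches_derivation(self, rng):
        """Difference SD 0.5 gives limits of agreement at ~ +/-0.98."""
        a = rng.normal(size=20000)
        b = a + rng.normal(scale=0.5, size=20000)
        res = bland_altman(a, b)
        half = 0.5 * (res["loa_high"] - res["loa_low"])
        assert half == pytest.approx(1.96 * 0.5, rel=0.03)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ConfigurationError):
            bland_altman(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestBootstrapR2:
    def test_exact_linear_relation(self, rng):
        x = rng.normal(size=40)
        res = bootstrap_r2(x, 2.0 * x - 1.0, n_boot=200, seed=0)
        assert res["r2"] == pytest.approx(1.0, abs=1e-12)
        assert res["ci_high"] - res["ci_low"] == pytest.approx(0.0, abs=1e-9)

    def test_independent_pairs_near_zero(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        res = bootstrap_r2(x, y, n_boot=500, seed=0)
        assert res["r2"] < 0.05
        assert res["ci_low"] < 0.05

    def test_default_replicates(self):
        assert inspect.signature(bootstrap_r2).parameters[
            "n_boot"].default == 10_000

    def test_zero_variance_x_raises(self):
        with pytest.raises(ConfigurationError):
            bootstrap_r2(np.ones(10), np.arange(10.0))


def _bh_oracle(p, alpha):
    """Direct step-up computation."""
    m = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = np.array(p)[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return reject


class TestFdr:
    def test_enumerated_case_all_rejected(self):
        reject, _ = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
        assert reject.all()

    def test_all_ones_none_rejected(self):
        reject, _ = fdr_bh(np.ones(6), alpha=0.05)
        assert not reject.any()

    def test_single_p_reduces_to_raw_threshold(self):
        reject, _ = fdr_bh(np.array([0.049]), alpha=0.05)
        assert reject[0]

    def test_matches_step_up_oracle(self, rng):
        for _ in range(20):
            p = rng.random(size=rng.integers(3, 30))
            reject, _ = fdr_bh(p, alpha=0.05)
            np.testing.assert_array_equal(reject, _bh_oracle(p, 0.05))

    def test_out_of_range_p_raises(self):
        with pytest.raises(ConfigurationError):
            fdr_bh(np.array([0.2, 1.3]))


class TestRegionalEffects:
    def test_detects_age_decline_with_reference_normalization(self, rng):
        n_sub, n_roi = 60, 10
        age = rng.uniform(20, 80, size=n_sub)
        vals = np.ones((n_sub, n_roi)) * 2.0
        decline = -0.01 * (age - 50)[:, None]
        vals[:, :5] += decline + 0.05 * rng.normal(size=(n_sub, 5))
        vals[:, 5:] += 0.05 * rng.normal(size=(n_sub, 5))
        res = regional_covariate_effects(vals, age, reference_roi=9)
        assert res["decrease"][:5].sum() >= 4
        assert res["decrease"][5:].sum() <= 1
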