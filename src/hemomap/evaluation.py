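"""Quantitative assessment: map similarity, reliability, lesion contrast.

Similarity metrics follow the conventions used when comparing a predicted
hemodynamic map against its hypercapnic reference: spatial Pearson
correlation over in-mask voxels; SSIM with the standard constants over the
mask bounding box; PSNR defined with the *predicted* map's maximum (an
intentionally asymmetric convention); RMSE in map units.  Reliability uses
the two-way random-effects absolute-agreement single-measurement ICC on
ROI values pooled across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import ConfigurationError, VolumeMap, as_mask


@dataclass
class SimilarityReport:
    pearson_cc: float
    ssim: float
    psnr: float
    rmse: float


@dataclass
class IccResult:
    icc: float
    ci95: tuple[float, float]
    variance_components: dict[str, float]


def _masked_bbox(arr: np.ndarray, mask: np.ndarray) -> np.ndarray:
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    return arr[sl]


def ssim_image(a: np.ndarray, b: np.ndarray, data_range: float | None = None,
               win_size: int = 7) -> float:
    """Mean structural similarity over all fully valid square windows.

    Uniform windows, sample (n-1) covariance, C1=(0.01 L)^2, C2=(0.03 L)^2
    with L the joint data range — the standard formulation.  Works on 2D or
    3D arrays (the window is hyper-cubic).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("ssim requires equal shapes")
    if min(a.shape) < win_size:
        raise ConfigurationError(
            f"image dims {a.shape} smaller than window {win_size}")
    if data_range is None:
        data_range = max(a.max(), b.max()) - min(a.min(), b.min())
        if data_range == 0:
            return 1.0
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    n = win_size ** a.ndim
    cov_norm = n / (n - 1)
    filt = lambda x: ndimage.uniform_filter(x, size=win_size)
    ua, ub = filt(a), filt(b)
    uaa, ubb, uab = filt(a * a), filt(b * b), filt(a * b)
    va = cov_norm * (uaa - ua * ua)
    vb = cov_norm * (ubb - ub * ub)
    cab = cov_norm * (uab - ua * ub)
    s = ((2 * ua * ub + c1) * (2 * cab + c2)
         / ((ua ** 2 + ub ** 2 + c1) * (va + vb + c2)))
    pad = win_size // 2
    core = s[tuple(slice(pad, d - pad) for d in s.shape)]
    return float(core.mean())


def compare_maps(
    pred: VolumeMap | np.ndarray,
    ref: VolumeMap | np.ndarray,
    mask: np.ndarray | VolumeMap,
) -> SimilarityReport:
    """Pearson CC, SSIM, PSNR and RMSE of a prediction against a reference.

    PSNR = 10 log10(max(pred)^2 / MSE) — the maximum is taken over the
    predicted map, so the metric is not symmetric in its arguments.
    Zero-variance inputs make the correlation undefined (NaN with warning).
    """
    p = pred.values if isinstance(pred, VolumeMap) else np.asarray(pred, float)
    r = ref.values if isinstance(ref, VolumeMap) else np.asarray(ref, float)
    m = as_mask(mask)
    if p.shape != r.shape or p.shape != m.shape:
        raise ConfigurationError("compare_maps requires a shared grid")
    if not m.any():
        raise ConfigurationError("mask is empty")
    pm, rm = p[m], r[m]
    mse = float(np.mean((pm - rm) ** 2))
    rmse = float(np.sqrt(mse))
    if pm.std() == 0 or rm.std() == 0:
        warnings.warn("zero-variance map: Pearson correlation undefined",
                      RuntimeWarning, stacklevel=2)
        cc = float("nan")
    else:
        cc = float(np.corrcoef(pm, rm)[0, 1])
    peak = float(np.max(pm))
    psnr = float("inf") if mse == 0 else 10.0 * np.log10(peak ** 2 / mse)
    ssim = ssim_image(_masked_bbox(p, m), _masked_bbox(r, m))
    return SimilarityReport(pearson_cc=cc, ssim=ssim, psnr=psnr, rmse=rmse)


def icc(measurements: np.ndarray) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is (n_units, n_raters) — e.g. ROI values from two
    repeated scans, pooled across subjects.  The estimate and F-based 95% CI
    come from pingouin; variance components from the ANOVA mean squares.
    """
    import pandas as pd
    import pingouin as pg

    data = np.asarray(measurements, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3 or data.shape[1] < 2:
        raise ConfigurationError("icc needs >= 3 units with >= 2 measurements")
    n, k = data.shape
    long = pd.DataFrame({
        "unit": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "value": data.ravel(),
    })
    res = pg.intraclass_corr(long, targets="unit", raters="rater",
                             ratings="value")
    # two-way random, absolute agreement, single measurement; the label
    # differs across pingouin versions
    sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
    row = res[sel].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    # variance components from mean squares
    grand = data.mean()
    msr = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = np.sum((data - data.mean(axis=1, keepdims=True)
                  - data.mean(axis=0, keepdims=True) + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    lo, hi = row[ci_col]
    return IccResult(icc=float(row["ICC"]), ci95=(float(lo), float(hi)),
                     variance_components={"ms_rows": float(msr),
                                          "ms_cols": float(msc),
                                          "ms_error": float(mse)})


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks count as 1."""
    a, b = as_mask(mask_a), as_mask(mask_b)
    if a.shape != b.shape:
        raise ConfigurationError("dice requires a shared grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("dice of two empty masks defined as 1", RuntimeWarning,
                      stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def mirror_mask(mask: np.ndarray,
                brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Mirror-flip about the x mid-plane (left-right in MNI-like grids).

    Used to build contralateral control regions; intersected with the brain
    mask (with a warning) if the mirror leaves it.
    """
    m = as_mask(mask)[::-1].copy()
    if brain_mask is not None:
        brain = as_mask(brain_mask)
        if np.any(m & ~brain):
            warnings.warn("mirrored ROI leaves the brain; intersecting",
                          RuntimeWarning, stacklevel=2)
        m &= brain
    return m


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled SD."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def lesion_contrast(
    maps: list[VolumeMap] | VolumeMap,
    lesion_mask: np.ndarray,
    control_mask: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Lesion-vs-control ROI statistics across subjects.

    ``maps`` is one map per subject (or a single map).  The control region
    defaults to the mirror of the lesion about the x mid-plane.  Returns per
    group means and Cohen's d (lesion minus control).
    """
    if isinstance(maps, VolumeMap):
        maps = [maps]
    lesion = as_mask(lesion_mask)
    if not lesion.any():
        raise ConfigurationError("empty lesion mask")
    control = (as_mask(control_mask) if control_mask is not None
               else mirror_mask(lesion, brain_mask))
    if not control.any():
        raise ConfigurationError("empty control mask")
    les_means = np.array([m.values[lesion].mean() for m in maps])
    ctl_means = np.array([m.values[control].mean() for m in maps])
    return {
        "lesion_mean": float(les_means.mean()),
        "control_mean": float(ctl_means.mean()),
        "effect_size_d": cohens_d(les_means, ctl_means),
        "n_subjects": float(len(maps)),
    }


def bland_altman(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Bias, 95% limits of agreement (bias ± 1.96 SD of differences) and the
    slope of difference vs mean (proportional-bias trend)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size != b.size or a.size < 3:
        raise ConfigurationError("bland_altman needs >= 3 paired values")
    diff = b - a
    mean = 0.5 * (a + b)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if mean.std() > 0:
        slope = float(stats.linregress(mean, diff).slope)
    else:
        slope = 0.0
    return {"bias": bias, "loa_low": bias - 1.96 * sd,
            "loa_high": bias + 1.96 * sd, "sd_diff": sd,
            "trend_slope": slope}


def bootstrap_r2(
    x: np.ndarray, y: np.ndarray, n_boot: int = 10_000, seed: int = 0,
) -> dict[str, float]:
    """R^2 of simple linear regression with a percentile bootstrap 95% CI."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ConfigurationError("bootstrap_r2 needs >= 3 paired samples")
    if x.std() == 0:
        raise ConfigurationError("bootstrap_r2: x has zero variance")

    def r2(xv: np.ndarray, yv: np.ndarray) -> float:
        if xv.std() == 0 or yv.std() == 0:
            return 0.0
        return float(np.corrcoef(xv, yv)[0, 1] ** 2)

    est = r2(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot = np.array([r2(x[i], y[i]) for i in idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {"r2": est, "ci_low": float(lo), "ci_high": float(hi),
            "n_boot": float(n_boot)}


def fdr_bh(p_values: np.ndarray,
           alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def regional_covariate_effects(
    roi_values: np.ndarray,
    covariate: np.ndarray,
    reference_roi: int | None = None,
    alpha: float = 0.05,
) -> dict[str, np.ndarray]:
    """Per-ROI linear regression of (optionally reference-normalized) values
    on a covariate, with BH-FDR control.

    ``roi_values`` is (n_subjects, n_rois).  When ``reference_roi`` is given
    every ROI is divided by that ROI's value per subject (e.g. occipital
    normalization in aging analyses) and the reference column is excluded
    from testing.  Returns slopes, raw and adjusted p-values, and the
    significance masks for decreasing/increasing effects.
    """
    vals = np.asarray(roi_values, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if reference_roi is not None:
        denom = vals[:, reference_roi][:, None]
        if np.any(denom == 0):
            raise ConfigurationError("reference ROI contains zero values")
        vals = vals / denom
    n_rois = vals.shape[1]
    slopes = np.zeros(n_rois)
    pvals = np.ones(n_rois)
    for j in range(n_rois):
        if reference_roi is not None and j == reference_roi:
            continue
        res = stats.linregress(cov, vals[:, j])
        slopes[j], pvals[j] = res.slope, res.pvalue
    reject, p_adj = fdr_bh(pvals, alpha)
    return {"slope": slopes, "p": pvals, "p_adj": p_adj,
            "decrease": reject & (slopes < 0), "increase": reject & (slopes > 0)}
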