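"""Global-regression resting-state (GRRS) estimation.

The classical baseline method and the source of the network's primary
inputs: a voxel-wise general linear model against the cerebellar reference
time course yields the beta0/beta1 CVR coefficient maps, an exhaustive
time-shift search maximizing full-model R^2 yields the bolus-arrival-time
(BAT) map, and the regression residual 4D series feeds the supplementary
(ROI cross-correlation) features.

Conventions
-----------
* The reference is the cerebellar spatial-mean time course after detrend +
  low-pass filtering; the cerebellum is used (rather than the global signal)
  because it is typically spared in the target diseases.
* The voxel fit keeps the voxel's temporal mean (the pass-band includes
  0 Hz), so the intercept beta0 estimates baseline signal and the ratio
  beta1/beta0 is a meaningful fractional reactivity; voxels with beta0 at or
  below 10% of the within-mask median are treated as non-vascular and get
  CVR = 0 before Z-scoring.
* A positive BAT shift means the voxel lags the reference (later arrival).
  Sub-TR shifts evaluate a cubic-spline interpolant of the reference at
  fractionally shifted times; rows where the shifted reference would be
  extrapolated are dropped from that candidate's fit.
* Ties in the R^2 profile resolve to the smallest |shift|, then the more
  negative shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .core import BoldSeries, ConfigurationError, MotionTrace, VolumeMap, as_mask
from .preprocess import DEFAULT_BAND, detrend_bandpass, zscore_map

#: Resting-state BAT search window (s) and grid step (s).
RS_BAT_RANGE: tuple[float, float] = (-9.0, 9.0)
BAT_STEP_S = 0.1
#: beta0 guard: fraction of the within-mask median intercept.
BETA0_GUARD_FRACTION = 0.1


@dataclass
class DesignMatrix:
    """A named GLM design. Column 0 is the intercept, column 1 the reference."""

    matrix: np.ndarray
    names: list[str]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def covariates(self) -> np.ndarray:
        """All columns beyond intercept + reference."""
        return self.matrix[:, 2:]


@dataclass
class GlmResult:
    beta0: float
    beta1: float
    covariate_betas: np.ndarray
    residual: np.ndarray
    r_squared: float
    fitted: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass
class GrrsOutputs:
    """Everything the resting-state stage produces for one subject."""

    beta0_z: VolumeMap
    beta1_z: VolumeMap
    cvr_z: VolumeMap
    bat_seconds: VolumeMap | None = None
    bat_z: VolumeMap | None = None
    residual_series: BoldSeries | None = None
    reference_tc: np.ndarray | None = None


def build_design(
    reference_tc: np.ndarray,
    motion: MotionTrace | np.ndarray | None,
    band: tuple[float, float] = DEFAULT_BAND,
    tr: float = 2.0,
) -> DesignMatrix:
    """Intercept + reference + 12 motion covariates (filtered params and
    their squares, squared after filtering).  14 columns with motion."""
    ref = np.asarray(reference_tc, dtype=float)
    cols = [np.ones_like(ref), ref]
    names = ["intercept", "reference"]
    if motion is not None:
        m = motion.values if isinstance(motion, MotionTrace) else np.asarray(motion)
        if m.shape[0] != ref.shape[0]:
            raise ConfigurationError(
                f"motion length {m.shape[0]} != reference length {ref.shape[0]}"
            )
        mf = detrend_bandpass(m, tr=tr, band=band, axis=0)
        cols.extend(mf.T)
        cols.extend((mf ** 2).T)
        names += [f"motion{i}" for i in range(6)] + [f"motion{i}_sq" for i in range(6)]
    X = np.column_stack(cols)
    return DesignMatrix(X, names)


def _lstsq_fit(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of rows of Y (V, T) on X (T, P) via pseudo-inverse.

    Returns (betas (V, P), residual (V, T)).  The pseudo-inverse handles
    rank-deficient designs (e.g. all-zero motion columns) gracefully.
    """
    betas = Y @ np.linalg.pinv(X).T
    resid = Y - betas @ X.T
    return betas, resid


def _r_squared(Y: np.ndarray, resid: np.ndarray) -> np.ndarray:
    ss_res = np.sum(resid ** 2, axis=-1)
    ss_tot = np.sum((Y - Y.mean(axis=-1, keepdims=True)) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    return np.clip(r2, 0.0, 1.0)


def fit_glm(voxel_tc: np.ndarray, design: DesignMatrix) -> GlmResult:
    """Ordinary least squares of one voxel time course on the design.

    ``beta0`` is the intercept coefficient and ``beta1`` the reference
    coefficient; ``r_squared`` is the full model's 1 - SS_res/SS_tot.
    """
    y = np.asarray(voxel_tc, dtype=float)
    X = design.matrix
    if y.shape[0] <= X.shape[1]:
        raise ConfigurationError(
            f"need more timepoints ({y.shape[0]}) than design columns ({X.shape[1]})"
        )
    betas, resid = _lstsq_fit(y[None, :], X)
    r2 = float(_r_squared(y[None, :], resid)[0])
    fitted = y - resid[0]
    return GlmResult(beta0=float(betas[0, 0]), beta1=float(betas[0, 1]),
                     covariate_betas=betas[0, 2:], residual=resid[0],
                     r_squared=r2, fitted=fitted)


def _shift_candidates(range_s: tuple[float, float], step_s: float) -> np.ndarray:
    lo, hi = range_s
    if step_s <= 0 or lo >= hi:
        raise ConfigurationError(f"invalid shift grid: range {range_s}, step {step_s}")
    n = int(round((hi - lo) / step_s))
    return np.round(lo + step_s * np.arange(n + 1), 6)


def _tie_break_order(shifts: np.ndarray) -> np.ndarray:
    """Index order implementing: smallest |shift| first, then more negative."""
    return np.lexsort((shifts, np.abs(shifts)))


def shift_search_map(
    Y: np.ndarray,
    reference_tc: np.ndarray,
    covariates: np.ndarray | None,
    tr: float,
    range_s: tuple[float, float],
    step_s: float = BAT_STEP_S,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exhaustive lag search for many voxels at once.

    For each candidate shift ``s`` the reference is evaluated at ``t - s``
    (cubic spline), rows where that would extrapolate are dropped, and the
    full-model R^2 (intercept + shifted reference + covariates) is computed
    for every voxel.  Returns (optimal shifts (V,), boundary flags (V,),
    r2 profile (V, S) in candidate order sorted ascending).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if not np.all(np.isfinite(Y)):
        raise ConfigurationError("shift search requires finite time courses")
    ref = np.asarray(reference_tc, dtype=float)
    T = ref.shape[0]
    times = np.arange(T) * tr
    spline = CubicSpline(times, ref)
    shifts = _shift_candidates(range_s, step_s)
    order = _tie_break_order(shifts)
    V = Y.shape[0]
    r2_all = np.zeros((V, shifts.size))
    for j, s in enumerate(shifts):
        t_shift = times - s
        valid = (t_shift >= times[0] - 1e-9) & (t_shift <= times[-1] + 1e-9)
        if valid.sum() <= 3:
            continue
        r_s = spline(t_shift[valid])
        X = np.column_stack([np.ones(int(valid.sum())), r_s])
        if covariates is not None and np.asarray(covariates).size:
            cov = np.asarray(covariates, dtype=float)
            cov = cov[:, None] if cov.ndim == 1 else cov
            X = np.hstack([X, cov[valid]])
        Yv = Y[:, valid]
        _, resid = _lstsq_fit(Yv, X)
        r2_all[:, j] = _r_squared(Yv, resid)
    best_in_order = np.argmax(r2_all[:, order], axis=1)
    best = order[best_in_order]
    opt = shifts[best]
    boundary = (best == 0) | (best == shifts.size - 1)
    return opt, boundary, r2_all


def bat_shift_search(
    voxel_tc: np.ndarray,
    reference_tc: np.ndarray,
    covariates: np.ndarray | None = None,
    tr: float = 2.0,
    range_s: tuple[float, float] = RS_BAT_RANGE,
    step_s: float = BAT_STEP_S,
) -> tuple[float, np.ndarray]:
    """Optimal time shift (s) of one voxel against the reference.

    Returns ``(optimal_shift, r2_profile)``; the profile is ordered by
    ascending candidate shift.  Positive shifts mean later arrival than the
    reference.  A true delay outside the window returns the clamped boundary
    value (flag available via :func:`shift_search_map`).
    """
    opt, _, r2 = shift_search_map(voxel_tc, reference_tc, covariates, tr,
                                  range_s, step_s)
    return float(opt[0]), r2[0]


def _prepare(bold: BoldSeries, cerebellum_mask, brain_mask, motion,
             band: tuple[float, float]):
    brain = as_mask(brain_mask)
    cereb = as_mask(cerebellum_mask)
    if not cereb.any():
        raise ConfigurationError("cerebellum mask is empty")
    if not brain.any():
        raise ConfigurationError("brain mask is empty")
    Y_raw = bold.values[brain].astype(float)
    Yf = detrend_bandpass(Y_raw, tr=bold.tr, band=band, axis=-1)
    ref = detrend_bandpass(bold.values[cereb].mean(axis=0), tr=bold.tr,
                           band=band, axis=-1)
    design = build_design(ref, motion, band=band, tr=bold.tr)
    return brain, Y_raw, Yf, ref, design


def grrs_cvr(
    bold: BoldSeries,
    cerebellum_mask: np.ndarray | VolumeMap,
    brain_mask: np.ndarray | VolumeMap,
    motion: MotionTrace | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> GrrsOutputs:
    """Voxel-wise GLM against the cerebellar reference: CVR coefficient maps.

    Produces Z-scored beta0, beta1 and CVR (= beta1/beta0 with the beta0
    guard) maps plus the residual 4D series used for supplementary features.
    """
    brain, Y_raw, Yf, ref, design = _prepare(bold, cerebellum_mask, brain_mask,
                                             motion, band)
    # restore the temporal mean so the intercept estimates baseline signal
    Y_fit = Yf + Y_raw.mean(axis=-1, keepdims=True)
    betas, resid = _lstsq_fit(Y_fit, design.matrix)
    beta0, beta1 = betas[:, 0], betas[:, 1]

    guard = BETA0_GUARD_FRACTION * np.median(beta0)
    cvr = np.zeros_like(beta0)
    ok = beta0 > guard
    cvr[ok] = beta1[ok] / beta0[ok]
    n_guarded = int((~ok).sum())

    def to_map(vec: np.ndarray, units: str = "raw") -> VolumeMap:
        vol = np.zeros(bold.grid_shape)
        vol[brain] = vec
        return VolumeMap(vol, units=units, voxel_size_mm=bold.voxel_size_mm)

    resid_vol = np.zeros(bold.values.shape)
    resid_vol[brain] = resid
    cvr_z = zscore_map(to_map(cvr), brain)
    cvr_z.meta["n_beta0_guarded"] = n_guarded
    return GrrsOutputs(
        beta0_z=zscore_map(to_map(beta0), brain),
        beta1_z=zscore_map(to_map(beta1), brain),
        cvr_z=cvr_z,
        residual_series=BoldSeries(resid_vol, tr=bold.tr,
                                   voxel_size_mm=bold.voxel_size_mm,
                                   meta={"kind": "grrs_residual"}),
        reference_tc=ref,
    )


def grrs_bat(
    bold: BoldSeries,
    cerebellum_mask: np.ndarray | VolumeMap,
    brain_mask: np.ndarray | VolumeMap,
    motion: MotionTrace | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    range_s: tuple[float, float] = RS_BAT_RANGE,
    step_s: float = BAT_STEP_S,
) -> tuple[VolumeMap, VolumeMap]:
    """Voxel-wise lag search in [-9, +9] s (0.1 s steps): BAT map.

    Returns ``(bat_seconds, bat_z)``; the Z-map is standardized within the
    brain mask (degenerate all-equal searches yield zeros with a warning
    from the Z-scoring step).
    """
    brain, _, Yf, ref, design = _prepare(bold, cerebellum_mask, brain_mask,
                                         motion, band)
    covs = design.covariates if design.n_columns > 2 else None
    opt, boundary, _ = shift_search_map(Yf, ref, covs, bold.tr, range_s, step_s)
    vol = np.zeros(bold.grid_shape)
    vol[brain] = opt
    bat_s = VolumeMap(vol, units="s", voxel_size_mm=bold.voxel_size_mm,
                      meta={"boundary_fraction": float(boundary.mean()),
                            "range_s": list(range_s), "step_s": step_s})
    bat_z = zscore_map(bat_s, brain)
    return bat_s, bat_z


def run_grrs(
    bold: BoldSeries,
    cerebellum_mask: np.ndarray | VolumeMap,
    brain_mask: np.ndarray | VolumeMap,
    motion: MotionTrace | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> GrrsOutputs:
    """CVR maps, BAT maps and residual series in one pass."""
    out = grrs_cvr(bold, cerebellum_mask, brain_mask, motion, band)
    bat_s, bat_z = grrs_bat(bold, cerebellum_mask, brain_mask, motion, band)
    out.bat_seconds, out.bat_z = bat_s, bat_z
    return out
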