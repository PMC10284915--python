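"""Hypercapnic (CO2-inhalation) label generation.

The hypercapnic run is the reference method: a +9 mmHg end-tidal CO2 block
paradigm drives a large, well-characterized BOLD response from which
absolute CVR and a wide-window BAT are estimated.  The resulting Z-maps,
clipped to [-5, 5], are the training targets of the image-translation
network.

Absolute CVR uses the baseline-referenced formula::

    CVR = beta1 / (beta0 + bEtCO2 * beta1)      [x100 -> %/mmHg]

(a GLM of the voxel signal on the synchronized EtCO2 regressor plus a linear
drift term), not the plain beta1/beta0 ratio: the denominator evaluates the
baseline signal at the room-air CO2 level so that CVR is expressed relative
to the basal state.

The BAT search window is [-10, +30] s (0.1 s steps), wider than the
resting-state window because the inhaled CO2 bolus is on the order of a
minute and dispersed arrival can lag far behind the end-tidal recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoldSeries, ConfigurationError, EtCo2Trace, VolumeMap, as_mask
from .grrs import BAT_STEP_S, _lstsq_fit, shift_search_map
from .preprocess import clip_map, pad_volume, zscore_map

#: Hypercapnic BAT search window (s).
HC_BAT_RANGE: tuple[float, float] = (-10.0, 30.0)
#: EtCO2-to-BOLD alignment window (s) and step (s).
ALIGN_RANGE_S: tuple[float, float] = (-30.0, 30.0)
ALIGN_STEP_S = 0.1


@dataclass
class HcOutputs:
    """Hypercapnic reference maps; ``labels`` holds the clipped+padded pair."""

    cvr_abs: VolumeMap            # %/mmHg
    cvr_z: VolumeMap
    bat_seconds: VolumeMap
    bat_z: VolumeMap
    etco2_lag_s: float
    negative_denominator_count: int = 0


def align_etco2(
    etco2: EtCo2Trace,
    cerebellum_tc: np.ndarray,
    tr: float,
    window_s: tuple[float, float] = ALIGN_RANGE_S,
    step_s: float = ALIGN_STEP_S,
) -> tuple[np.ndarray, float]:
    """Synchronize the EtCO2 recording with the cerebellar BOLD time course.

    Searches a global advance ``lag`` of the EtCO2 timestamps over the given
    window, maximizing Pearson correlation between ``etco2(t + lag)`` sampled
    on the TR grid and the cerebellar time course.  A positive lag means
    EtCO2 events were recorded later than the BOLD events they caused; the
    physiological lung-to-brain transit shows up as a negative lag.

    Returns ``(regressor at TR grid, lag_s)``.
    """
    cereb = np.asarray(cerebellum_tc, dtype=float)
    if np.ptp(etco2.values) == 0:
        raise ConfigurationError("EtCO2 trace is constant; cannot align")
    T = cereb.shape[0]
    scan = (T - 1) * tr
    overlap = min(etco2.timestamps[-1], scan) - max(etco2.timestamps[0], 0.0)
    if overlap < 0.8 * scan:
        raise ConfigurationError(
            f"EtCO2 covers only {overlap:.0f} s of a {scan:.0f} s scan (<80%)"
        )
    times = np.arange(T) * tr
    spline = etco2.interpolator()
    lags = np.round(np.arange(window_s[0], window_s[1] + step_s / 2, step_s), 6)
    cz = cereb - cereb.mean()
    c_norm = np.sqrt(np.sum(cz ** 2))
    best_lag, best_r = 0.0, -np.inf
    for lag in lags:
        t_eval = np.clip(times + lag, etco2.timestamps[0], etco2.timestamps[-1])
        x = spline(t_eval)
        xz = x - x.mean()
        denom = np.sqrt(np.sum(xz ** 2)) * c_norm
        r = np.dot(xz, cz) / denom if denom > 0 else -np.inf
        if r > best_r:
            best_r, best_lag = r, float(lag)
    regressor = spline(np.clip(times + best_lag,
                               etco2.timestamps[0], etco2.timestamps[-1]))
    return regressor, best_lag


def _drift_column(T: int) -> np.ndarray:
    """Mean-zero linear drift covariate."""
    t = np.arange(T, dtype=float)
    return t - t.mean()


def hc_cvr(
    bold: BoldSeries,
    etco2_sync: np.ndarray,
    brain_mask: np.ndarray | VolumeMap,
    b_etco2: float,
) -> tuple[VolumeMap, VolumeMap, int]:
    """Absolute CVR from the hypercapnic GLM.

    Fits each voxel on [intercept, drift, EtCO2]; CVR =
    100 * beta1 / (beta0 + bEtCO2*beta1) %/mmHg.  Voxels whose denominator is
    non-positive get CVR = 0 and are counted.  Returns
    ``(cvr_abs, cvr_z, n_bad_denominator)``.
    """
    brain = as_mask(brain_mask)
    if not brain.any():
        raise ConfigurationError("brain mask is empty")
    Y = bold.values[brain].astype(float)
    T = bold.n_timepoints
    reg = np.asarray(etco2_sync, dtype=float)
    X = np.column_stack([np.ones(T), _drift_column(T), reg])
    betas, _ = _lstsq_fit(Y, X)
    beta0, beta1 = betas[:, 0], betas[:, 2]
    denom = beta0 + b_etco2 * beta1
    bad = denom <= 0
    cvr = np.zeros_like(beta0)
    cvr[~bad] = 100.0 * beta1[~bad] / denom[~bad]
    vol = np.zeros(bold.grid_shape)
    vol[brain] = cvr
    cvr_abs = VolumeMap(vol, units="%/mmHg", voxel_size_mm=bold.voxel_size_mm,
                        meta={"b_etco2": b_etco2,
                              "negative_denominator_count": int(bad.sum())})
    return cvr_abs, zscore_map(cvr_abs, brain), int(bad.sum())


def hc_bat(
    bold: BoldSeries,
    etco2_sync: np.ndarray,
    brain_mask: np.ndarray | VolumeMap,
    range_s: tuple[float, float] = HC_BAT_RANGE,
    step_s: float = BAT_STEP_S,
) -> tuple[VolumeMap, VolumeMap]:
    """Wide-window BAT against the synchronized EtCO2 regressor.

    Same R^2-maximizing search as the resting-state method but over
    [-10, +30] s with a linear drift covariate.  Returns
    ``(bat_seconds, bat_z)``.
    """
    brain = as_mask(brain_mask)
    Y = bold.values[brain].astype(float)
    covs = _drift_column(bold.n_timepoints)
    opt, boundary, _ = shift_search_map(Y, np.asarray(etco2_sync, float), covs,
                                        bold.tr, range_s, step_s)
    vol = np.zeros(bold.grid_shape)
    vol[brain] = opt
    bat_s = VolumeMap(vol, units="s", voxel_size_mm=bold.voxel_size_mm,
                      meta={"boundary_fraction": float(boundary.mean()),
                            "range_s": list(range_s), "step_s": step_s})
    return bat_s, zscore_map(bat_s, brain)


def run_hc_reference(
    bold: BoldSeries,
    etco2: EtCo2Trace,
    brain_mask: np.ndarray | VolumeMap,
    cerebellum_mask: np.ndarray | VolumeMap,
) -> HcOutputs:
    """Full hypercapnic stage: align, absolute CVR, wide-window BAT."""
    brain = as_mask(brain_mask)
    cereb = as_mask(cerebellum_mask)
    cereb_tc = bold.values[cereb].mean(axis=0)
    regressor, lag = align_etco2(etco2, cereb_tc, bold.tr)
    b = etco2.estimate_baseline()
    cvr_abs, cvr_z, n_bad = hc_cvr(bold, regressor, brain, b)
    bat_s, bat_z = hc_bat(bold, regressor, brain)
    return HcOutputs(cvr_abs=cvr_abs, cvr_z=cvr_z, bat_seconds=bat_s,
                     bat_z=bat_z, etco2_lag_s=lag,
                     negative_denominator_count=n_bad)


def make_labels(
    hc: HcOutputs, depth: int = 4
) -> tuple[np.ndarray, dict[str, float]]:
    """Clip the HC Z-maps to [-5, 5] and pad to the network grid.

    Returns a (2, X', Y', Z) float array (channel 0 CVR, channel 1 BAT) and
    a clip report with the fraction of voxels clipped per channel.
    """
    report = {}
    channels = []
    for name, zmap in (("cvr", hc.cvr_z), ("bat", hc.bat_z)):
        clipped, frac = clip_map(zmap)
        padded = pad_volume(clipped, depth=depth)
        channels.append(padded.values)
        report[f"{name}_fraction_clipped"] = frac
    return np.stack(channels), report
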