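"""Deterministic signal and image conditioning shared by all estimators.

Spatial smoothing, detrend + low-pass filtering of time courses, within-mask
Z-scoring, clipping of label maps, and zero-padding of volumes to the grid a
2D encoder-decoder with ``depth`` down-samplings can consume.

The default temporal pass-band is [0, 0.1164] Hz, the range in which
spontaneous arterial CO2 fluctuations carry the vascular signal of interest;
higher-frequency content (cardiac/respiratory aliases, thermal noise) is
removed before any regression.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .core import BoldSeries, ConfigurationError, VolumeMap, as_mask

#: Default temporal pass-band (Hz) for resting-state BOLD conditioning.
DEFAULT_BAND: tuple[float, float] = (0.0, 0.1164)

#: Width (Hz) of the half-cosine roll-off applied at the band edge.
EDGE_ROLLOFF_HZ = 0.01

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def gaussian_smooth(series: BoldSeries, fwhm_mm: float) -> BoldSeries:
    """Smooth each volume with an isotropic Gaussian of the given FWHM (mm).

    ``fwhm_mm = 0`` is the identity.  The kernel width is converted to voxel
    units per axis using the series voxel size; FWHM = sigma * sqrt(8 ln 2).
    """
    if fwhm_mm < 0:
        raise ConfigurationError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return series.with_values(series.values.copy())
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in series.voxel_size_mm]
    out = ndimage.gaussian_filter(
        series.values.astype(float), sigma=sigma_vox + [0.0], mode="constant"
    )
    return series.with_values(out)


def smooth_volume(vol: VolumeMap, fwhm_mm: float) -> VolumeMap:
    """3D counterpart of :func:`gaussian_smooth` for single maps."""
    if fwhm_mm < 0:
        raise ConfigurationError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return vol.with_values(vol.values.copy())
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in vol.voxel_size_mm]
    return vol.with_values(ndimage.gaussian_filter(vol.values.astype(float),
                                                   sigma=sigma_vox, mode="constant"))


def _band_gain(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase gain profile: unity inside the band, half-cosine roll-off
    of width ``EDGE_ROLLOFF_HZ`` ending at each finite band edge."""
    f_lo, f_hi = band
    gain = np.ones_like(freqs)
    w = EDGE_ROLLOFF_HZ
    if f_hi is not None and np.isfinite(f_hi):
        hi_edge = np.clip((freqs - (f_hi - w)) / w, 0.0, 1.0)
        gain *= 0.5 * (1.0 + np.cos(np.pi * hi_edge))
    if f_lo > 0:
        lo_edge = np.clip(((f_lo + w) - freqs) / w, 0.0, 1.0)
        gain *= 0.5 * (1.0 + np.cos(np.pi * lo_edge))
        gain[freqs < f_lo] = 0.0
    return gain


def detrend_bandpass(
    tc: np.ndarray,
    tr: float,
    band: tuple[float, float] = DEFAULT_BAND,
    axis: int = -1,
) -> np.ndarray:
    """Remove mean + linear trend, then low/band-pass filter along ``axis``.

    The filter is zero-phase: an rFFT mask with unity gain in the pass-band
    and a half-cosine roll-off near the edges.  Works on arrays of any
    dimensionality (time along ``axis``).

    Raises if the upper band edge reaches the Nyquist frequency 1/(2*tr).
    """
    tc = np.asarray(tc, dtype=float)
    nyquist = 0.5 / tr
    f_lo, f_hi = band
    if f_hi >= nyquist:
        raise ConfigurationError(
            f"Upper band edge {f_hi} Hz must be below Nyquist {nyquist} Hz (tr={tr} s)"
        )
    n = tc.shape[axis]
    x = np.moveaxis(tc, axis, -1)
    # least-squares linear detrend (mean + slope)
    t = np.arange(n, dtype=float)
    t = t - t.mean()
    slope = (x @ t) / (t @ t)
    x = x - x.mean(axis=-1, keepdims=True) - slope[..., None] * t
    # even (mirror) extension suppresses the circular-wraparound edge
    # artifacts the DFT would otherwise impose on non-periodic signals
    ext = np.concatenate([x, x[..., ::-1]], axis=-1)
    freqs = np.fft.rfftfreq(2 * n, d=tr)
    gain = _band_gain(freqs, (f_lo, f_hi))
    ext = np.fft.irfft(np.fft.rfft(ext, axis=-1) * gain, n=2 * n, axis=-1)
    return np.moveaxis(ext[..., :n], -1, axis)


def zscore_map(vol: VolumeMap, mask: np.ndarray | VolumeMap) -> VolumeMap:
    """Standardize within the mask to zero mean, unit (population) SD.

    Out-of-mask voxels are set to 0.  A degenerate (constant) map yields an
    all-zero map with a warning rather than NaNs.
    """
    m = as_mask(mask)
    if not m.any():
        raise ConfigurationError("zscore_map: mask is empty")
    vals = np.asarray(vol.values, dtype=float)
    inside = vals[m]
    sd = float(inside.std())  # population (1/n) SD
    out = np.zeros_like(vals)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("zscore_map: zero variance within mask; returning zeros",
                      RuntimeWarning, stacklevel=2)
    else:
        out[m] = (inside - inside.mean()) / sd
    return vol.with_values(out, units="zscore")


def clip_map(vol: VolumeMap, lo: float = -5.0, hi: float = 5.0) -> tuple[VolumeMap, float]:
    """Clip values to [lo, hi]; returns (clipped map, fraction of voxels clipped)."""
    if lo >= hi:
        raise ConfigurationError(f"clip bounds require lo < hi, got [{lo}, {hi}]")
    vals = np.asarray(vol.values, dtype=float)
    clipped = np.clip(vals, lo, hi)
    frac = float(np.mean((vals < lo) | (vals > hi)))
    out = vol.with_values(clipped)
    out.meta["clip"] = {"lo": lo, "hi": hi, "fraction_clipped": frac}
    return out, frac


def pad_target(shape_xy: tuple[int, int], depth: int = 4) -> tuple[int, int]:
    """Smallest in-plane dims that are multiples of 2**depth and >= input."""
    m = 2 ** depth
    return tuple(int(np.ceil(s / m) * m) for s in shape_xy)  # type: ignore[return-value]


def pad_volume(
    vol: VolumeMap,
    depth: int = 4,
    target_xy: tuple[int, int] | None = None,
) -> VolumeMap:
    """Zero-pad x/y symmetrically so in-plane dims divide by 2**depth.

    The standard 91x109x91 MNI grid pads to 96x112x91 with depth 4.  When the
    split is odd the extra voxel goes on the high-index side; the per-axis pad
    amounts are stored in ``meta['pad']`` so :func:`unpad_volume` inverts
    exactly.  z is never padded (the network is 2D slice-wise).
    """
    nx, ny, nz = vol.shape
    tx, ty = target_xy if target_xy is not None else pad_target((nx, ny), depth)
    if nx > tx or ny > ty:
        raise ConfigurationError(
            f"input dims ({nx},{ny}) exceed pad target ({tx},{ty})"
        )
    pads = []
    for n, t in ((nx, tx), (ny, ty)):
        extra = t - n
        lo = extra // 2
        pads.append((lo, extra - lo))
    out = np.pad(vol.values, (pads[0], pads[1], (0, 0)))
    padded = vol.with_values(out)
    padded.meta["pad"] = {"x": pads[0], "y": pads[1], "orig_shape": (nx, ny, nz)}
    return padded


def unpad_volume(vol: VolumeMap, pad: dict | None = None) -> VolumeMap:
    """Invert :func:`pad_volume` using the recorded (or supplied) pad spec."""
    spec = pad if pad is not None else vol.meta.get("pad")
    if spec is None:
        raise ConfigurationError("unpad_volume: no pad record in meta and none given")
    (lx, hx), (ly, hy) = spec["x"], spec["y"]
    nx, ny = vol.shape[0] - lx - hx, vol.shape[1] - ly - hy
    out = vol.with_values(vol.values[lx:lx + nx, ly:ly + ny, :])
    out.meta.pop("pad", None)
    return out
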