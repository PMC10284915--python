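"""Supplementary network inputs: ROI-referenced residual correlation maps.

After global regression, the residual 4D series still carries regional
vascular information that a single global reference cannot explain.  For
each atlas parcel the spatially averaged residual time course serves as a
reference, and its zero-lag Pearson correlation with every brain voxel's
residual yields one map; the Z-scored stack of all parcels (133 with the
default whole-brain parcellation) is the supplementary input channel block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import BoldSeries, ConfigurationError, VolumeMap, as_mask
from .preprocess import zscore_map


@dataclass
class CCStack:
    """Ordered Z-scored correlation maps, one per atlas label (ascending)."""

    maps: np.ndarray            # (N, X, Y, Z)
    label_ids: np.ndarray       # (N,)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    def as_volume_maps(self) -> list[VolumeMap]:
        return [VolumeMap(m, units="zscore", voxel_size_mm=self.voxel_size_mm)
                for m in self.maps]


def roi_mean_timecourses(
    residual: BoldSeries,
    atlas: VolumeMap | np.ndarray,
    brain_mask: np.ndarray | VolumeMap | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-label unweighted spatial mean of the residual series.

    Labels are taken in ascending order of their (nonzero) ids; the mean is
    computed over the intersection of each label with the brain mask when
    one is given.  Empty labels produce a zero series and a warning.

    Returns ``(timecourses (N, T), label_ids (N,))``.
    """
    labels = (atlas.values if isinstance(atlas, VolumeMap)
              else np.asarray(atlas)).astype(int)
    if labels.shape != residual.grid_shape:
        raise ConfigurationError(
            f"atlas grid {labels.shape} != series grid {residual.grid_shape}"
        )
    restrict = as_mask(brain_mask) if brain_mask is not None else None
    ids = np.unique(labels)
    ids = ids[ids > 0]
    T = residual.n_timepoints
    out = np.zeros((ids.size, T))
    for i, lab in enumerate(ids):
        sel = labels == lab
        if restrict is not None:
            sel &= restrict
        if not sel.any():
            warnings.warn(f"label {lab} has no voxels; zero time course",
                          RuntimeWarning, stacklevel=2)
            continue
        out[i] = residual.values[sel].mean(axis=0)
    return out, ids


def cc_stack(
    residual: BoldSeries,
    atlas: VolumeMap | np.ndarray,
    brain_mask: np.ndarray | VolumeMap,
    zscore: bool = True,
) -> CCStack:
    """Zero-lag Pearson correlation of every voxel with each ROI reference.

    Each per-label correlation map is subsequently Z-scored within the brain
    mask (``zscore=False`` returns the raw correlations).  Zero-variance
    references (or voxels) contribute zero correlation, with a warning for
    degenerate references.
    """
    if residual.n_timepoints < 3:
        raise ConfigurationError("cc_stack needs at least 3 timepoints")
    brain = as_mask(brain_mask)
    refs, ids = roi_mean_timecourses(residual, atlas, brain)
    Y = residual.values[brain].astype(float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    y_norm = np.sqrt(np.sum(Yc ** 2, axis=1))
    y_ok = y_norm > 0
    maps = np.zeros((ids.size,) + residual.grid_shape)
    for i in range(ids.size):
        r = refs[i] - refs[i].mean()
        r_norm = np.sqrt(np.sum(r ** 2))
        corr = np.zeros(Y.shape[0])
        if r_norm == 0:
            warnings.warn(f"label {ids[i]}: zero-variance reference; zero map",
                          RuntimeWarning, stacklevel=2)
        else:
            corr[y_ok] = (Yc[y_ok] @ r) / (y_norm[y_ok] * r_norm)
        vol = np.zeros(residual.grid_shape)
        vol[brain] = corr
        if zscore:
            vol = zscore_map(
                VolumeMap(vol, voxel_size_mm=residual.voxel_size_mm), brain
            ).values
        maps[i] = vol
    return CCStack(maps=maps, label_ids=ids, voxel_size_mm=residual.voxel_size_mm)
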