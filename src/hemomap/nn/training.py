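"""Slice sampling, augmentation, cross-validation and L1 training.

The network is 2D: each subject contributes one training sample per axial
slice that intersects the brain mask, with the three global-regression maps
as primary channels, the ROI correlation stack as supplementary channels,
and the clipped hypercapnic Z-maps as the 2-channel label.  Flip
augmentation is applied to patient-cohort samples only (lesions break the
left-right symmetry that healthy anatomy largely respects, so flipped
patient slices add genuinely new configurations).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..core import ConfigurationError, VolumeMap
from ..grrs import GrrsOutputs
from ..preprocess import pad_volume
from ..supplementary import CCStack
from .layers import DTYPE
from .model import DualEncoderDecoder, NetworkConfig


@dataclass(frozen=True)
class TrainingHyperparams:
    learning_rate: float = 5e-5
    epsilon: float = 1e-12
    batch_size: int = 64
    epochs: int = 100
    optimizer: str = "adabelief"   # or "sgd"
    augment_patients: bool = True
    augment_healthy: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epsilon, self.batch_size,
               self.epochs) <= 0:
            raise ConfigurationError("hyperparameters must be positive")


@dataclass
class TrainingSample:
    primary: np.ndarray        # (3, H, W)
    supplementary: np.ndarray  # (N, H, W)
    label: np.ndarray          # (2, H, W)
    subject_id: str
    slice_index: int
    cohort: str = "healthy"    # or "patient"


def _padded(vol: VolumeMap, depth: int) -> np.ndarray:
    return pad_volume(vol, depth=depth).values


def make_samples(
    grrs_out: GrrsOutputs,
    cc: CCStack,
    labels: np.ndarray,
    brain_mask: np.ndarray,
    subject_id: str = "sub-00",
    cohort: str = "healthy",
    depth: int = 4,
    slice_stride: int = 1,
) -> list[TrainingSample]:
    """One sample per axial slice with non-empty brain mask.

    ``labels`` is the (2, X', Y', Z) clipped+padded stack from
    ``hc_reference.make_labels``.  Channel order is fixed: (beta0_z,
    beta1_z, bat_z | CC_1..CC_N ascending label id).  ``slice_stride``
    subsamples slices (used for scaled-down training studies).
    """
    prim = np.stack([_padded(grrs_out.beta0_z, depth),
                     _padded(grrs_out.beta1_z, depth),
                     _padded(grrs_out.bat_z, depth)])
    supp = np.stack([_padded(VolumeMap(m), depth) for m in cc.maps])
    if labels.shape[1:3] != prim.shape[1:3]:
        raise ConfigurationError(
            f"label grid {labels.shape[1:]} != input grid {prim.shape[1:]}"
        )
    samples = []
    nz = prim.shape[3]
    for z in range(0, nz, slice_stride):
        if not brain_mask[:, :, z].any():
            continue
        samples.append(TrainingSample(
            primary=prim[:, :, :, z].astype(DTYPE),
            supplementary=supp[:, :, :, z].astype(DTYPE),
            label=labels[:, :, :, z].astype(DTYPE),
            subject_id=subject_id, slice_index=z, cohort=cohort))
    return samples


def flip_sample(sample: TrainingSample, axis: int) -> TrainingSample:
    """Flip inputs and label jointly along a spatial axis (1=x, 2=y)."""
    f = lambda a: np.ascontiguousarray(np.flip(a, axis=axis))
    return replace(sample, primary=f(sample.primary),
                   supplementary=f(sample.supplementary),
                   label=f(sample.label))


def augment(sample: TrainingSample, horizontal: bool = True,
            vertical: bool = True) -> list[TrainingSample]:
    """Original plus requested flips (inputs and labels flipped together)."""
    out = [sample]
    if horizontal:
        out.append(flip_sample(sample, axis=1))
    if vertical:
        out.append(flip_sample(sample, axis=2))
    return out


def augment_cohort(samples: list[TrainingSample],
                   hp: TrainingHyperparams) -> list[TrainingSample]:
    out = []
    for s in samples:
        do = (hp.augment_patients if s.cohort == "patient"
              else hp.augment_healthy)
        out.extend(augment(s) if do else [s])
    return out


def kfold_split(
    subject_ids: list[str],
    cohorts: list[str],
    k: int = 5,
    seed: int = 0,
) -> dict[str, int]:
    """Subject-level stratified K-fold assignment.

    Subjects are shuffled within each cohort and dealt round-robin, so
    per-fold cohort counts differ by at most one and every subject lands in
    exactly one validation fold.
    """
    if k > len(subject_ids):
        raise ConfigurationError(f"k={k} exceeds {len(subject_ids)} subjects")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    next_fold = 0
    for cohort in sorted(set(cohorts)):
        members = [s for s, c in zip(subject_ids, cohorts) if c == cohort]
        order = rng.permutation(len(members))
        for j, idx in enumerate(order):
            assignment[members[idx]] = (next_fold + j) % k
        next_fold = (next_fold + len(members)) % k
    return assignment


def _batch_arrays(batch: list[TrainingSample]):
    prim = np.stack([s.primary for s in batch])
    supp = np.stack([s.supplementary for s in batch])
    lab = np.stack([s.label for s in batch])
    return prim, supp, lab


def l1_loss_and_grad(pred: np.ndarray,
                     label: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - label
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff, dtype=DTYPE) / diff.size
    return loss, grad


def evaluate_l1(model: DualEncoderDecoder, samples: list[TrainingSample],
                batch_size: int = 64) -> float:
    total, n = 0.0, 0
    for i in range(0, len(samples), batch_size):
        prim, supp, lab = _batch_arrays(samples[i:i + batch_size])
        pred = model.predict(prim, supp)
        total += float(np.abs(pred - lab).sum())
        n += lab.size
    return total / max(n, 1)


def train(
    model: DualEncoderDecoder,
    samples: list[TrainingSample],
    hp: TrainingHyperparams = TrainingHyperparams(),
    val_samples: list[TrainingSample] | None = None,
) -> dict[str, list[float]]:
    """Mini-batch L1 training with AdaBelief; returns per-epoch loss history.

    Fully deterministic under fixed ``hp.seed`` and model seed.  Aborts with
    diagnostics if the loss goes non-finite.
    """
    from .optim import SGD, AdaBelief

    if not samples:
        raise ConfigurationError("train requires at least one sample")
    params = model.params()
    if hp.optimizer == "adabelief":
        opt = AdaBelief(params, lr=hp.learning_rate, eps=hp.epsilon)
    elif hp.optimizer == "sgd":
        opt = SGD(params, lr=hp.learning_rate)
    else:
        raise ConfigurationError(f"unknown optimizer {hp.optimizer!r}")
    rng = np.random.default_rng(hp.seed)
    history: dict[str, list[float]] = {"train_l1": []}
    if val_samples is not None:
        history["val_l1"] = []
    for epoch in range(hp.epochs):
        order = rng.permutation(len(samples))
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(order), hp.batch_size):
            batch = [samples[j] for j in order[i:i + hp.batch_size]]
            prim, supp, lab = _batch_arrays(batch)
            pred = model.forward(prim, supp, training=True)
            loss, grad = l1_loss_and_grad(pred, lab)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"{loss}; |pred| max {np.abs(pred).max()}"
                )
            model.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history["train_l1"].append(epoch_loss / max(n_batches, 1))
        if val_samples is not None:
            history["val_l1"].append(evaluate_l1(model, val_samples,
                                                 hp.batch_size))
    return history


def predict_volume(
    model: DualEncoderDecoder,
    grrs_out: GrrsOutputs,
    cc: CCStack,
    brain_mask: np.ndarray,
    depth: int = 4,
) -> tuple[VolumeMap, VolumeMap]:
    """Slice-wise inference reassembled to the original (unpadded) grid.

    Returns ``(dlrs_cvr, dlrs_bat)`` Z-scale maps, zeroed outside the brain
    mask; values are bounded by the tanh head.
    """
    padded = pad_volume(grrs_out.beta0_z, depth=depth)
    pad_spec = padded.meta["pad"]
    prim = np.stack([padded.values,
                     _padded(grrs_out.beta1_z, depth),
                     _padded(grrs_out.bat_z, depth)])
    supp = np.stack([_padded(VolumeMap(m), depth) for m in cc.maps])
    nz = prim.shape[3]
    out = np.zeros((2, prim.shape[1], prim.shape[2], nz), dtype=DTYPE)
    batch = 16
    for z0 in range(0, nz, batch):
        zs = range(z0, min(z0 + batch, nz))
        p = np.stack([prim[:, :, :, z] for z in zs])
        s = np.stack([supp[:, :, :, z] for z in zs])
        pred = model.predict(p, s)
        for j, z in enumerate(zs):
            out[:, :, :, z] = pred[j]
    (lx, hx), (ly, hy) = pad_spec["x"], pad_spec["y"]
    nx, ny, _ = pad_spec["orig_shape"]
    cropped = out[:, lx:lx + nx, ly:ly + ny, :]
    maps = []
    for ch, units in ((0, "zscore"), (1, "zscore")):
        vals = cropped[ch].astype(float)
        vals[~brain_mask] = 0.0
        maps.append(VolumeMap(vals, units=units,
                              voxel_size_mm=grrs_out.beta0_z.voxel_size_mm))
    return maps[0], maps[1]
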