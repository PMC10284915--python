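"""Cohort-level studies on synthetic data: method comparison, test-retest
reliability, encoder ablation.

These functions reproduce, at simulation scale, the central experimental
questions of deep-learning resting-state hemodynamic mapping:

* does the network prediction (DLRS) agree with the hypercapnic labels
  better than the classical global-regression maps (GRRS) it was fed?
* is DLRS more reproducible across repeated scans (ICC over atlas ROIs)?
* does removing the supplementary (residual-correlation) encoder hurt?

The default study conditions are deliberately small — a 32x40x12 grid,
16 subjects, a quarter of them with lesions, 30 epochs — so the whole study
runs on one CPU in a few minutes while preserving the structure of the
full-scale experiment (noise, drift, shared regional confounds, patient
augmentation, subject-level stratified folds).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import VolumeMap
from .evaluation import icc
from .grrs import GrrsOutputs, run_grrs
from .hc_reference import HcOutputs, make_labels, run_hc_reference
from .nn.model import DualEncoderDecoder, NetworkConfig
from .nn.training import (TrainingHyperparams, augment_cohort, kfold_split,
                          make_samples, predict_volume, train)
from .preprocess import DEFAULT_BAND, gaussian_smooth
from .supplementary import CCStack, cc_stack
from .synth import (SimulationConfig, SubjectBundle, simulate_bold,
                    simulate_cohort)


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of the scaled method-comparison study."""

    n_subjects: int = 16
    patient_fraction: float = 0.25
    k_folds: int = 4
    validation_fold: int = 0
    simulation: SimulationConfig = field(default_factory=lambda: SimulationConfig(
        grid_shape=(32, 40, 12), hc_fluctuation_sd=1.5, hc_n_timepoints=210))
    base_channels: int = 8
    epochs: int = 60
    batch_size: int = 16
    learning_rate: float = 1e-3
    smoothing_fwhm_mm: float = 6.0
    seed: int = 0

    def network_config(self, use_supplementary: bool = True) -> NetworkConfig:
        return NetworkConfig(
            base_channels=self.base_channels,
            supplementary_in_channels=self.simulation.n_regions,
            use_supplementary_encoder=use_supplementary,
            seed=self.seed,
        )

    def hyperparams(self) -> TrainingHyperparams:
        return TrainingHyperparams(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, seed=self.seed)


@dataclass
class SubjectArtifacts:
    bundle: SubjectBundle
    grrs: GrrsOutputs
    cc: CCStack
    hc: HcOutputs
    labels: np.ndarray
    grrs_retest: GrrsOutputs | None = None
    cc_retest: CCStack | None = None


@dataclass
class StudyResult:
    """All quantities the comparison study measures."""

    folds: dict[str, int]
    validation_subjects: list[str]
    cc_with_labels: dict[str, dict[str, list[float]]]
    median_cc: dict[str, dict[str, float]]
    icc_by_method: dict[str, dict[str, float]]
    train_history: dict[str, list[float]]
    ablated_history: dict[str, list[float]]


def process_subject(bundle: SubjectBundle,
                    band: tuple[float, float] = DEFAULT_BAND,
                    smoothing_fwhm_mm: float = 6.0) -> SubjectArtifacts:
    """Run the full estimation chain (GRRS, residual CC, HC labels)."""
    truth = bundle.truth
    rest = gaussian_smooth(bundle.rest_bold, smoothing_fwhm_mm)
    hc_bold = gaussian_smooth(bundle.hc_bold, smoothing_fwhm_mm)
    g = run_grrs(rest, truth.cerebellum_mask, truth.brain_mask,
                 bundle.rest_motion, band=band)
    cc = cc_stack(g.residual_series, truth.atlas, truth.brain_mask)
    hc = run_hc_reference(hc_bold, bundle.hc_etco2, truth.brain_mask,
                          truth.cerebellum_mask)
    labels, _ = make_labels(hc)
    return SubjectArtifacts(bundle=bundle, grrs=g, cc=cc, hc=hc, labels=labels)


def _masked_cc(a: VolumeMap, b: VolumeMap, mask: np.ndarray) -> float:
    return float(np.corrcoef(a.values[mask], b.values[mask])[0, 1])


def _roi_means(vol: VolumeMap, atlas: VolumeMap) -> np.ndarray:
    labels = atlas.values.astype(int)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    return np.array([vol.values[labels == i].mean() for i in ids])


def run_method_comparison_study(config: StudyConfig) -> StudyResult:
    """Simulate, process, train (full + ablated), and evaluate a cohort.

    Returns per-validation-subject Pearson correlations with the hypercapnic
    labels for DLRS (full and ablated networks) and GRRS, plus test-retest
    ICCs over atlas ROIs for DLRS and GRRS.
    """
    sim = replace(config.simulation, seed=config.seed)
    cohort = simulate_cohort(config.n_subjects, sim, seed=config.seed,
                             patient_fraction=config.patient_fraction)
    artifacts = {
        s.subject_id: process_subject(s, smoothing_fwhm_mm=config.smoothing_fwhm_mm)
        for s in cohort
    }

    tags = {s.subject_id: ("patient" if s.is_patient else "healthy")
            for s in cohort}
    folds = kfold_split(list(tags), list(tags.values()), k=config.k_folds,
                        seed=config.seed)
    val_ids = [sid for sid, f in folds.items()
               if f == config.validation_fold]

    train_samples, val_samples = [], []
    for sid, art in artifacts.items():
        samples = make_samples(art.grrs, art.cc, art.labels,
                               art.bundle.truth.brain_mask, subject_id=sid,
                               cohort=tags[sid])
        if sid in val_ids:
            val_samples += samples
        else:
            train_samples += samples
    hp = config.hyperparams()
    train_samples = augment_cohort(train_samples, hp)

    model = DualEncoderDecoder(config.network_config(use_supplementary=True))
    history = train(model, train_samples, hp, val_samples=val_samples)
    # ablated model: no supplementary encoder (its input is simply ignored)
    ablated = DualEncoderDecoder(config.network_config(use_supplementary=False))
    abl_history = train(ablated, train_samples, hp, val_samples=val_samples)

    # second resting-state acquisition for validation subjects
    for sid in val_ids:
        art = artifacts[sid]
        sub_cfg = replace(sim, seed=art.bundle.rest_bold.meta["seed"])
        bold2, motion2 = simulate_bold(art.bundle.truth, art.bundle.rest_etco2,
                                       sub_cfg, rng_stream=5)
        bold2 = gaussian_smooth(bold2, config.smoothing_fwhm_mm)
        g2 = run_grrs(bold2, art.bundle.truth.cerebellum_mask,
                      art.bundle.truth.brain_mask, motion2)
        art.grrs_retest = g2
        art.cc_retest = cc_stack(g2.residual_series, art.bundle.truth.atlas,
                                 art.bundle.truth.brain_mask)

    cc_res: dict[str, dict[str, list[float]]] = {
        m: {"cvr": [], "bat": []} for m in ("dlrs", "grrs", "dlrs_ablated")}
    roi_pairs: dict[str, dict[str, list[np.ndarray]]] = {
        m: {"cvr": [], "bat": []} for m in ("dlrs", "grrs")}
    for sid in val_ids:
        art = artifacts[sid]
        truth = art.bundle.truth
        brain = truth.brain_mask
        d_cvr, d_bat = predict_volume(model, art.grrs, art.cc, brain)
        a_cvr, a_bat = predict_volume(ablated, art.grrs, art.cc, brain)
        for name, pair in (("dlrs", (d_cvr, d_bat)),
                           ("dlrs_ablated", (a_cvr, a_bat)),
                           ("grrs", (art.grrs.cvr_z, art.grrs.bat_z))):
            cc_res[name]["cvr"].append(_masked_cc(pair[0], art.hc.cvr_z, brain))
            cc_res[name]["bat"].append(_masked_cc(pair[1], art.hc.bat_z, brain))
        # test-retest ROI values
        d2_cvr, d2_bat = predict_volume(model, art.grrs_retest,
                                        art.cc_retest, brain)
        for param, m1, m2 in (("cvr", d_cvr, d2_cvr), ("bat", d_bat, d2_bat)):
            roi_pairs["dlrs"][param].append(np.column_stack([
                _roi_means(m1, truth.atlas), _roi_means(m2, truth.atlas)]))
        for param, m1, m2 in (
            ("cvr", art.grrs.cvr_z, art.grrs_retest.cvr_z),
            ("bat", art.grrs.bat_z, art.grrs_retest.bat_z),
        ):
            roi_pairs["grrs"][param].append(np.column_stack([
                _roi_means(m1, truth.atlas), _roi_means(m2, truth.atlas)]))

    icc_res = {
        method: {param: icc(np.vstack(mats)).icc
                 for param, mats in by_param.items()}
        for method, by_param in roi_pairs.items()
    }
    median_cc = {m: {p: float(np.median(v)) for p, v in by_p.items()}
                 for m, by_p in cc_res.items()}
    return StudyResult(
        folds=folds, validation_subjects=val_ids, cc_with_labels=cc_res,
        median_cc=median_cc, icc_by_method=icc_res, train_history=history,
        ablated_history=abl_history,
    )
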