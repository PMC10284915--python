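"""End-to-end orchestration: simulate -> grrs -> hcref -> suppmaps -> train
-> predict -> evaluate.

Each stage reads its inputs from, and writes its outputs to, a BIDS-like
layout under the configured output directory::

    out/
      manifest.json
      sub-00/ rest_bold.nii.gz, hc_bold.nii.gz, brain_mask.nii.gz, ...
              sub-00_grrs_cvrz.nii.gz, ..., sub-00_labels.nii.gz, ...
      model/  network.npz (+ .json config), training_log.csv
      reports/ similarity.csv

The manifest records every artifact with its SHA-256 hash, producing stage
and the hash of that stage's parameters; a re-run skips stages whose
parameters are unchanged and whose outputs all exist (``force`` recomputes).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .core import ConfigurationError, VolumeMap
from .evaluation import compare_maps
from .grrs import run_grrs
from .hc_reference import make_labels, run_hc_reference
from .nn.model import DualEncoderDecoder, NetworkConfig
from .nn.training import (TrainingHyperparams, augment_cohort, kfold_split,
                          make_samples, predict_volume, train)
from .preprocess import DEFAULT_BAND, gaussian_smooth
from .supplementary import cc_stack
from .synth import LesionSpec, SimulationConfig, simulate_cohort

STAGES = ("simulate", "grrs", "hcref", "suppmaps", "train", "predict",
          "evaluate")


@dataclass
class PipelineConfig:
    out_dir: str = "hemomap_out"
    n_subjects: int = 4
    patient_fraction: float = 0.25
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    band: tuple[float, float] = DEFAULT_BAND
    smoothing_fwhm_mm: float = 0.0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingHyperparams = field(default_factory=TrainingHyperparams)
    k_folds: int = 2
    validation_fold: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", {})
        lesions = tuple(LesionSpec(**ls) for ls in sim.pop("lesion_spec", []))
        net = raw.pop("network", {})
        tr_hp = raw.pop("training", {})
        return cls(
            simulation=SimulationConfig(**sim, lesion_spec=lesions),
            network=NetworkConfig(**net),
            training=TrainingHyperparams(**tr_hp),
            **raw,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_hash(payload) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.data: dict = {"artifacts": {}, "stages": {}}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def record(self, stage: str, params_hash: str, files: list[Path],
               root: Path) -> None:
        for f in files:
            rel = str(f.relative_to(root))
            self.data["artifacts"][rel] = {
                "sha256": _sha256(f), "stage": stage,
                "params_hash": params_hash,
            }
        self.data["stages"][stage] = {"params_hash": params_hash,
                                      "outputs": [str(f.relative_to(root))
                                                  for f in files]}
        self.path.write_text(json.dumps(self.data, indent=2))

    def up_to_date(self, stage: str, params_hash: str, root: Path) -> bool:
        info = self.data["stages"].get(stage)
        if not info or info["params_hash"] != params_hash:
            return False
        return all((root / rel).exists() for rel in info["outputs"])


def _subject_dirs(root: Path) -> list[Path]:
    return sorted(d for d in root.glob("sub-*") if d.is_dir())


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise ConfigurationError(
            f"missing artifact {path.name}: run the '{producing_stage}' "
            "stage first")
    return path


def run_pipeline(
    config: PipelineConfig,
    stages: list[str] | None = None,
    force: bool = False,
) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    Stages whose parameters and outputs are unchanged are skipped unless
    ``force``.  A stage whose input artifacts are missing raises an error
    naming the stage that produces them.
    """
    requested = list(stages) if stages else list(STAGES)
    for s in requested:
        if s not in STAGES:
            raise ConfigurationError(f"unknown stage {s!r}; valid: {STAGES}")
    ordered = [s for s in STAGES if s in requested]
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(root)
    for stage in ordered:
        fn = globals()[f"_stage_{stage}"]
        ph = _params_hash({"stage": stage, "config": config.to_dict()})
        if not force and manifest.up_to_date(stage, ph, root):
            continue
        files = fn(config, root)
        manifest.record(stage, ph, files, root)
    return manifest.data


def _stage_simulate(config: PipelineConfig, root: Path) -> list[Path]:
    cohort = simulate_cohort(config.n_subjects, config.simulation,
                             seed=config.seed,
                             patient_fraction=config.patient_fraction)
    files = []
    for sub in cohort:
        d = root / sub.subject_id
        d.mkdir(exist_ok=True)
        vs = sub.rest_bold.voxel_size_mm
        files += [
            hio.save_series(sub.rest_bold, d / "rest_bold.nii.gz"),
            hio.save_series(sub.hc_bold, d / "hc_bold.nii.gz"),
            hio.save_mask(sub.truth.brain_mask, d / "brain_mask.nii.gz", vs),
            hio.save_mask(sub.truth.cerebellum_mask,
                          d / "cerebellum_mask.nii.gz", vs),
            hio.save_mask(sub.truth.lesion_mask, d / "lesion_mask.nii.gz", vs),
            hio.save_volume(sub.truth.atlas, d / "atlas.nii.gz"),
            hio.save_volume(sub.truth.cvr_true, d / "cvr_true.nii.gz",
                            sidecar={"is_patient": sub.is_patient}),
            hio.save_volume(sub.truth.bat_true, d / "bat_true.nii.gz"),
            hio.save_motion(sub.rest_motion, sub.rest_bold.tr,
                            d / "rest_motion.tsv"),
            hio.save_motion(sub.hc_motion, sub.hc_bold.tr, d / "hc_motion.tsv"),
            hio.save_etco2(sub.rest_etco2, d / "rest_etco2.tsv"),
            hio.save_etco2(sub.hc_etco2, d / "hc_etco2.tsv"),
        ]
    return files


def _stage_grrs(config: PipelineConfig, root: Path) -> list[Path]:
    files = []
    for d in _subject_dirs(root):
        bold = hio.load_series(_require(d / "rest_bold.nii.gz", "simulate"))
        bold = gaussian_smooth(bold, config.smoothing_fwhm_mm)
        brain = hio.load_volume(d / "brain_mask.nii.gz").values.astype(bool)
        cereb = hio.load_volume(d / "cerebellum_mask.nii.gz").values.astype(bool)
        motion = hio.load_motion(d / "rest_motion.tsv")
        out = run_grrs(bold, cereb, brain, motion, band=config.band)
        sid = d.name
        files += [
            hio.save_volume(out.beta0_z, d / f"{sid}_grrs_beta0z.nii.gz"),
            hio.save_volume(out.beta1_z, d / f"{sid}_grrs_beta1z.nii.gz"),
            hio.save_volume(out.cvr_z, d / f"{sid}_grrs_cvrz.nii.gz"),
            hio.save_volume(out.bat_seconds, d / f"{sid}_grrs_bat_s.nii.gz"),
            hio.save_volume(out.bat_z, d / f"{sid}_grrs_batz.nii.gz"),
            hio.save_series(out.residual_series,
                            d / f"{sid}_grrs_residual.nii.gz"),
        ]
    return files


def _stage_hcref(config: PipelineConfig, root: Path) -> list[Path]:
    files = []
    depth = config.network.decoder_blocks
    for d in _subject_dirs(root):
        bold = hio.load_series(_require(d / "hc_bold.nii.gz", "simulate"))
        bold = gaussian_smooth(bold, config.smoothing_fwhm_mm)
        brain = hio.load_volume(d / "brain_mask.nii.gz").values.astype(bool)
        cereb = hio.load_volume(d / "cerebellum_mask.nii.gz").values.astype(bool)
        etco2 = hio.load_etco2(d / "hc_etco2.tsv")
        hc = run_hc_reference(bold, etco2, brain, cereb)
        labels, report = make_labels(hc, depth=depth)
        sid = d.name
        vs = bold.voxel_size_mm
        lab_img = np.moveaxis(labels, 0, -1)  # (X', Y', Z, 2)
        files += [
            hio.save_volume(hc.cvr_abs, d / f"{sid}_hc_cvr_abs.nii.gz"),
            hio.save_volume(hc.cvr_z, d / f"{sid}_hc_cvrz.nii.gz"),
            hio.save_volume(hc.bat_seconds, d / f"{sid}_hc_bat_s.nii.gz"),
            hio.save_volume(hc.bat_z, d / f"{sid}_hc_batz.nii.gz"),
        ]
        import nibabel as nib
        p = d / f"{sid}_labels.nii.gz"
        nib.save(nib.Nifti1Image(lab_img.astype(np.float32),
                                 np.diag(list(vs) + [1.0])), str(p))
        hio.write_sidecar(p, {"clip_report": report,
                              "etco2_lag_s": hc.etco2_lag_s})
        files.append(p)
    return files


def _stage_suppmaps(config: PipelineConfig, root: Path) -> list[Path]:
    import nibabel as nib

    files = []
    for d in _subject_dirs(root):
        sid = d.name
        resid = hio.load_series(
            _require(d / f"{sid}_grrs_residual.nii.gz", "grrs"))
        atlas = hio.load_volume(d / "atlas.nii.gz")
        brain = hio.load_volume(d / "brain_mask.nii.gz").values.astype(bool)
        stack = cc_stack(resid, atlas, brain)
        p = d / f"{sid}_ccmaps.nii.gz"
        nib.save(nib.Nifti1Image(
            np.moveaxis(stack.maps, 0, -1).astype(np.float32),
            np.diag(list(resid.voxel_size_mm) + [1.0])), str(p))
        hio.write_sidecar(p, {"label_ids": stack.label_ids.tolist()})
        files.append(p)
    return files


def _load_subject_samples(d: Path, depth: int, cohort: str):
    from .grrs import GrrsOutputs
    from .supplementary import CCStack

    sid = d.name
    _require(d / f"{sid}_labels.nii.gz", "hcref")
    _require(d / f"{sid}_ccmaps.nii.gz", "suppmaps")
    g = GrrsOutputs(
        beta0_z=hio.load_volume(d / f"{sid}_grrs_beta0z.nii.gz"),
        beta1_z=hio.load_volume(d / f"{sid}_grrs_beta1z.nii.gz"),
        cvr_z=hio.load_volume(d / f"{sid}_grrs_cvrz.nii.gz"),
        bat_z=hio.load_volume(d / f"{sid}_grrs_batz.nii.gz"),
    )
    import nibabel as nib
    cc_img = np.asarray(nib.load(str(d / f"{sid}_ccmaps.nii.gz")).dataobj)
    ids = json.loads((d / f"{sid}_ccmaps.json").read_text())["label_ids"]
    cc = CCStack(np.moveaxis(cc_img, -1, 0), np.asarray(ids))
    lab = np.moveaxis(
        np.asarray(nib.load(str(d / f"{sid}_labels.nii.gz")).dataobj), -1, 0)
    brain = hio.load_volume(d / "brain_mask.nii.gz").values.astype(bool)
    samples = make_samples(g, cc, lab, brain, subject_id=sid, cohort=cohort,
                           depth=depth)
    return g, cc, brain, samples


def _cohort_tags(root: Path) -> dict[str, str]:
    tags = {}
    for d in _subject_dirs(root):
        les = hio.load_volume(d / "lesion_mask.nii.gz").values
        tags[d.name] = "patient" if les.any() else "healthy"
    return tags


def _stage_train(config: PipelineConfig, root: Path) -> list[Path]:
    depth = config.network.decoder_blocks
    tags = _cohort_tags(root)
    folds = kfold_split(list(tags), list(tags.values()), k=config.k_folds,
                        seed=config.seed)
    train_samples, val_samples = [], []
    for d in _subject_dirs(root):
        _, _, _, samples = _load_subject_samples(d, depth, tags[d.name])
        if folds[d.name] == config.validation_fold:
            val_samples += samples
        else:
            train_samples += samples
    train_samples = augment_cohort(train_samples, config.training)
    model = DualEncoderDecoder(config.network)
    history = train(model, train_samples, config.training,
                    val_samples=val_samples or None)
    mdir = root / "model"
    mdir.mkdir(exist_ok=True)
    model.save(mdir / "network.npz")
    log = pd.DataFrame({"epoch": np.arange(1, len(history["train_l1"]) + 1),
                        **history})
    log.to_csv(mdir / "training_log.csv", index=False)
    folds_path = mdir / "folds.json"
    folds_path.write_text(json.dumps(folds, indent=2))
    return [mdir / "network.npz", mdir / "network.npz.json",
            mdir / "training_log.csv", folds_path]


def _stage_predict(config: PipelineConfig, root: Path) -> list[Path]:
    depth = config.network.decoder_blocks
    model_path = _require(root / "model" / "network.npz", "train")
    model = DualEncoderDecoder.load(model_path)
    tags = _cohort_tags(root)
    files = []
    for d in _subject_dirs(root):
        g, cc, brain, _ = _load_subject_samples(d, depth, tags[d.name])
        cvr, bat = predict_volume(model, g, cc, brain, depth=depth)
        sid = d.name
        files += [hio.save_volume(cvr, d / f"{sid}_dlrs_cvrz.nii.gz"),
                  hio.save_volume(bat, d / f"{sid}_dlrs_batz.nii.gz")]
    return files


def _stage_evaluate(config: PipelineConfig, root: Path) -> list[Path]:
    folds_file = root / "model" / "folds.json"
    folds = json.loads(folds_file.read_text()) if folds_file.exists() else {}
    rows = []
    for d in _subject_dirs(root):
        sid = d.name
        brain = hio.load_volume(d / "brain_mask.nii.gz").values.astype(bool)
        hc_cvr = hio.load_volume(d / f"{sid}_hc_cvrz.nii.gz")
        hc_bat = hio.load_volume(d / f"{sid}_hc_batz.nii.gz")
        for method, cvr_name, bat_name in (
            ("dlrs", f"{sid}_dlrs_cvrz.nii.gz", f"{sid}_dlrs_batz.nii.gz"),
            ("grrs", f"{sid}_grrs_cvrz.nii.gz", f"{sid}_grrs_batz.nii.gz"),
        ):
            if not (d / cvr_name).exists():
                _require(d / cvr_name,
                         "predict" if method == "dlrs" else "grrs")
            for param, pred_name, ref in (("cvr", cvr_name, hc_cvr),
                                          ("bat", bat_name, hc_bat)):
                rep = compare_maps(hio.load_volume(d / pred_name), ref, brain)
                rows.append({
                    "subject": sid, "method": method, "parameter": param,
                    "fold": folds.get(sid, -1),
                    "in_validation": folds.get(sid) == config.validation_fold,
                    "pearson_cc": rep.pearson_cc, "ssim": rep.ssim,
                    "psnr": rep.psnr, "rmse": rep.rmse,
                })
    rdir = root / "reports"
    rdir.mkdir(exist_ok=True)
    out = rdir / "similarity.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return [out]
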