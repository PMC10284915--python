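"""Synthetic CO2-driven BOLD cohorts with known voxel-wise hemodynamics.

Every downstream stage of the package (global-regression estimation,
hypercapnic label generation, residual feature extraction, network training,
evaluation) is exercised against cohorts produced here, for which the true
cerebrovascular reactivity (CVR, %/mmHg) and bolus arrival time (BAT, s)
fields are known exactly.

Forward model
-------------
Each voxel ``v`` inside the brain obeys a linear CO2-coupling equation::

    S_v(t) = S0 * [1 + cvr(v)/100 * (P(t - transit - bat(v)) - bEtCO2)]
             + S0 * drift(t) + S0 * sum_k w_k(v) c_k(t) + noise

where ``P`` is the end-tidal CO2 trace (mmHg), ``bEtCO2`` its room-air
baseline, ``transit`` a global lung-to-brain delay, ``drift`` a linear scanner
drift, ``c_k`` shared low-frequency confound time courses with smooth
region-specific weight fields ``w_k`` (the regional signal that a global
regressor cannot explain), and ``noise`` i.i.d. Gaussian.  Sub-TR delays are
realized by evaluating a cubic-spline interpolant of ``P`` at shifted times,
so noiseless voxels satisfy the equation exactly at any delay.

Resting-state EtCO2 is modelled as baseline plus band-limited fluctuations
with a red amplitude spectrum ``exp(-f / 0.015 Hz)`` cut off at 0.1 Hz:
breath-by-breath CO2 variation is dominated by very slow components
(drowsiness cycles, slow breathing modulation), and this spectral shape is
what makes the zero-lag regression coefficient informative at multi-second
arrival delays.  Hypercapnic runs are trapezoidal block designs (room air
alternating with a +9 mmHg plateau, ramped over ~30 s as inhaled CO2
equilibrates over several breaths).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import BoldSeries, ConfigurationError, EtCo2Trace, MotionTrace, VolumeMap

#: Cut-off (Hz) of resting EtCO2 fluctuations.
RESTING_F_CUT = 0.1
#: e-folding frequency (Hz) of the red resting amplitude spectrum.
RESTING_F_SCALE = 0.015
#: Hypercapnic block: full cycle length and ramp duration, seconds.
HC_PERIOD_S = 160.0
HC_RAMP_S = 30.0
#: Internal sampling interval of generated EtCO2 traces, seconds.
ETCO2_DT = 0.1
#: Extra EtCO2 coverage beyond the scan window, seconds (delays + alignment).
ETCO2_PAD_S = 45.0

# Healthy-tissue truth-field statistics (before lesions).
CVR_MEAN, CVR_SD, CVR_RANGE = 0.25, 0.075, (0.05, 0.45)   # %/mmHg
BAT_MEAN, BAT_SD, BAT_RANGE = 0.5, 0.8, (-3.0, 5.0)      # s
FIELD_SMOOTH_SIGMA = 4.0                                  # voxels


@dataclass(frozen=True)
class LesionSpec:
    """An ellipsoidal lesion: CVR scaled by ``cvr_scale``, BAT shifted by
    ``bat_offset`` seconds.  Center/radii are fractions of the grid shape."""

    center_frac: tuple[float, float, float] = (0.30, 0.55, 0.60)
    radii_frac: tuple[float, float, float] = (0.12, 0.14, 0.18)
    cvr_scale: float = 0.3
    bat_offset: float = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one simulated acquisition.

    Defaults describe the resting-state condition on the small test grid;
    ``hypercapnic`` settings are used when the matching mode is requested.
    """

    grid_shape: tuple[int, int, int] = (48, 56, 24)
    tr: float = 2.0
    n_timepoints: int = 150
    hc_n_timepoints: int | None = None  # hypercapnic run length (defaults to
    #                                     n_timepoints)
    baseline_etco2: float = 40.0       # mmHg, room-air bEtCO2
    rs_fluctuation_sd: float = 1.5     # mmHg
    hc_block_amplitude: float = 9.0    # mmHg (5% CO2 plateau above baseline)
    hc_fluctuation_sd: float = 0.0     # mmHg breath-by-breath variability
    #                                    superimposed on the block design
    s0: float = 1000.0                 # baseline signal, arbitrary units
    noise_sd: float = 0.01             # fraction of S0 (temporal SNR ~100)
    drift_slope: float = 0.01          # fraction of S0 over the whole scan
    n_shared_components: int = 3
    confound_amplitude: float = 0.0015  # per-component weight SD, fraction of S0
    transit_delay_s: float = 6.0       # lung-to-brain delay, s
    n_regions: int = 133               # atlas parcels
    anatomy_seed: int = 20             # shared template anatomy (MNI-like)
    subject_field_variation: float = 0.3  # fraction of field variance that is
    #                                       subject-specific (rest is shared)
    lesion_spec: tuple[LesionSpec, ...] = ()
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        # tolerate list-valued fields (e.g. from YAML configs)
        object.__setattr__(self, "grid_shape", tuple(self.grid_shape))
        object.__setattr__(self, "voxel_size_mm", tuple(self.voxel_size_mm))
        object.__setattr__(self, "lesion_spec", tuple(self.lesion_spec))
        if self.tr <= 0:
            raise ConfigurationError(f"tr must be positive, got {self.tr}")
        if self.n_timepoints < 2:
            raise ConfigurationError("n_timepoints must be >= 2")
        if self.rs_fluctuation_sd < 0:
            raise ConfigurationError("rs_fluctuation_sd must be >= 0")
        if min(self.grid_shape[:2]) < 8:
            raise ConfigurationError("in-plane grid dimensions must be >= 8")

    def noiseless(self) -> "SimulationConfig":
        """Copy with noise, drift and shared confounds switched off."""
        return replace(self, noise_sd=0.0, drift_slope=0.0, n_shared_components=0)

    @property
    def scan_duration(self) -> float:
        return (self.n_timepoints - 1) * self.tr


@dataclass
class GroundTruthFields:
    """The parameter-recovery oracle: true hemodynamics plus anatomy masks."""

    cvr_true: VolumeMap        # %/mmHg
    bat_true: VolumeMap        # s
    lesion_mask: np.ndarray
    brain_mask: np.ndarray
    cerebellum_mask: np.ndarray
    atlas: VolumeMap           # integer labels 1..n_regions, 0 outside brain


@dataclass
class SubjectBundle:
    """Everything one simulated participant contributes."""

    subject_id: str
    rest_bold: BoldSeries
    hc_bold: BoldSeries
    rest_etco2: EtCo2Trace
    hc_etco2: EtCo2Trace
    rest_motion: MotionTrace
    hc_motion: MotionTrace
    truth: GroundTruthFields
    is_patient: bool = False


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def _band_limited_noise(
    n: int, dt: float, rng: np.random.Generator,
    f_cut: float = RESTING_F_CUT, f_scale: float = RESTING_F_SCALE,
) -> np.ndarray:
    """Zero-mean unit-SD trace with amplitude spectrum exp(-f/f_scale) <= f_cut."""
    freqs = np.fft.rfftfreq(n, dt)
    amp = np.where((freqs > 0) & (freqs <= f_cut), np.exp(-freqs / f_scale), 0.0)
    spec = (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)) * amp
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_etco2(config: SimulationConfig, mode: str = "resting") -> EtCo2Trace:
    """Generate an end-tidal CO2 trace covering the scan plus delay margins.

    ``resting``: bEtCO2 plus band-limited red-spectrum fluctuations with the
    configured standard deviation.  ``hypercapnic``: trapezoidal block design
    alternating room air and a plateau ``hc_block_amplitude`` mmHg above
    baseline; samples on room-air plateaus are flagged in ``baseline_mask``.
    """
    if mode not in ("resting", "hypercapnic"):
        raise ConfigurationError(f"unknown EtCO2 mode {mode!r}")
    t = np.arange(-ETCO2_PAD_S, config.scan_duration + ETCO2_PAD_S + ETCO2_DT,
                  ETCO2_DT)
    b = config.baseline_etco2
    if mode == "resting":
        fluct = np.zeros_like(t)
        if config.rs_fluctuation_sd > 0:
            fluct = _band_limited_noise(t.size, ETCO2_DT, _rng(config, 1))
            fluct *= config.rs_fluctuation_sd
        values = b + fluct
        mask = None
    else:
        # trapezoid: baseline plateau, ramp up, hyper plateau, ramp down, ...
        period, ramp = HC_PERIOD_S, HC_RAMP_S
        plateau = period / 2 - ramp
        phase = np.mod(t, period)
        frac = np.zeros_like(t)
        frac = np.where(phase < plateau, 0.0, frac)
        up = (phase >= plateau) & (phase < plateau + ramp)
        frac = np.where(up, (phase - plateau) / ramp, frac)
        high = (phase >= plateau + ramp) & (phase < 2 * plateau + ramp)
        frac = np.where(high, 1.0, frac)
        down = phase >= 2 * plateau + ramp
        frac = np.where(down, 1.0 - (phase - 2 * plateau - ramp) / ramp, frac)
        values = b + config.hc_block_amplitude * frac
        if config.hc_fluctuation_sd > 0:
            values = values + config.hc_fluctuation_sd * _band_limited_noise(
                t.size, ETCO2_DT, _rng(config, 1))
        mask = frac == 0.0
    return EtCo2Trace(timestamps=t, values=values, baseline=b, baseline_mask=mask)


def _smooth_field(shape: tuple[int, int, int], rng: np.random.Generator,
                  sigma: float = FIELD_SMOOTH_SIGMA) -> np.ndarray:
    """Unit-SD smooth Gaussian random field, mirror-symmetrized about x."""
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="nearest")
    f = 0.5 * (f + f[::-1])  # left-right symmetric base anatomy
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipsoid_mask(shape: tuple[int, int, int],
                    center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d2 <= 1.0


def _poisson_disk_seeds(coords: np.ndarray, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Greedy best-candidate sampling: well-spread seed points among coords."""
    seeds = [coords[rng.integers(len(coords))]]
    tree_pts = np.array(seeds, dtype=float)
    for _ in range(n - 1):
        cand = coords[rng.integers(len(coords), size=min(32, len(coords)))]
        d = cKDTree(tree_pts).query(cand)[0]
        best = cand[np.argmax(d)]
        seeds.append(best)
        tree_pts = np.vstack([tree_pts, best])
    return np.array(seeds, dtype=float)


def make_truth_fields(config: SimulationConfig) -> GroundTruthFields:
    """Build smooth, left-right-symmetric CVR/BAT truth fields with anatomy.

    The anatomy emulates a cohort normalized to a standard (MNI-like) space:
    the brain mask, cerebellum, atlas parcellation and a population template
    of each hemodynamic field derive from ``anatomy_seed`` and are therefore
    identical across subjects, while a ``subject_field_variation`` fraction
    of the field variance is subject-specific (seeded per subject).  The
    brain is an inscribed ellipsoid; the cerebellum is its inferior-posterior
    cap and is assigned BAT = 0 (it is the reference territory of the
    resting-state method and is typically spared in the diseases of
    interest).  Lesions multiply CVR by ``cvr_scale`` and add ``bat_offset``
    within their ellipsoid; the atlas is a nearest-centroid partition of the
    brain around well-spread seed points.
    """
    shape = config.grid_shape
    anat_rng = np.random.default_rng(
        np.random.SeedSequence((config.anatomy_seed, 0)))
    rng = _rng(config, 2)
    nx, ny, nz = shape
    center = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
    radii = np.array([0.45 * nx, 0.45 * ny, 0.45 * nz])
    brain = _ellipsoid_mask(shape, center, radii)
    # cerebellum: inferior-posterior cap of the brain
    zz = np.arange(nz)[None, None, :]
    yy = np.arange(ny)[None, :, None]
    cereb = brain & (zz < 0.25 * nz) & (yy > 0.62 * ny)
    if not cereb.any():
        raise ConfigurationError("grid too small to carve a cerebellum region")

    v = float(np.clip(config.subject_field_variation, 0.0, 1.0))
    w_shared, w_subj = np.sqrt(1.0 - v), np.sqrt(v)
    cvr_template = _smooth_field(shape, anat_rng)
    bat_template = _smooth_field(shape, anat_rng)
    cvr = CVR_MEAN + CVR_SD * (w_shared * cvr_template
                               + w_subj * _smooth_field(shape, rng))
    cvr = np.clip(cvr, *CVR_RANGE)
    bat = BAT_MEAN + BAT_SD * (w_shared * bat_template
                               + w_subj * _smooth_field(shape, rng))
    bat = np.clip(bat, *BAT_RANGE)
    bat[cereb] = 0.0

    lesion = np.zeros(shape, dtype=bool)
    for spec in config.lesion_spec:
        c = np.array(spec.center_frac) * (np.array(shape) - 1)
        r = np.array(spec.radii_frac) * np.array(shape)
        ell = _ellipsoid_mask(shape, c, r)
        if not brain[tuple(np.round(c).astype(int))]:
            raise ConfigurationError(f"lesion center {spec.center_frac} outside brain")
        ell &= brain & ~cereb
        cvr[ell] *= spec.cvr_scale
        bat[ell] += spec.bat_offset
        lesion |= ell
    cvr[~brain] = 0.0
    bat[~brain] = 0.0

    coords = np.argwhere(brain)
    n_regions = min(config.n_regions, len(coords))
    seeds = _poisson_disk_seeds(coords, n_regions, anat_rng)
    labels = np.zeros(shape, dtype=np.int32)
    nearest = cKDTree(seeds).query(coords)[1]
    labels[tuple(coords.T)] = nearest + 1

    vs = config.voxel_size_mm
    return GroundTruthFields(
        cvr_true=VolumeMap(cvr, units="%/mmHg", voxel_size_mm=vs),
        bat_true=VolumeMap(bat, units="s", voxel_size_mm=vs),
        lesion_mask=lesion,
        brain_mask=brain,
        cerebellum_mask=cereb,
        atlas=VolumeMap(labels, units="label", voxel_size_mm=vs),
    )


def _motion_trace(n: int, rng: np.random.Generator) -> MotionTrace:
    steps = rng.normal(size=(n, 6)) * np.array([0.02] * 3 + [4e-4] * 3)
    return MotionTrace(np.cumsum(steps, axis=0))


def simulate_bold(
    truth: GroundTruthFields,
    etco2: EtCo2Trace,
    config: SimulationConfig,
    rng_stream: int = 3,
) -> tuple[BoldSeries, MotionTrace]:
    """Evaluate the forward model on the truth fields for one run.

    The EtCO2 trace must cover every shifted sampling time
    ``t - transit - bat(v)``; a trace that is too short raises an error
    stating the required coverage.  Motion is a six-parameter random walk that
    is reported (for use as nuisance covariates) but does not corrupt the
    signal.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, rng_stream)))
    times = np.arange(config.n_timepoints) * config.tr
    brain = truth.brain_mask
    bat = truth.bat_true.values
    delay = config.transit_delay_s + bat[brain]
    t_needed = (times[0] - delay.max(), times[-1] - delay.min())
    if etco2.timestamps[0] > t_needed[0] or etco2.timestamps[-1] < t_needed[1]:
        raise ConfigurationError(
            "EtCO2 trace too short: needs coverage "
            f"[{t_needed[0]:.1f}, {t_needed[1]:.1f}] s but spans "
            f"[{etco2.timestamps[0]:.1f}, {etco2.timestamps[-1]:.1f}] s"
        )
    spline = etco2.interpolator()
    b = etco2.baseline
    s0 = config.s0

    # evaluate P(t - transit - bat) on quantized delays (0.01 s bins)
    q = np.round(delay / 0.01).astype(np.int64)
    uniq, inv = np.unique(q, return_inverse=True)
    table = spline(times[None, :] - (uniq * 0.01)[:, None])  # (U, T)
    p_shift = table[inv]                                      # (Vbrain, T)

    cvr = truth.cvr_true.values[brain][:, None]
    signal = s0 * (1.0 + cvr / 100.0 * (p_shift - b))

    if config.drift_slope != 0.0:
        drift = config.drift_slope * np.linspace(-0.5, 0.5, config.n_timepoints)
        signal = signal + s0 * drift[None, :]
    if config.n_shared_components > 0:
        for k in range(config.n_shared_components):
            tc = _band_limited_noise(times.size, config.tr, rng)
            w = _smooth_field(config.grid_shape, rng) * config.confound_amplitude
            signal = signal + s0 * w[brain][:, None] * tc[None, :]
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd * s0, signal.shape)

    vol = np.zeros(config.grid_shape + (config.n_timepoints,))
    vol[brain] = signal
    series = BoldSeries(vol, tr=config.tr, voxel_size_mm=config.voxel_size_mm,
                        meta={"seed": config.seed, "stream": rng_stream})
    motion = _motion_trace(config.n_timepoints, rng)
    return series, motion


def simulate_subject(
    config: SimulationConfig,
    subject_id: str = "sub-00",
    is_patient: bool = False,
) -> SubjectBundle:
    """Simulate one participant: resting + hypercapnic runs on shared anatomy."""
    cfg = config
    if is_patient and not cfg.lesion_spec:
        cfg = replace(cfg, lesion_spec=(LesionSpec(),))
    hc_cfg = (cfg if cfg.hc_n_timepoints is None
              else replace(cfg, n_timepoints=cfg.hc_n_timepoints))
    truth = make_truth_fields(cfg)
    rest_et = simulate_etco2(cfg, "resting")
    hc_et = simulate_etco2(hc_cfg, "hypercapnic")
    rest_bold, rest_mot = simulate_bold(truth, rest_et, cfg, rng_stream=3)
    hc_bold, hc_mot = simulate_bold(truth, hc_et, hc_cfg, rng_stream=4)
    return SubjectBundle(subject_id, rest_bold, hc_bold, rest_et, hc_et,
                         rest_mot, hc_mot, truth, is_patient=is_patient)


def simulate_cohort(
    n_subjects: int,
    config: SimulationConfig,
    seed: int | None = None,
    patient_fraction: float = 0.0,
) -> list[SubjectBundle]:
    """Simulate a cohort with per-subject independent seeds.

    ``round(n_subjects * patient_fraction)`` subjects (the first ones, so the
    assignment is reproducible) carry a lesion.  Per-subject seeds derive from
    the master seed (``seed`` or ``config.seed``) via ``SeedSequence`` so the
    whole cohort is bitwise reproducible.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    master = config.seed if seed is None else seed
    n_patients = int(round(n_subjects * patient_fraction))
    children = np.random.SeedSequence(master).spawn(n_subjects)
    cohort = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = replace(config, seed=sub_seed)
        cohort.append(simulate_subject(cfg, subject_id=f"sub-{i:02d}",
                                       is_patient=i < n_patients))
    return cohort
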