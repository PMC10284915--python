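# Methods

`hemomap` estimates two voxel-wise hemodynamic parameters from BOLD fMRI:
cerebrovascular reactivity (CVR, the fractional signal response per mmHg of
arterial CO₂ change, %/mmHg) and bolus arrival time (BAT, the delay with
which a CO₂ perturbation reaches a voxel, s). Three estimation routes are
implemented: the classical global-regression resting-state method (GRRS),
the hypercapnic CO₂-inhalation reference method (HC), and a deep-learning
resting-state method (DLRS) — a dual-encoder image-translation network that
maps GRRS-derived inputs onto HC-quality targets. A synthetic CO₂-driven
BOLD simulator with known truth fields makes every stage testable without
clinical data.

## Forward model (synthetic data)

Each brain voxel obeys a linear CO₂-coupling equation

    S_v(t) = S0 · [1 + cvr(v)/100 · (P(t − τ − bat(v)) − bEtCO₂)]
             + S0 · drift(t) + S0 · Σ_k w_k(v) c_k(t) + ε_v(t)

with `P` the end-tidal CO₂ trace (mmHg), `bEtCO₂ = 40 mmHg` its room-air
baseline, `τ = 6 s` a global lung-to-brain transit delay, a linear scanner
drift (1% of S0 over the scan), `K = 3` shared band-limited confound time
courses with smooth region-specific weight fields (SD 0.15% of S0 each),
and white Gaussian noise (SD 1% of S0, i.e. temporal SNR ≈ 100). Sub-grid
delays evaluate a cubic-spline interpolant of `P`, so noiseless voxels obey
the equation exactly at any delay. This is deliberately the simplest model
consistent with both GLM estimators; the shared confounds are the regional
signal a single global regressor cannot explain and are what gives the
residual-correlation features their information content.

**EtCO₂ traces.** Resting-state: baseline plus band-limited fluctuations
(SD 1.5 mmHg) with a red amplitude spectrum `exp(−f/0.015 Hz)` cut off at
0.1 Hz. Breath-to-breath CO₂ variation is dominated by very slow
components; concretely, the zero-lag regression slope at a voxel with
arrival delay `b` is attenuated by the trace's autocorrelation at `b`, and
only a spectrum concentrated well below 0.1 Hz keeps this attenuation small
over physiological delays. Hypercapnic: a trapezoidal block design (160 s
period, 30 s ramps, +9 mmHg plateau emulating 5% CO₂ inhalation) — ramps
model the multi-breath equilibration of end-tidal CO₂ and are also what
keeps the zero-lag hypercapnic CVR fit accurate at nonzero BAT. Optional
breath-by-breath variability (`hc_fluctuation_sd`, default 0) can be
superimposed; the cohort studies enable it (1.5 mmHg) because a pure
trapezoid's autocorrelation is so flat near its peak that the lag estimate
becomes imprecise under noise.

**Truth fields and anatomy.** The brain is an inscribed ellipsoid, the
cerebellum its inferior-posterior cap (the reference territory, BAT ≡ 0).
Anatomy emulates a cohort normalized to a common (MNI-like) space: the
brain mask, atlas (nearest-centroid partition around well-spread seeds,
133 regions by default) and a population template of each field derive from
a fixed `anatomy_seed`; 30% of the field variance is subject-specific.
Healthy-tissue statistics: CVR ~ N(0.25, 0.075) clipped to
[0.05, 0.45] %/mmHg; BAT ~ N(0.5 s, 0.8 s) clipped to [−3, 5] s. Fields are
left-right symmetrized (mirror averaging), which makes
lesion-vs-contralateral contrasts exact by construction. Lesions are
ellipsoids that multiply CVR by `cvr_scale` and shift BAT by `bat_offset`;
they carry the large, pathological delays. The BAT spread matters: the
detrend/filter chain attenuates shifted copies of the regressor by a few
percent across the delay range, and a healthy spread much wider than ~1 s
would make that attenuation visible in the recovered CVR maps.

**What the simulator does not model:** breathing mechanics, BOLD biophysics
(no balloon model — coupling is linear by construction), motion-induced
signal artifacts (the motion trace is a reported nuisance, not a corruption
process), scanner artifacts, and real anatomical geometry. Passing
recovery tests therefore show the estimators invert this forward model;
they do not certify performance against physiological confounds absent
from it.

## Resting-state estimation (GRRS)

The series is (optionally) smoothed with an isotropic Gaussian, detrended
and low-pass filtered on [0, 0.1164] Hz (zero-phase rFFT mask with a
half-cosine roll-off; the signal is mirror-extended before the transform so
the filter does not wrap the scan edges — without this, filtering and
time-shifting fail to commute at the edges and the lag search acquires a
~0.2 s bias). The reference is the cerebellar mean time course. The
voxel-wise GLM uses 14 columns: intercept, reference, six band-pass
filtered motion parameters and their squares (squared after filtering).
The voxel's temporal mean is kept (the pass-band includes 0 Hz), so the
intercept β₀ estimates baseline signal and CVR = β₁/β₀ is meaningful;
voxels with β₀ at or below 10% of the within-mask median get CVR = 0
(β₀ guard). β₀, β₁ and CVR maps are Z-scored within the brain mask
(population SD). BAT is the shift in [−9, +9] s (0.1 s grid) maximizing
the full model's R²; the reference is evaluated at fractionally shifted
times via cubic spline, rows where the shifted reference would be
extrapolated are dropped, ties resolve to the smallest |shift| then the
more negative one, and window-boundary optima are flagged. The regression
residual 4D series is retained.

## Hypercapnic reference (HC)

The EtCO₂ recording is aligned to the cerebellar time course by exhaustive
cross-correlation over ±30 s (0.1 s grid) — the recovered lag is the
transit delay. The voxel GLM uses intercept, mean-zero linear drift, and
the aligned EtCO₂; absolute CVR is the baseline-referenced formula

    CVR = 100 · β₁ / (β₀ + bEtCO₂ · β₁)   [%/mmHg]

(bEtCO₂ estimated as the mean over marked room-air blocks), which differs
from β₁/β₀ exactly by the factor β₀/(β₀ + bEtCO₂·β₁) and expresses the
response relative to the room-air baseline state. Non-positive
denominators yield CVR 0 and are counted. HC BAT reuses the lag search over
[−10, +30] s with the drift covariate — the wider window reflects the
minute-long CO₂ bolus. Labels for training are the Z-scored HC maps clipped
to [−5, 5] (clipped fraction reported; well under 1% on simulated data)
and zero-padded in-plane to multiples of 2⁴ (91×109 → 96×112).

## Supplementary features

For each atlas region, the spatial mean of the residual series is the
reference for a zero-lag Pearson correlation map over brain voxels;
the Z-scored stack (one channel per region, ascending label id) is the
supplementary network input. ROI means are taken over the intersection of
each label with the brain mask; empty labels and zero-variance references
degrade to zero maps with warnings.

## Network

Two structurally identical U-Net-style encoders with separate weights
(primary: the 3 GRRS Z-maps; supplementary: the N correlation maps), five
blocks each (conv3×3–ReLU–BN twice, then 2×2 max pooling; channels double,
dims halve). The fifth block omits pooling and acts as the bottleneck so
that four decoder blocks (2×2 stride-2 transpose conv, concatenation of the
primary encoder's pre-pool features, conv–ReLU–BN twice) restore input
resolution exactly — five poolings could not be undone by four upsamplings.
The bottlenecks of both encoders are concatenated before each of two
identical-architecture decoders (CVR and BAT); each head is a 1×1
convolution into 5·tanh, bounding outputs to the label range [−5, 5].
Skip connections come from the primary encoder (from the supplementary one
when the primary is ablated). Channel widths are base·2^level with
base 32 by default (config-exposed; the cohort studies use base 8).

The tensor engine is a compact NumPy implementation (float32, NCHW) with
hand-written backprop: convolutions as kernel-offset loops over BLAS
tensordots, standard batch-norm statistics (momentum 0.1), max-pool ties
sharing gradient equally. Gradients verify against central finite
differences to ~1e−6 relative in float64. Training minimizes mean absolute
error over both output channels with AdaBelief (defaults lr 5×10⁻⁵,
ε 1×10⁻¹², batch 64, 100 epochs); flip augmentation (horizontal + vertical,
inputs and labels jointly) is applied to patient cohorts only. Fold
assignment is subject-level, stratified by cohort. Everything is seeded;
two runs with the same seeds produce identical loss histories.

## Evaluation

Pearson correlation over in-mask voxels; SSIM (uniform 7-pixel windows over
the mask bounding box, sample covariance, C₁=(0.01L)², C₂=(0.03L)²); PSNR
defined as 10·log₁₀(max(pred)²/MSE) with the maximum over the *predicted*
map — an intentionally asymmetric convention; RMSE in map units.
Reliability is ICC(2,1) (two-way random effects, absolute agreement,
single measurement; pingouin, F-based CI) over atlas-ROI values pooled
across subjects. Lesion contrast uses mirrored-control ROIs (flip about the
x mid-plane, intersected with the brain mask) and Cohen's d with pooled SD.
Bland-Altman reports bias, 1.96·SD limits and a difference-vs-mean trend
slope. Bootstrap R² resamples pairs (default N = 10,000, percentile CI).
Multiplicity control is Benjamini-Hochberg (statsmodels). The
regional-covariate helper (e.g. aging analyses) normalizes ROI values by a
reference region, regresses on the covariate per ROI, and applies BH-FDR.

## Cohort studies (scaled)

`hemomap.studies.run_method_comparison_study` reproduces the central
experimental questions at desk scale: 16 subjects (25% with lesions),
32×40×12 grid, 150 resting frames, 210 hypercapnic frames, 6 mm smoothing,
stratified 4-fold split with one validation fold, network base width 8,
AdaBelief lr 1×10⁻³, batch 16, 60 epochs (at these sample sizes the
full-scale default learning rate is far from converged within a CPU
budget). It reports, for validation subjects only: per-subject Pearson
correlation of DLRS, ablated-DLRS and GRRS maps with the HC labels;
and test-retest ICC (DLRS vs GRRS) from an independently simulated second
resting run per subject. Expected qualitative readings, mirrored from the
full-scale experiment: DLRS > GRRS agreement with HC for both parameters,
markedly higher DLRS ICC, and no improvement from ablating the
supplementary encoder.

## Numerical choices and degenerate inputs

Population (1/n) SD for all Z-scoring; Z of a Z-map is itself. Constant
maps Z-score to zeros with a warning. Rank-deficient designs (e.g. all-zero
motion) fall back to the pseudo-inverse. R² is clipped to [0, 1] and
defined 0 for zero-variance windows. Lag-search candidate grids are built
as `lo + k·step` rounded to 1 µs to avoid float drift. Odd padding puts the
extra voxel on the high-index side and records the pad in map metadata for
exact inversion. Two empty masks have Dice 1 (with warning). The simulator
quantizes arrival delays to 10 ms for table-based spline evaluation.

## Known limitations

The NumPy engine is CPU-only and slower than a GPU framework; full-scale
(232-subject, full-MNI) training is out of reach here, so all network
results are at simulation scale. DLRS outputs are relative (Z-scale) maps,
not absolute %/mmHg. The simulator's linearity means nonlinear vascular
saturation, dispersion of the bolus, and neural-activity confounds are not
represented. The alignment search assumes a single global EtCO₂ lag.
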