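# Methods

## Problem and model

NOE/CEST imaging at ultra-high field samples the normalized water signal
Z(Δω) = M_Z(Δω)/M_Z0 while a saturation pulse train is swept over offsets
Δω near the water resonance. Saturation transfer from distinct proton pools
carves overlapping dips into this Z-spectrum. This package decomposes each
voxel's spectrum into five Lorentzian pools,

    Z(Δω) = Z_Base − Σ_i L_i(Δω),
    L_i(Δω) = A_i (Γ_i²/4) / (Γ_i²/4 + (Δω − δ_i)²),

with the baseline Z_Base fixed at 1 (normalization against a 100 ppm
reference acquisition puts measured spectra on this scale, and the far
off-resonance reference is treated as fully unsaturated). The five pools
and their nominal centers are direct water saturation (DS, 0 ppm),
semi-solid magnetization transfer (MT, −2 ppm), amide (+3.5 ppm), amine
(+2.2 ppm) and relayed NOE (rNOE, −3.5 ppm). The model-free companion
metric is NOE_MTR = (S₀ − S(−3.5 ppm))/S₀ × 100.

The scientific use case is a cross-sectional multiple-sclerosis study:
fitted pool-amplitude maps are averaged over tissue ROIs (whole brain, GM,
WM, lesions) per subject and compared between 15 MS subjects and 10 healthy
controls, with lesioned white matter compared against normal-appearing WM
(NAWM) and control WM.

## Pipeline and numerical choices

Order of operations is fixed: denoise → normalize → B0 estimate/correct →
fit → B1 correct → segment → ROI statistics.

* **Denoising** is a pluggable hook (`none` default, `gaussian` separable
  spatial smoothing per offset image, external plugins registerable).
  Spatio-spectral filters of the BM4D family are intentionally out of
  scope; the hook is where one would attach them.
* **Normalization** divides each offset image by the 100 ppm reference
  image; voxels with reference signal ≤ a floor (default 1e-6) are masked.
* **B0 mapping** uses the WASSR series (−1..+1 ppm, 0.1 ppm steps): a
  second-order polynomial is fit to the 5 samples around the discrete
  minimum (window clipped at grid edges) and the vertex abscissa is the
  water center. A 5-point window stabilizes the parabola against noise.
  Degenerate voxels are flagged: minimum on the grid edge → edge offset
  returned; downward-opening fit or vertex escaping the window → discrete
  argmin returned. For the phantom's 0.5 ppm WASSR linewidth the noiseless
  vertex bias is ≤ 0.008 ppm over |B0| ≤ 0.5 ppm (contract: ≤ 0.02 ppm).
* **B0 correction** resamples each spectrum at (nominal offsets + shift)
  with a piecewise-cubic interpolant on the 0.2 ppm grid and regrids onto
  the nominal axis. Samples that fall outside the acquired range are filled
  with the nearest edge value and *flagged*; the fitter excludes flagged
  samples from its residual. This matters: edge fills are not measurements,
  and keeping them biases the rNOE and MT amplitudes by ~2% at |B0| up to
  0.3 ppm, while excluding them restores sub-1% full-chain recovery.
* **Fitting** minimizes the residual between the observed spectrum and
  1 − ΣL_i by bounded trust-region least squares with an analytic Jacobian
  (the bounded analogue of Levenberg–Marquardt on the identical objective).
  Defaults: DS A∈[0,1] (init 0.8·(1−min Z)), Γ∈[0.3,10] init 2, δ∈[−0.2,0.2];
  MT A∈[0,0.5] init 0.1, Γ∈[10,60] init 25, δ fixed at −2 (a broad pool's
  center is not identifiable from a ±5 ppm window); amide A∈[0,0.3] init
  0.05, Γ∈[0.4,3] init 1, δ∈[3.4,3.6]; amine A∈[0,0.3] init 0.03,
  Γ∈[0.4,4] init 1.5, δ∈[2.1,2.3]; rNOE A∈[0,0.5] init 0.1, Γ∈[1,5] init 3,
  δ∈[−3.7,−3.3]. Narrow center windows let the sharp pools float without
  absorbing residual B0 error into amplitudes. Solver tolerances default to
  1e-12 (ftol/xtol/gtol), max 400 evaluations. The reference point is never
  part of the residual. QC: voxels that fail to converge or whose residual
  norm exceeds 5× the in-mask median are excluded from ROI statistics.
  Volume fits are embarrassingly parallel (joblib) with outputs written in
  voxel order, so results are independent of worker count.
* **B1 correction** is first order: fitted amplitudes are divided by the
  voxel's relative transmit amplitude (clip to [0,1]; voxels with B1 < 0.3
  masked). It is applied to fitted amplitudes, not raw spectra, mirroring
  the phantom's multiplicative saturation-efficiency model so the chain is
  self-consistent and recovery-testable; a two-point calibration variant
  could be slotted in behind the same interface.
* **Segmentation** thresholds the T1 map: WM < 1450 ms < GM < 2600 ms < CSF
  (brackets the tissue T1 priors; lesion T1 ≈ 1600 ms falls in the GM range,
  which is why lesion masks — manual segmentations in a real study — are
  inputs that override the T1 labels). "Whole brain" is GM ∪ WM, excluding
  CSF, including lesions for MS subjects.
* **Statistics**: Welch (unequal-variance) two-sample t-tests by default
  (a pooled switch exists); age/sex-adjusted OLS with group as the primary
  predictor for whole-brain and GM contrasts; the three WM pairwise tests
  (control WM / NAWM / lesion) with Bonferroni family size 3,
  adjusted p = min(1, 3p), not corrected across contrasts; MS-only simple
  regressions of each contrast on disease duration and in-slab lesion
  volume; percent change reported as 100·(comparison − reference)/reference.
  α = 0.05 throughout. Degenerate inputs have defined behavior: two
  zero-variance equal groups give t = 0, p = 1; a constant outcome gives
  slope 0 with R² reported as 0; rank-deficient designs raise with the
  collinear columns named.

## The phantom: what it emulates and what it does not

The generator produces a desk-scale emulation of a 7T NOE exam (default
64×64×10 voxels of 1×1×2 mm; cohort runs in the tests and acceptance script
use 24×24×4 voxels of 2.5×2.5×5 mm, preserving the 20 mm effective slab and
realistic tissue volumes, so WM holds ≈17.5 cm³ and the drawn lesion loads
fit). Anatomy is concentric: WM core, GM ring, CSF ring; lesions are
quasi-spherical regions carved from WM voxels nearest uniformly drawn WM
seeds, with the voxel count matched exactly to the subject's drawn in-slab
lesion volume (1.2 ± 1.4 cm³, truncated at 0).

Pool amplitudes are drawn hierarchically: subject-level tissue means from
group×tissue priors (truncated normal, by resampling so means are
preserved), then voxel jitter (SD 0.003, clipped to [0,1]). The priors
encode the published group summaries where printed — control WM
rNOE 0.114±0.014, amine 0.039±0.007, DS 0.655±0.021, T1 1154.6±31.7 ms;
NAWM 0.101±0.007 / 0.033±0.006 / 0.660±0.009 / 1197.3±31.8 ms; lesion
0.076±0.019 / 0.032±0.007 / 0.703±0.040 / 1600.7±269.7 ms; GM rNOE
0.094±0.012 (control) and 0.085±0.012 (MS). MT and amide amplitudes, GM
DS/MT/amide/T1 and all CSF values are not published numerically; the
defaults (MT 0.10±0.02 with Γ = 25 ppm, amide 0.05±0.01, GM T1 ≈ 1950 ms,
CSF T1 ≈ 3500 ms with near-zero solute pools) are this package's choices,
tunable in `TissueParamPrior`. Generative linewidths are fixed per pool
(DS 2, MT 25, amide 1, amine 1.5, rNOE 3 ppm).

Demographics follow the emulated cohort: 15 MS (age 43.7±14.7 y truncated
to 21–70, 10F:5M, duration 6.5±6.6 y truncated at 0) and 10 controls
(40.9±16.9 y on 23–71, 5F:5M). An optional coupling adds
24.34 ms × duration to the lesion T1 prior mean (off by default), matching
the published lesion-T1/duration slope, for regression-recovery tests.

Fields and noise: B0 is a random smooth second-order polynomial bounded by
0.3 ppm; B1 a smooth field in [0.7, 1.15] acting multiplicatively on pool
amplitudes before synthesis (first-order saturation-efficiency model).
Noise is additive Gaussian on normalized Z (SD 0.002, the high-SNR
normalized regime) — not Rician on magnitude. The WASSR series is a
DS-only line (amplitude 0.85, FWHM 0.5 ppm — a typical low-power
linewidth) at the voxel's water center. Ground truth (labels, per-voxel
amplitudes, fields, subject tissue draws) is stored losslessly so the
generator doubles as the recovery oracle. A fixed seed determines the
entire cohort bit-for-bit.

Not emulated: pulse-level Bloch–McConnell exchange (spectra come directly
from the Lorentzian forward model, so model misspecification of real
exchange lineshapes is outside what recovery tests can show), realistic
anatomy templates, motion/drift, Rician magnitude noise, MT asymmetry.
Passing recovery tests therefore demonstrate the *pipeline's* correctness
under its own generative assumptions, not the biological fidelity of the
five-pool description.

## Known limitations and open choices

* The NOE_MTR level of the phantom (~26% in WM) is lower than published
  in-vivo values (~36%) because the unprinted MT amplitude default is
  conservative; group *differences*, which the analysis targets, are
  governed by the printed priors.
* At the emulated cohort size (15 vs 10), the sampling SD of the
  NAWM-vs-control-WM rNOE percent-change estimate under the printed priors
  is ≈ 3.8 percentage points; single-cohort results scatter accordingly and
  only converge near the published −11.4% at much larger n.
* Whether B1 correction should act on raw images or fitted amplitudes is
  not standardized; this package corrects fitted amplitudes (documented
  above), which is exact under its own generative model.
* The −3.5 ppm sample used by NOE_MTR is not a grid point of the −5..+5 by
  0.2 ppm acquisition; maps interpolate it cubically (error ≲ 0.05
  percentage points on smooth spectra), while closed-form evaluations use
  the exact model value.
* Acquisition-grid sizes, tolerances, bounds and priors are all carried in
  dataclass configs (`PhantomSpec`, `FitConfig`, `PreprocessOptions`) and
  recorded next to outputs; nothing is hard-coded in the pipeline path.
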