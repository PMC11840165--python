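# noemri

Five-pool Lorentzian Z-spectrum analysis of NOE/CEST brain MRI, with a
digital phantom for validation and the tissue-stratified group statistics
of a multiple-sclerosis imaging study.

Saturation-transfer (CEST/NOE) imaging sweeps a saturation pulse over
frequency offsets Δω near the water resonance and records the normalized
water signal Z(Δω) = M_Z/M_Z0 — the Z-spectrum. Distinct proton pools carve
overlapping Lorentzian dips into it. This package decomposes each voxel's
spectrum as

    Z(Δω) = 1 − Σᵢ Lᵢ(Δω),   Lᵢ(Δω) = Aᵢ (Γᵢ²/4) / (Γᵢ²/4 + (Δω − δᵢ)²)

into direct water saturation (DS, 0 ppm), semi-solid magnetization transfer
(MT, −2 ppm), amide (+3.5 ppm), amine (+2.2 ppm) and relayed nuclear
Overhauser effect (rNOE, −3.5 ppm) pools, plus the model-free metric
NOE_MTR = (S₀ − S(−3.5 ppm))/S₀ × 100. It is aimed at researchers analyzing
volumetric 7T NOE exams of MS and control cohorts: voxel-wise bounded
nonlinear least squares produces pool-amplitude maps; WASSR-based B0
correction and a first-order B1 correction handle field inhomogeneity;
T1-based segmentation (with manual lesion masks as inputs) defines ROIs;
Welch t-tests, age/sex-adjusted regressions, Bonferroni-corrected pairwise
WM comparisons and clinical-covariate regressions produce a tidy results
table.

Because subject-level data of such studies are rarely deposited, the
package ships a first-class synthetic cohort generator (`noemri.phantom`)
whose priors encode the published group means and demographics, with
lossless ground truth for parameter-recovery testing.

## Worked example

```python
import numpy as np
from noemri import (FivePoolParams, POOL_FWHMS, main_axis, zspectrum_forward,
                    fit_voxel, noe_mtr, percent_change, zspectrum_eval)

# healthy white matter: published amplitudes, nominal linewidths
amps = {"DS": 0.655, "MT": 0.10, "amide": 0.05, "amine": 0.039, "rNOE": 0.114}
params = FivePoolParams.from_dicts(amps, POOL_FWHMS)

z = zspectrum_forward(main_axis(), params)       # 51-point Z-spectrum, −5..+5 ppm
res = fit_voxel(z)                               # five-pool decomposition
print("fitted rNOE amplitude:", round(res.params["rNOE"].amplitude, 4))
print("residual norm:", f"{res.residual_norm:.2e}")
print("NOE_MTR (%):", round(noe_mtr(1.0, zspectrum_eval(-3.5, params)), 2))
print("NAWM vs control-WM rNOE change (%):", round(percent_change(0.114, 0.101), 1))
```

prints

```
fitted rNOE amplitude: 0.114
residual norm: 8.05e-16
NOE_MTR (%): 26.29
NAWM vs control-WM rNOE change (%): -11.4
```

The fitter recovers the generating rNOE amplitude exactly on a noiseless
spectrum (residual at machine precision), the NOE_MTR value is the summed
pool deficit at −3.5 ppm, and the percent-change of the published WM group
means reproduces the reported −11.4% rNOE deficit in normal-appearing
white matter.

A full simulated cohort runs from the shell:

```sh
noemri simulate --seed 7 --out cohort/            # phantom subjects (NIfTI + CSV)
noemri fit --subject cohort/MS-01 --subjects-csv cohort/subjects.csv --out fits/MS-01
noemri stats --roi-tables fits/ --out stats.csv
noemri run-all --seed 7 --out run/                # all three stages chained
```

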