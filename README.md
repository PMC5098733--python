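# pdtmri

Multi-parametric quantitative MRI analysis of tumor response to
vascular-targeted therapy (e.g. photodynamic therapy, PDT), with a digital
tumor phantom for ground-truth validation.

Preclinical therapy-response studies acquire four quantitative series per
subject and timepoint and reduce them to tumor-level readouts. `pdtmri`
implements that whole chain for researchers running (or simulating) such
studies:

- **B1 / flip-angle correction** from a 180°-signal-null series:
  S = |a·FA_n + b|, ζ = −(a/b)·180°, actual angle FA_a = ζ·FA_n;
- **T1 mapping** from a variable-flip-angle spoiled gradient echo,
  S ∝ sin α·(1−E1)/(1−E1·cos α), E1 = exp(−TR/T1), with R1 = 1/T1;
- **T2 mapping** from a multi-echo series, S ∝ exp(−TE/T2);
- **ADC mapping** from multi-b-value diffusion, S ∝ exp(−b·ADC), averaged
  over three orthogonal directions;
- **DCE-MRI**: dynamic signal → R1(t) → concentration via
  R1(t) = R1,pre + r1·[CA]; area under the curve; the standard
  Tofts-Kermode model Ct(t) = K^trans ∫ Cp(τ)·e^(−K^trans(t−τ)/v_e) dτ with
  a bi-exponential population AIF (A1 = 5.36 mM, A2 = 1.27 mM,
  τ1 = 5.36 s, τ2 = 915 s), fitted voxelwise for K^trans and v_e;
- **enhancement classification** (median post-injection concentration vs
  2× pre-contrast SD) and **QC filters** (enhanced, R² > 0.80, peak before
  800 s, 0 ≤ K^trans, 0 ≤ v_e ≤ 1);
- **cohort statistics**: tumor volume, ROI summaries, non-enhanced tumor
  fraction, and Levene-gated independent / paired two-tailed t-tests.

Every estimator is a Model class whose `fit()` returns a Results object
with parameter maps, fit diagnostics and a `summary()`; the phantom module
generates all four acquisitions from known ground truth, applies a
parametric treatment effect (non-enhanced tumor core, reduced K^trans, late
ADC/R1/R2 changes), and adds Gaussian or Rician noise. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from pdtmri import (VoxelGrid, AcquisitionProtocol, build_phantom,
                    DEFAULT_EFFECTS, analyze_subject, compute_fluence,
                    ROIMask, roi_summary, tumor_volume,
                    simulate_echo_series, MultiEchoT2Model)

compute_fluence(200.0, 600.0)          # light dose: 200 mW/cm2 x 10 min
# 120.0                                # -> 120 J/cm2

grid = VoxelGrid(32, 32, 8, dx_mm=40/32, dy_mm=40/32)
gt = build_phantom(grid, seed=7)       # tumor/muscle/skin + B1 field
protocol = AcquisitionProtocol()       # 7 T small-animal defaults

res = MultiEchoT2Model(simulate_echo_series(gt, protocol)).fit()
print(res.summary())
# T2 (multi-echo) fit
#   valid voxels: 6272/8192
#   ms: median 25, IQR [25, 30]
#   median R^2: 1.0000

roi = ROIMask(grid, gt.tumor_mask)
s = roi_summary(res.t2_map, roi)
print(f"tumor T2 = {s.mean:.1f} +/- {s.sd:.1f} ms over n = {s.n} voxels")
print(f"tumor volume = {tumor_volume(roi):.1f} mm^3")
# tumor T2 = 40.0 +/- 0.0 ms over n = 1208 voxels
# tumor volume = 2076.3 mm^3

# end-to-end DCE arm: simulate, map, classify, summarize
base    = analyze_subject(seed=7, grid=grid, snr=50.0)
treated = analyze_subject(seed=7, effect=DEFAULT_EFFECTS["24h"],
                          grid=grid, snr=50.0)
print(f"baseline non-enhanced fraction: {base.nonenhanced_fraction:.3f}")
print(f"24 h non-enhanced fraction:     {treated.nonenhanced_fraction:.3f}")
# baseline non-enhanced fraction: 0.000
# 24 h non-enhanced fraction:     0.770
```

The fraction of tumor voxels without significant contrast uptake is the
vascular-shutdown readout: near 0 before treatment, and recovering the
simulated 77% non-enhanced core a day after therapy.

A command-line interface mirrors the library
(`pdtmri simulate | fit-b1 | fit-t1 | fit-t2 | fit-adc | fit-dce |
classify | summarize | compare | run-all`), reading 4D NIfTI stacks with
JSON sidecars and YAML configs, and writing NIfTI maps, tidy CSV cohort
tables and structured reproducibility logs.

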