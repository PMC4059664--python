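# mp2rage

Uniform and robust (β-regularized) combination of MP2RAGE brain images,
with a steady-state forward signal model, lookup-table T1 mapping, a
digital head phantom, and the evaluation metrics to compare the two
combinations. Intended for researchers working with quantitative
T1-weighted imaging at high field (7T) and for anyone who needs a fully
synthetic, ground-truthed MP2RAGE test bed.

## The problem and the method

The MP2RAGE sequence acquires two gradient-echo volumes (GRE_TI1, GRE_TI2)
at different inversion times within one cycle. The *uniform* T1-weighted
image is the real part of their normalized complex ratio,

    S = Re(conj(s1) · s2) / (|s1|² + |s2|²)  ∈  [−0.5, 0.5],

which cancels proton density, T2\*, receive-field (B1−) modulation and any
common phase exactly — but is numerically unstable where the signal
vanishes: in air, the random phase makes the background a uniform
salt-and-pepper spread over the full intensity range, which degrades
registration and automated segmentation.

The *robust* combination regularizes the ratio with a constant β in
squared-signal units:

    S_β = (Re(conj(s1) · s2) − β) / (|s1|² + |s2|² + 2β).

It reduces to the uniform image at β = 0, keeps the [−0.5, 0.5] range for
all inputs, and forces S_β → −0.5 wherever the signal power drops below β,
so the background becomes uniformly dark — darker than CSF — at the cost
of a small, signal-dependent intensity bias. `estimate_beta` selects
β = multiplier · σ̂² from a robust estimate of the background noise power.
Quantitative T1 maps are still derived from the *uniform* image by
inverting the forward-model intensity–T1 relation with a dense lookup
table.

## Worked example

```python
import numpy as np
from mp2rage import *

phantom = make_phantom((64, 64, 64), seed=0)       # nested-ellipsoid head
pair = simulate_acquisition(phantom, seed=1)       # default 7T protocol

beta = estimate_beta(pair)
uni = uniform_image(pair)
rob = robust_image(pair, beta)

bg = phantom.background_mask
print(f"auto beta = {beta:.3e}")
print("uniform background: mean %+.3f  std %.3f" % tuple(
    background_stats(uni, bg)[k] for k in ("mean", "std")))
print("robust  background: mean %+.3f  std %.3f" % tuple(
    background_stats(rob, bg)[k] for k in ("mean", "std")))

_, ratios = bias_ratio(rob, uni, phantom.brain_mask,
                       labels=phantom.labels, label_names={"wm": 3, "gm": 2, "csf": 1})
print("median robust/uniform ratio: wm %.3f  gm %.3f  csf %.3f"
      % (ratios["wm"], ratios["gm"], ratios["csf"]))

lut = build_lut(AcquisitionProtocol())
t1, valid = t1_from_uniform(uni.values, lut)
wm = phantom.masks["wm"]
print("T1 lookup: monotone range %.2f-%.2f s, median WM T1 = %.3f s"
      % (*lut.monotone_range, np.nanmedian(t1[wm])))
```

prints

```
auto beta = 7.218e-06
uniform background: mean -0.001  std 0.289
robust  background: mean -0.484  std 0.016
median robust/uniform ratio: wm 0.943  gm 1.034  csf 1.001
T1 lookup: monotone range 0.14-5.20 s, median WM T1 = 1.165 s
```

Reading: the uniform image's background is centered on 0 with a std of
0.289 = 1/√12 — the full-range uniform spread of pure-noise voxels — while
the robust image's background collapses to −0.484 ± 0.016, just above the
−0.5 floor. Inside the brain the robust image deviates from the uniform
one by ≤ 6% (median) in white matter, and CSF, lying near the −0.5 floor,
is almost unchanged. The median white-matter T1 recovered from the
uniform image (1.165 s) is close to the phantom's ground truth (1.2 s);
the residual bias comes from the simulated transmit-field (B1+)
inhomogeneity, which the default single-table lookup does not correct
(see `build_lut_2d`).

## Command line

```bash
mp2rage simulate --shape 64,64,64 --seed 7 -o scratch/phantom
mp2rage combine --inv1 scratch/phantom_inv1_mag.nii.gz --phase1 scratch/phantom_inv1_phase.nii.gz \
                --inv2 scratch/phantom_inv2_mag.nii.gz --phase2 scratch/phantom_inv2_phase.nii.gz \
                --mode robust --beta auto -o scratch/robust.nii.gz
mp2rage t1map   --uniform scratch/uniform.nii.gz -o scratch/t1.nii.gz
mp2rage evaluate --uniform scratch/uniform.nii.gz --robust scratch/robust.nii.gz \
                 --labels scratch/phantom_labels.nii.gz -o scratch/report.json
```

Each command logs the resolved parameters (including the effective β) to a
JSON sidecar next to its output.

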