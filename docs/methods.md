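# Methods

## Signal model

One MP2RAGE cycle is modeled as a fixed sequence of affine maps on the
longitudinal magnetization Mz (in units of M0): adiabatic inversion
Mz → −eff·Mz; free relaxation over a gap t, Mz → M0 + (Mz − M0)·e^(−t/T1);
and, for each of the n_readout low-flip excitations of a GRE train,
Mz → Mz·cos(α·B1+)·E + M0(1 − E) with E = e^(−TR_readout/T1). Because the
composition of affine maps is affine, the steady state is the closed-form
fixed point b/(1 − m) of the full-cycle map m·Mz + b — no iteration is
needed, and the whole model vectorizes over volumes. Transverse
magnetization history is ignored (perfect spoiling), the standard
approximation for spoiled GRE trains; RF pulse shapes and slice profiles
are not modeled.

The complex signal of each volume is read just before the excitation at
the center of its train (index n_readout/2), where the k-space center is
acquired under linear phase-encode ordering. Proton density, receive
field (B1−), T2\* decay e^(−TE/T2\*) and any global phase enter both
signals as one common complex factor, which the uniform combination
cancels exactly; the transmit field (B1+) scales the flip angles and does
not cancel.

Inversion efficiency follows the convention Mz → −eff·Mz: eff = 1 is a
perfect inversion and eff = 0 is saturation (Mz → 0), not identity.

### Timing and the inner-loop choice

The gap times are TA = TI1 − (n/2)·TR_readout, TB = TI2 − TI1 −
n·TR_readout, TC = TR_MP2RAGE − TI2 − (n/2)·TR_readout, all required
nonnegative. The default protocol (TR 6 s / TR_readout 6.5 ms / TE
2.89 ms, α 4°/5°, TI 0.8/2.7 s, matrix 256×240×176, voxel 1.0×1.0×1.2 mm)
takes **n_readout = 240**, i.e. the inner loop runs over the phase-encode
dimension. Vendor implementations differ in loop ordering and the choice
is not derivable from the protocol card; with n = 240 the uniform
intensity is strictly monotone in T1 over [0.13, 5.2] s, comfortably
covering the physiological range needed for lookup-table T1 mapping,
whereas with the partition dimension (n = 176) as inner loop the monotone
range ends near 4.3 s, too close to the CSF T1 of 4.0 s for reliable
inversion. Both ordering and the default inversion efficiency (0.96) are
exposed as protocol fields.

## Combination formulas and β selection

Uniform: S = Re(conj(s1)·s2)/(|s1|²+|s2|²); exact 0/0 voxels return 0 and
are flagged (NaNs would break downstream segmentation tools). Robust:
S_β = (Re(conj(s1)·s2) − β)/(|s1|²+|s2|² + 2β), the unique affine
regularization that reduces to the uniform form at β = 0, forces −0.5 at
zero signal, and preserves the [−0.5, 0.5] range. β is defined on squared
raw-signal units, so it is *not* invariant to global intensity rescaling:
robust(c·s, β) = robust(s, β/|c|²). The CLI logs the effective β for this
reason.

`estimate_beta` returns β = multiplier · σ̂², where σ̂² estimates the
per-channel noise variance from the lowest-intensity decile of the
combined power p = |s1|² + |s2|². On background voxels p follows σ²·χ²₄;
the lowest overall decile is that distribution's lower tail truncated at
an *unknown* quantile (it depends on the air fraction of the volume), so
no fixed median- or MAD-to-variance constant applies. Instead the
truncation point is taken as the observed subsample maximum c and σ²
solves median(sub) = σ²·median(χ²₄ | χ²₄ ≤ c/σ²), a monotone 1-D equation
solved by bisection. On the default phantom this recovers the generating
σ² to about 2%, and it returns exactly 0 on a noise-free volume.

The default multiplier is 60, calibrated once on the default phantom so
that the robust background mean lands within 0.05 of −0.5 and below the
CSF mean while the white-matter median bias stays below 10%; it scales β
linearly and is a CLI option.

## T1 lookup table

`build_lut` tabulates the uniform intensity over a T1 grid (default
0.1–6.0 s at 5 ms) with the forward model at B1+ = 1, then stores the
longest strictly monotone run. Run ends that abut a curvature reversal
are trimmed by one node, because the continuous extremum lies inside the
neighboring grid cell and intensities there may not be invertible.
Within the stored range, piecewise-linear inversion brackets every
intermediate T1 between its neighboring nodes, so the roundtrip error is
bounded by one grid step by construction. Out-of-range intensities are
flagged invalid (NaN), never silently clamped — they mark background or
inversion-artifact voxels; `clamp=True` overrides. A B1+-resolved list of
tables (`build_lut_2d`) is available for users with a measured transmit
map, selecting the nearest-B1 table per voxel; the default pipeline does
not use it.

## Phantom

A nested-ellipsoid head: skull-fat shell, subarachnoid CSF rim, cortical
GM ribbon, WM core with two CSF ventricles. Tissue values (T1 s / relative
PD): CSF 4.0/1.0, GM 1.85/0.8, WM 1.2/0.7, fat 0.6/0.9 — literature-typical
7T defaults, overridable per call. Labels are hard (exact ground-truth
masks for metrics); an optional Gaussian blur of the parameter maps adds
partial-volume realism without touching the masks. B1+ and B1− are sums of
four broad Gaussian bumps rescaled to the band [1−strength, 1+strength]
(defaults 0.25 / 0.30) and normalized to mean 1 over the brain. The
inversion-efficiency map is 0.96 with a smooth inferior dip to ≈ 0.67,
emulating the poor adiabatic coverage over the cerebellum at 7T.

Noise is i.i.d. complex Gaussian, drawn independently for the two volumes,
added in the image domain (equivalent to white k-space noise). The default
σ = 3.5×10⁻⁴ puts the WM second-inversion magnitude SNR near 100, a
high-SNR 7T whole-brain acquisition; the background (PD = 0) is pure
noise. All generation is deterministic per seed.

What the phantom does *not* emulate: real anatomy and partial-volume
mixtures, k-space sampling artifacts (ghosting, ringing), motion,
physiological noise, multi-channel coil combination, and susceptibility
or flow effects. Consequently, passing phantom tests demonstrates the
combination algebra, the noise-suppression mechanism and the T1-mapping
pipeline — not segmentation-grade realism.

### A note on two phantom-level expectations

Two qualitative expectations about this regime deserve care. First, for
i.i.d. complex Gaussian noise the uniform combination of pure-noise voxels
is *exactly* uniformly distributed on [−0.5, 0.5] (sample std 1/√12 ≈
0.289); the fraction of background voxels outside [−0.4, 0.4] is therefore
0.2 in expectation — the background does spread across the whole range,
but no more than that. Second, the spatial pattern of the robust-image
bias depends on where tissues sit on the intensity scale: the
robust/uniform ratio at uniform value u and power p is
(1 − β/(u·p))/(1 + 2β/p), which tends to 1 as u → −0.5. Under the default
protocol CSF (T1 = 4 s) lies at u ≈ −0.48, essentially the floor, so its
median ratio stays within ~0.1% of 1, while WM, sitting near its inversion
null (u ≈ +0.11), shows the largest relative change (~6% at the default
β). On real scans whose tissue intensities fall elsewhere on the scale,
the CSF bias can dominate instead.

## Metrics

Background statistics report mean, std, the spread fraction (voxels
outside the open interval (−0.4, 0.4); boundary-exclusive so a constant
−0.5 background counts as spread — the separate `above_fraction`, voxels
above −0.4, is the operational "not suppressed" statistic), per-tissue
bias-ratio medians (computed only where |uniform| > 10⁻³, since the
uniform image crosses zero inside the brain), tissue contrast means, and a
magnitude-threshold masking baseline. Volumetric reproducibility uses the
symmetric relative difference 100·|V1 − V2|/((V1+V2)/2) per structure,
with its mean and maximum (worst case) across structures; mean
normalization makes it symmetric in the repetitions, bounded by 200%, and
scale-invariant.

## Problem sizes and numerical choices

Tests and examples use 64³ phantoms (32³ for CLI end-to-end runs), T1
grids at 5 ms spacing, 10-seed Monte-Carlo checks, and 10⁶-sample range
checks; these sizes give sampling errors far below the asserted
tolerances while keeping the whole suite in seconds. Degenerate cases are
handled explicitly: 0/0 uniform voxels → 0 + flag, all-zero volumes →
β = 0 with a warning, geometric-series train composition guarded at
cos(α)·E → 1, empty masks and mismatched structure sets → errors.
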