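# Methods

This note documents the models, numerical choices and limitations of
`cestkit`, in the order data flow through the pipeline.

## Acquisition axis

The default saturation-offset axis reproduces a common preclinical CEST
protocol: −5 to +5 ppm with 0.2 ppm steps on [−5, −4] and [4, 5] and
0.1 ppm steps on [−4, 4], i.e. 91 unique offsets with fine sampling where
the 2, 3 and −3.5 ppm contrasts live. Axes are built from contiguous
arithmetic segments; shared endpoints are de-duplicated and overlapping
segments rejected. The WASSR axis defaults to ±1 ppm at 0.05 ppm steps —
the protocol being emulated does not document its WASSR sampling, so this
is the conventional choice, wide enough to bracket ±0.5 ppm field offsets.

## Z-spectrum model and fitting

The spectrum is modeled as `Z = 1 − Σ Lᵢ` with amplitude/FWHM Lorentzians
for water (0 ppm), semi-solid MT (−1 ppm), creatine (2 ppm), glutamate
(3 ppm) and NOE (−3.5 ppm).

Choices that the model family leaves open, and how they are fixed here:

- **Centers.** Solute/MT/NOE centers are fixed; the water center floats
  within ±0.2 ppm. Freeing all centers makes the five-pool problem poorly
  conditioned at realistic SNR; fixing them is the standard stabilizer,
  and residual B0 error is absorbed by the water term after correction.
- **Bounds.** Amplitudes in [0, 1); FWHM bounds (ppm): water [0.3, 4],
  creatine [0.3, 3], glutamate [0.3, 4], NOE [0.5, 6], MT [1, 20] (the MT
  line is intrinsically broad). All configurable per pool.
- **Initialization.** Water amplitude from `1 − min(Z)`; solute amplitudes
  0.02; linewidths at bound midpoints. Deterministic — no random
  restarts by default; an optional seeded multi-start exists for difficult
  data.
- **Objective.** Unweighted least squares; the mask enters as 0/1 weights,
  so masked points can never influence the fit. Solver:
  trust-region-reflective with an analytic Jacobian, ftol = xtol = gtol =
  1e-10, at most 500 function evaluations.
- **Preconditions.** A voxel needs at least `n_free + 2` unmasked points
  (13 with the default pool table) and values inside [−0.1, 1.2]; failures
  are flagged and skipped, never silently zeroed.

On noiseless data generated by the model itself the fit recovers all
amplitudes to better than 1e-4 with residual sum of squares below 1e-10
(tested), so the solver configuration is not a limiting factor.

Precision at realistic noise is information-limited: at σ = 0.005 on the
91-point axis, the Fisher information of the 11-parameter model puts the
creatine amplitude (A = 0.04, Γ = 1 ppm) at a standard deviation of
~0.0031, i.e. an expected median relative error of ~5.2%; the fitter
attains this bound, and the other three solutes sit at 3.5–4.5%. Nonlinear
least squares also carries a small O(σ²) amplitude bias (≈ +0.5% of A for
creatine), visible only across thousands of replicates.

## B0 correction

The WASSR spectrum's minimum is located by cubic-spline upsampling
(factor 100, giving 5·10⁻⁴ ppm resolution on the default axis) and argmin;
a minimum on the axis boundary, a flat spectrum, or an offset beyond the
configured bound (default 1 ppm) marks the voxel invalid. Each Z-spectrum
is then re-sampled at `axis + B0` with the same interpolant (linear below
5 points) and reported on the nominal axis. Offsets that fall outside the
measured range are masked rather than extrapolated; a shift that would
invalidate more than 20% of points rejects the voxel. The symmetry-based
center-frequency variant was considered and not used: at WASSR SNR the
interpolated argmin is accurate to ~0.002 ppm (tested at σ = 0.01) and is
simpler to reason about; the interpolant is swappable.

Whether the original analysis re-interpolated spectra or shifted the
fitted axis per voxel is not documented; spectrum re-interpolation is the
choice made here and is flagged as an assumption.

## Contrast

The per-pool contrast is the area under the fitted Lorentzian. The default
is the analytic full-line integral `A·π·Γ/2`, which is sampling-independent
and scale-consistent across pools of different linewidth. A numeric mode
integrates over a finite window (default the ±5 ppm acquisition window);
the two are linked exactly by the closed-form window fraction
`(arctan(2(b−δ)/Γ) − arctan(2(a−δ)/Γ))/π`. Lorentzian tails are heavy:
±100 ppm still misses ~0.64% of the Γ = 2 line's mass, a point worth
remembering when comparing windowed numbers across linewidths. Units are
ppm·(normalized signal); no percent scaling is applied. Heatmaps for
different arms share one color window and print the window and colormap in
the margin; rendering is byte-deterministic.

## Group statistics

Contrast maps are averaged over unmasked voxels per labeled region; empty
regions become missing rows. The comparison scheme per (region, pool) is:
ordinary one-way ANOVA across arms, pooled two-tailed t for baseline vs
the 6-week arm, Welch two-tailed t for baseline vs the 12-week vehicle arm
(unequal n), and a post-hoc two-tailed t for treated vs vehicle — pooled
by default, Welch behind a flag, since the design's wording leaves the
post-hoc variance model ambiguous. Arms are treated as independent groups
even though early timepoints re-scan the same animals; this matches the
analysis being mirrored, and a paired mode is available but off by
default. No multiplicity correction is applied by default (again
mirroring the design); Holm is available behind a flag. Zero-variance
situations produce explicit "degenerate" reports instead of NaNs.
Significance tiers are half-open bins: [0, 1e-4) "****", [1e-4, 1e-3)
"***", [1e-3, 0.01) "**", [0.01, 0.05) "*", [0.05, 0.1) "#", else "ns".

## Synthetic phantoms

The generator emulates the four-arm study the pipeline targets:

- **Arms and sample sizes.** baseline n = 14, 6 weeks post-infection
  n = 14, 12-week vehicle n = 5, 12-week treated n = 4.
- **Truth amplitudes.** Water 0.72, MT 0.08, creatine 0.04, glutamate
  0.05, NOE 0.06 at baseline (sum 0.95, keeping every noiseless spectrum
  positive). Arm effects mirror the studied phenomenology: creatine down
  15% in cortex/hippocampus at 6 weeks and 20% in four regions by 12 weeks
  untreated; glutamate down 20% in cortex/hippocampus/piriform (10%
  elsewhere) at 12 weeks untreated; NOE up 10–20% from 6 weeks onward in
  both 12-week arms; the treated arm restores glutamate and creatine.
- **Between-subject variation** is Gaussian jitter on region amplitudes
  with 5% coefficient of variation (no variance components are published
  for the design; 5% is a realistic biological CV and drives the power
  analyses).
- **Noise** is additive Gaussian on the normalized signal (σ = 0.005
  default). Z-spectra are high-SNR magnitude ratios, so Rician bias is
  negligible and deliberately not modeled.
- **B0 field** is a quadratic polynomial in normalized grid coordinates,
  bounded to ±0.5 ppm and shared by all subjects (one shim); the WASSR
  stack uses the same field. The WASSR line is A = 0.9, Γ = 0.3 ppm —
  low-power saturation still saturates water nearly completely on
  resonance while leaving solutes untouched.
- **Geometry.** Five disjoint rectangular "regions" on a 64×64 grid by
  default (32×32 with 6×6 blocks in the demo configuration). Anatomical
  fidelity is explicitly not a goal; the label structure is what the
  pipeline consumes.

What passing phantom tests does **not** show: robustness to motion,
partial-volume mixing at region borders, B1 inhomogeneity, Rician bias at
low SNR, or lineshapes that deviate from Lorentzian (true in vivo MT is
super-Lorentzian). Real-data claims need real data.

A table-level generator (`simulate_contrast_table`) draws per-subject
region contrasts directly from the truth (AUC × (1 + CV·N(0,1))) — the
region-level marginal the imaging chain estimates — so that calibration
studies with thousands of replicate tables are cheap. The type-I error of
the comparison scheme at α = 0.05 is nominal (rate 0.049 over 3000
tests), a 20% cortex glutamate drop in the n = 5 vehicle arm is detected
in ~100% of replicates, and the restored treated arm stays
non-significant vs baseline in ~95%.

## Bloch–McConnell oracle

An independent physics generator, used only for cross-checks: coupled
magnetization ODEs for exchanging pools (star topology around water,
detailed balance) under continuous-wave saturation, defaulting to 2 µT
for 2 s at 7 T. Because CW irradiation makes the system linear
time-invariant, it is propagated exactly by matrix exponential — no
step-size tolerance to tune. The readout train is not modeled. With zero
exchange the solute decouples and the water spectrum matches the
water-only system to machine precision; with rising solute fraction the
Lorentzian-fitted solute amplitude rises strictly, which is the property
that justifies using fitted amplitudes as concentration surrogates. Note
that fast-exchanging pools (glutamate amine at ~5000 s⁻¹) produce
exchange-broadened dips whose apparent maximum shifts toward water — the
Lorentzian amplitude remains monotone in fraction, but the line is not
centered exactly at the chemical shift.

## Pipeline and determinism

The end-to-end runner consumes a phantom directory (NIfTI stacks + CSV
offsets/tables + JSON metadata), applies B0 estimation/correction,
voxelwise fitting over labeled voxels, contrast mapping, aggregation and
statistics, and writes a manifest with SHA-256 checksums, library
versions and voxel counts. All data artifacts are byte-identical across
reruns with the same inputs; the echoed `config.yaml` records the
resolved output path, so runs written to different directories differ in
that one file only. Problem sizes used by the shipped demo (32×32 grid,
6×6 regions, 37 subjects, ~6700 voxel fits) complete in about half a
minute on one core; the full-voxel run of the test configuration (16×16,
3×3 regions, 8 subjects) in a few seconds.
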