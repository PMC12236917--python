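# cestkit

Quantification of chemical exchange saturation transfer (CEST) MRI
Z-spectra: WASSR B0 correction, five-pool Lorentzian decomposition, AUC
contrast mapping and region-of-interest group statistics, with a synthetic
phantom generator and a Bloch–McConnell physics oracle for validation.

## Who this is for

Preclinical CEST studies quantify brain metabolites — glutamate via its
3 ppm amine contrast, creatine via the 2 ppm guanidinium contrast, mobile
macromolecules via the relayed nuclear Overhauser effect (NOE) at
−3.5 ppm — by decomposing the normalized Z-spectrum `Z(Δω) = S(Δω)/S0`
into overlapping saturation pools and comparing region averages across
experimental groups and timepoints. `cestkit` implements that full chain
as a tested Python library with a thin CLI, for imaging scientists who
need a reproducible, inspectable alternative to one-off analysis scripts.

## The model

Each resonance is an amplitude/FWHM Lorentzian dip:

    Z(Δω) = 1 − Σᵢ Lᵢ(Δω),   Lᵢ(Δω) = Aᵢ (Γᵢ/2)² / ((Γᵢ/2)² + (Δω − δᵢ)²)

with five pools at fixed centers δ = 0 (direct water saturation),
−1 (semi-solid magnetization transfer), +2 (creatine), +3 (glutamate) and
−3.5 ppm (NOE); the water center floats within ±0.2 ppm to absorb residual
B0 error. Fitting is bounded trust-region least squares with an analytic
Jacobian. The per-metabolite contrast is the area under the fitted
Lorentzian, `AUC = A·π·Γ/2` (a windowed trapezoidal mode is also
provided). Before fitting, each voxel's B0 offset is read off the
interpolated minimum of a low-power water-only (WASSR) spectrum and the
Z-spectrum is re-referenced onto the nominal axis — points that would
require extrapolation are masked, never invented.

Group analysis mirrors a four-arm longitudinal design (baseline, 6 weeks
post-infection, 12 weeks vehicle, 12 weeks treated): one-way ANOVA across
arms plus pooled, Welch and post-hoc two-tailed t-tests, with significance
tiers (# p<0.1, * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001) and
mean ± SEM summaries.

## Worked example

`examples/02_fit_single_spectrum.py` simulates one noisy spectrum on the
91-point acquisition axis (−5…+5 ppm; 0.1 ppm steps in the core, 0.2 ppm
in the wings) and fits it:

```
converged: True   RSS: 1.751e-03

pool        center  A true   A fit  G fit     AUC
water        -0.00   0.720   0.710   1.40  1.5592
mt           -1.00   0.080   0.086   3.14  0.4216
creatine      2.00   0.040   0.037   1.25  0.0734
glutamate     3.00   0.050   0.046   1.18  0.0849
noe          -3.50   0.060   0.061   2.14  0.2044
```

Each row is one pool: fitted amplitude and linewidth against the generating
truth, and the AUC contrast in ppm·(normalized signal). At noise σ = 0.005
the solute amplitudes come back within a few percent — the Monte-Carlo
characterization in `tests/test_acceptance.py` quantifies this precisely.

The other examples cover phantom simulation (`01`), the WASSR round trip
(`03`, recovering a +0.2 ppm field offset to ±0.0001 ppm), the group
statistics suite (`04`) and the Bloch–McConnell cross-check (`05`).

The same stages are available from the shell:

```sh
cestkit simulate --out study/ --seed 0
cestkit run --input study/ --out results/
```

`results/` then holds the B0 map, per-pool parameter and contrast NIfTIs,
the tidy region-contrast table, test reports with tiers, heatmaps and bar
plots, and a manifest with SHA-256 checksums of every artifact.

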