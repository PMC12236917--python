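"""WASSR B0 estimation and Z-spectrum re-referencing, round trip.

Simulates a spectrum acquired under a +0.2 ppm field offset, locates the
offset from a paired WASSR scan, re-references the spectrum, and shows
that the fitted water line returns to 0 ppm.
"""

from cestkit.axis import default_axis, default_wassr_axis
from cestkit.b0 import correct_zspectrum, estimate_b0
from cestkit.lorentzfit import fit_zspectrum
from cestkit.pools import default_pools
from cestkit.synthetic import simulate_wassr, simulate_zspectrum

TRUE_B0 = 0.2
axis = default_axis()
waxis = default_wassr_axis()

pools = [p.with_values(amplitude=a, fwhm=g) for p, a, g in
         zip(default_pools(), (0.72, 0.08, 0.04, 0.05, 0.06),
             (1.4, 3.0, 1.0, 1.2, 2.5))]
z = simulate_zspectrum(pools, axis, b0_offset=TRUE_B0, noise_sigma=0.003, seed=1)
wassr = simulate_wassr(TRUE_B0, waxis, noise_sigma=0.003, seed=2)

b0_hat = estimate_b0(wassr, waxis)
print(f"true B0: {TRUE_B0:+.3f} ppm   estimated: {b0_hat:+.4f} ppm")

before = fit_zspectrum(z, axis).pool("water").center
zc = correct_zspectrum(z, axis, b0_hat)
after = fit_zspectrum(zc, axis).pool("water").center
print(f"fitted water center before correction: {before:+.4f} ppm")
print(f"fitted water center after  correction: {after:+.4f} ppm")
print(f"points dropped at the axis edge (never extrapolated): "
      f"{int((~zc.mask).sum())}")
print("\nA residual |center| well below 0.02 ppm means the CEST offsets are "
      "back on the nominal frequency axis.")
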