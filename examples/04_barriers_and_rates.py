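"""Bridge free-energy barriers and rates through the MFPT integral.

For 1-D diffusion with coefficient D on a barrier profile over [0, L], the
mean first passage time gives the rate for each barrier height; fitting
ln(rate) = ln(nu) - dF recovers the attempt frequency, and an observed rate
inverts to a barrier upper bound.
"""

import numpy as np

import landscape_bridge as lb

D = 0.06          # units^2/ns
SPAN = 22.0       # full coordinate change between endpoints (Angstrom)
bounds = lb.CoordinateBounds("tRNA-displacement", SPAN)

grid = np.arange(0.0, 20.5, 0.5)
curve = lb.rate_vs_barrier(D, bounds, x_ts_fraction=0.5, barrier_grid=grid)
print(f"flat-landscape rate 2D/L^2 = {2 * D / SPAN**2:.3e} /ns; "
      f"at 10 kT the rate drops to {np.interp(10, grid, curve.rates):.3e} /ns")

nu = lb.attempt_frequency(curve, fit_range=(8.0, 14.0))
print(f"attempt frequency nu = {nu.nu:.3e} /ns = {nu.nu * 1e9:.3g} /s "
      f"(ln-residual rms {nu.residual_rms:.3f})")

rate_obs = 5e-9  # 5 per second, a full-translocation scale, in /ns
barrier, flat = lb.invert_barrier(rate_obs, D, bounds)
print(f"observed rate {rate_obs * 1e9:.0f} /s -> barrier upper bound "
      f"{barrier:.1f} kT = {barrier * 0.596:.1f} kcal/mol")

rep = lb.robustness_scan(D, SPAN, 10.0, [0.2 * SPAN, 0.5 * SPAN, 0.8 * SPAN])
print(f"moving the transition state across the domain changes the rate by "
      f"x{rep.ratio_extremes:.1f} overall,")
print(f"but shifts the inferred barrier by only "
      f"{rep.max_shift_vs_reference_kt:.2f} kT relative to the symmetric "
      f"form (< 1 kT)")
# Because each translocation substep must be at least as fast as the whole
# process, the inverted barrier is an upper bound for every substep.
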