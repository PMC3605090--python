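"""Identify rigid core residues by iterative rmsf exclusion.

Builds a synthetic two-domain assembly in which 50 residues are internally
rigid (0.2 Å jitter) and 20 peripheral residues random-walk freely, then runs
the descending-threshold exclusion (5, 4, 3, 2, 1.5, 1 Å) and checks the
result against the generator's ground truth.
"""

import landscape_bridge as lb

spec = lb.AssemblySpec(
    n_fixed_core=50, n_moving_core=3, n_mobile=20,
    core_jitter_sigma=0.2, mobile_sigma=3.0,
    rotation_path=(0.0,) * 30, seed=4,
)
topology, trajectory, truth = lb.gen_assembly_trajectory(spec)

candidates = lb.select_residues(topology, "A:all")
core = lb.iterative_exclusion(
    trajectory, candidates,
    lb.ExclusionConfig(analysis_window_ns=None),
    region_label="demo",
)

print(f"candidates: {candidates.n_residues} residues "
      f"({len(truth.fixed_core_keys)} rigid + "
      f"{sum(1 for k in truth.mobile_keys if k[0] == 'A')} mobile planted)")
print("threshold (A)  removed  remaining")
for eps, removed, remaining in core.iteration_log:
    print(f"{eps:12.1f}  {removed:7d}  {remaining:9d}")
print(f"converged core: {core.n_members} residues, "
      f"max rmsf {max(core.final_rmsf.values()):.3f} A (< 1 A by construction)")
print("recovered exactly the planted rigid set:",
      set(core.members) == set(truth.fixed_core_keys))
# The audit log shows the mobile residues leaving as the threshold drops;
# every residue that survives fluctuates below the final 1 A cutoff.
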