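# End-to-end pipeline config for `landscape-bridge run --config pipeline.yml`.
# Generate matching inputs first, e.g.:
#   landscape-bridge simulate --kind assembly --seed 21 --out data/
# then point the paths below at the generated files plus two endpoint models.

topology_path: data/topology.pdb
trajectory_path: data/trajectory.pdb
classical_path: data/classical.pdb
rotated_path: data/rotated.pdb
time_step_ns: 1.0

fixed_candidates: "A:all"
moving_candidates: "B:all"

# descending rmsf thresholds (Å); first 1000 ns analysed at 1 ns sampling
threshold_schedule: [5, 4, 3, 2, 1.5, 1]
analysis_window_ns: 1000
sampling_stride: 1

# MSD fit: burst cutoff ~30 ns for rotation angles (~10 ns for tRNA distance)
burst_cutoff_ns: 30.0
msd_max_lag_ns: null      # default: 10% of the series span

temperature_k: 300.0

# Full coordinate change between translocation endpoints.  22 Å is the tRNA
# elbow-displacement span; the angular spans below are literature-scale
# placeholders, NOT study-derived values — set them for your system.
coordinate_span: 8.0      # degrees (body rotation placeholder)
x_ts_fraction: 0.5
barrier_grid_max_kt: 20.0
attempt_fit_range_kt: [8, 14]

# observed rate (per ns) to invert into a barrier upper bound; null to skip
observed_rate: 5.0e-9

out_dir: landscape_bridge_out
seed: 0
resume: false
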