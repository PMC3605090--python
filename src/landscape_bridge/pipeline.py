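"""End-to-end orchestration: cores → axes → angles → diffusion → rates.

The pipeline reads a single config (YAML file or :class:`PipelineConfig`),
executes the stages in order, and writes one machine-readable artifact per
stage into the output directory:

    cores.json       converged core sets with iteration logs
    axis.json        rotation-axis definition (pair, plane normal, reference)
    angles.csv       time series of the rotation coordinate
    diffusion.json   MSD fit, D, correlation coefficient, split-half shift
    kinetics.json    rate-vs-barrier curve, attempt frequency, inverted barrier
    report.json      versioned summary with units on every quantity

A stage whose artifact already exists is reloaded rather than recomputed when
``resume`` is set, so a failed run can be continued.  Failures halt with the
stage name; artifacts written so far are left in place.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cores as cores_mod
from . import diffusion as diff_mod
from . import kinetics as kin_mod
from . import rotation as rot_mod
from . import structures as struct_mod

__all__ = ["PipelineConfig", "run_pipeline"]

REPORT_SCHEMA_VERSION = 1

log = logging.getLogger("landscape_bridge.pipeline")


@dataclass
class PipelineConfig:
    """Inputs, stage parameters and defaults for a full analysis run.

    Defaults annotated "paper" in the emitted effective config are the study
    conditions (threshold schedule, 1 ns sampling, burst cutoff, 300 K, 22 Å
    tRNA span); the rest are artifact choices.
    """

    # inputs
    topology_path: str = ""
    trajectory_path: str = ""            # multi-model PDB
    classical_path: str = ""
    rotated_path: str = ""
    time_step_ns: float = 1.0

    # residue selections (text ranges per region)
    fixed_candidates: str = "A:all"
    moving_candidates: str = "B:all"

    # core exclusion
    threshold_schedule: tuple[float, ...] = cores_mod.DEFAULT_SCHEDULE
    analysis_window_ns: float | None = 1000.0
    sampling_stride: int = 1

    # diffusion
    msd_max_lag_ns: float | None = None  # default: 10% of span
    burst_cutoff_ns: float = 30.0
    fit_end_ns: float | None = None      # default: max lag
    split_half: bool = True

    # kinetics
    temperature_k: float = 300.0
    coordinate_span: float = 10.0        # full change between endpoints
    x_ts_fraction: float = 0.5
    barrier_grid_max_kt: float = 20.0
    attempt_fit_range_kt: tuple[float, float] = (8.0, 14.0)
    observed_rate: float | None = None   # per ns, optional barrier inversion
    profile_family: str = "piecewise_parabola"

    # run control
    out_dir: str = "landscape_bridge_out"
    seed: int = 0
    resume: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "threshold_schedule" in raw:
            raw["threshold_schedule"] = tuple(raw["threshold_schedule"])
        if "attempt_fit_range_kt" in raw:
            raw["attempt_fit_range_kt"] = tuple(raw["attempt_fit_range_kt"])
        return cls(**raw)

    def validate(self):
        for name in ("topology_path", "trajectory_path", "classical_path",
                     "rotated_path"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p}")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be > 0")

    def effective(self) -> dict:
        """Config as written to disk, with provenance tags on defaults."""
        paper_keys = {
            "threshold_schedule", "analysis_window_ns", "sampling_stride",
            "burst_cutoff_ns", "temperature_k",
        }
        out = {}
        for key, value in asdict(self).items():
            out[key] = {
                "value": value,
                "provenance": "paper" if key in paper_keys else "artifact",
            }
        return out


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage(name: str, out_path: Path, resume: bool, compute, load=None):
    """Run one stage with logging; reuse the artifact when resuming."""
    t0 = time.perf_counter()
    if resume and out_path.exists() and load is not None:
        log.info("stage %-10s reusing %s", name, out_path.name)
        return load(out_path)
    try:
        result = compute()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    log.info("stage %-10s done in %.2f s -> %s",
             name, time.perf_counter() - t0, out_path.name)
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the summary report dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(asctime)s %(message)s")

    topology = struct_mod.read_structure(config.topology_path)
    trajectory = struct_mod.read_trajectory(
        config.trajectory_path, time_step=config.time_step_ns)
    classical = struct_mod.read_structure(config.classical_path)
    rotated = struct_mod.read_structure(config.rotated_path)

    excl = cores_mod.ExclusionConfig(
        threshold_schedule=config.threshold_schedule,
        analysis_window_ns=config.analysis_window_ns,
        sampling_stride=config.sampling_stride,
    )

    # --- cores ---------------------------------------------------------
    def compute_cores():
        fixed_sel = struct_mod.select_residues(topology, config.fixed_candidates)
        moving_sel = struct_mod.select_residues(topology, config.moving_candidates)
        fixed = cores_mod.iterative_exclusion(
            trajectory, fixed_sel, excl, region_label="fixed")
        moving = cores_mod.iterative_exclusion(
            trajectory, moving_sel, excl, region_label="moving")
        _write_json(out / "cores.json", {
            region.region_label: {
                "members": [list(k) for k in region.members],
                "final_rmsf": {f"{c}:{r}": v
                               for (c, r), v in region.final_rmsf.items()},
                "iteration_log": [list(e) for e in region.iteration_log],
                "analysis_window_ns": region.analysis_window_ns,
            }
            for region in (fixed, moving)
        })
        return fixed, moving

    def load_cores(path: Path):
        raw = json.loads(path.read_text())
        out_sets = []
        for label in ("fixed", "moving"):
            entry = raw[label]
            out_sets.append(cores_mod.CoreSet(
                region_label=label,
                members=tuple((c, int(r)) for c, r in entry["members"]),
                final_rmsf={(k.split(":")[0], int(k.split(":")[1])): v
                            for k, v in entry["final_rmsf"].items()},
                iteration_log=tuple(tuple(e) for e in entry["iteration_log"]),
                analysis_window_ns=entry["analysis_window_ns"],
            ))
        return tuple(out_sets)

    fixed_core, moving_core = _stage("cores", out / "cores.json",
                                     config.resume, compute_cores, load_cores)

    # --- axis ----------------------------------------------------------
    def compute_axis():
        axis = rot_mod.find_max_rotation_pair(
            classical, rotated, moving_core, fixed_core, label="theta")
        _write_json(out / "axis.json", rot_mod.axis_to_dict(axis))
        return axis

    def load_axis(path: Path):
        return rot_mod.axis_from_dict(json.loads(path.read_text()))

    axis = _stage("axis", out / "axis.json", config.resume,
                  compute_axis, load_axis)

    # --- angles --------------------------------------------------------
    def compute_angles():
        series = rot_mod.angle_series(trajectory, axis)
        pd.DataFrame({"time_ns": series.times, "value": series.values}).to_csv(
            out / "angles.csv", index=False)
        return series

    def load_angles(path: Path):
        df = pd.read_csv(path)
        return rot_mod.AngleSeries(
            coordinate_label=axis.label,
            times=df["time_ns"].to_numpy(),
            values=df["value"].to_numpy(),
        )

    series = _stage("angles", out / "angles.csv", config.resume,
                    compute_angles, load_angles)

    # --- diffusion -----------------------------------------------------
    def compute_diffusion():
        span = series.times[-1] - series.times[0]
        max_lag = config.msd_max_lag_ns or 0.1 * span
        fit_end = config.fit_end_ns or max_lag
        tau_min = min(config.burst_cutoff_ns, 0.5 * fit_end)
        curve = diff_mod.msd_curve(series, max_lag)
        est = diff_mod.fit_diffusion(curve, tau_min, fit_end)
        payload = {
            "D": est.D, "units": est.units, "tau_min_ns": est.tau_min,
            "tau_max_ns": est.tau_max, "slope": est.slope,
            "intercept": est.intercept, "corr_coeff": est.corr_coeff,
            "flags": {"floored": est.floored,
                      "low_correlation": est.low_correlation,
                      "non_diffusive": est.non_diffusive},
        }
        if config.split_half:
            try:
                e1, e2, shift = diff_mod.split_half(series, tau_min,
                                                    0.5 * fit_end)
                payload["split_half"] = {
                    "D_first": e1.D, "D_second": e2.D,
                    "delta_barrier_kt": shift,
                }
            except ValueError as exc:
                payload["split_half"] = {"error": str(exc)}
        pd.DataFrame({
            "lag_ns": curve.lags, "msd": curve.msd,
            "n_pairs": curve.pairs_per_lag,
        }).to_csv(out / "msd.csv", index=False)
        _write_json(out / "diffusion.json", payload)
        return est, payload

    estimate, diff_payload = _stage("diffusion", out / "diffusion.json",
                                    False, compute_diffusion)

    # --- kinetics ------------------------------------------------------
    def compute_kinetics():
        if estimate.D <= 0:
            raise ValueError("cannot run kinetics with D = 0")
        bounds = kin_mod.CoordinateBounds(
            coordinate_label=series.coordinate_label,
            span=config.coordinate_span)
        grid = np.arange(0.0, config.barrier_grid_max_kt + 0.25, 0.5)
        curve = kin_mod.rate_vs_barrier(
            estimate.D, bounds, config.x_ts_fraction, grid,
            config.profile_family)
        nu = kin_mod.attempt_frequency(curve, config.attempt_fit_range_kt)
        payload = {
            "D": estimate.D,
            "span": bounds.span,
            "x_ts_fraction": config.x_ts_fraction,
            "family": config.profile_family,
            "attempt_frequency_per_ns": nu.nu,
            "attempt_fit_residual_rms": nu.residual_rms,
        }
        if config.observed_rate is not None:
            barrier, flat = kin_mod.invert_barrier(
                config.observed_rate, estimate.D, bounds,
                config.x_ts_fraction, config.profile_family)
            kt_kcal = diff_mod.BOLTZMANN_KCAL * config.temperature_k
            payload["barrier_upper_bound"] = {
                "observed_rate": config.observed_rate,
                "barrier_kt": barrier,
                "barrier_kcal_mol": barrier * kt_kcal,
                "no_barrier_required": flat,
            }
        pd.DataFrame({"barrier_kt": curve.barriers,
                      "rate_per_ns": curve.rates}).to_csv(
            out / "rates.csv", index=False)
        _write_json(out / "kinetics.json", payload)
        return payload

    kin_payload = _stage("kinetics", out / "kinetics.json",
                         False, compute_kinetics)

    # --- report --------------------------------------------------------
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "effective_config": config.effective(),
        "cores": {
            "fixed": {"n_members": fixed_core.n_members,
                      "max_final_rmsf_angstrom":
                          max(fixed_core.final_rmsf.values())},
            "moving": {"n_members": moving_core.n_members,
                       "max_final_rmsf_angstrom":
                           max(moving_core.final_rmsf.values())},
        },
        "axis": {"pair_angle_change_deg": axis.pair_angle_change},
        "diffusion": diff_payload,
        "kinetics": kin_payload,
    }
    _write_json(out / "report.json", report)
    return report
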