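"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import landscape_bridge as lb


def make_endpoint_models(spec: lb.AssemblySpec):
    """Noiseless classical/rotated endpoint models sharing the geometry of
    ``spec`` (same seed), rotated by the first/last path angle."""
    clean = lb.AssemblySpec(
        n_fixed_core=spec.n_fixed_core,
        n_moving_core=spec.n_moving_core,
        n_mobile=spec.n_mobile,
        core_jitter_sigma=0.0,
        mobile_sigma=0.0,
        rotation_path=(spec.rotation_path[0], spec.rotation_path[-1]),
        axis=spec.axis,
        seed=spec.seed,
        domain_extent=spec.domain_extent,
    )
    topo, traj, truth = lb.gen_assembly_trajectory(clean)
    classical = topo.with_coords(traj.coords[0], label="classical")
    rotated = topo.with_coords(traj.coords[1], label="rotated")
    return classical, rotated, truth


def truth_cores(truth: lb.AssemblyTruth):
    """CoreSets straight from generator ground truth (no exclusion run)."""
    moving = lb.CoreSet("moving", truth.moving_core_keys, {}, ())
    fixed = lb.CoreSet("fixed", truth.fixed_core_keys, {}, ())
    return fixed, moving


@pytest.fixture(scope="session")
def small_assembly():
    """A 60-residue two-domain assembly with a 10° linear rotation ramp,
    modest core jitter and a mobile periphery."""
    spec = lb.AssemblySpec(
        n_fixed_core=25,
        n_moving_core=25,
        n_mobile=10,
        core_jitter_sigma=0.2,
        mobile_sigma=3.0,
        rotation_path=tuple(np.linspace(0.0, 10.0, 60)),
        seed=42,
    )
    topo, traj, truth = lb.gen_assembly_trajectory(spec)
    return spec, topo, traj, truth


@pytest.fixture(scope="session")
def static_assembly():
    """Completely rigid, noise-free assembly (every frame identical)."""
    spec = lb.AssemblySpec(
        n_fixed_core=30,
        n_moving_core=30,
        n_mobile=0,
        core_jitter_sigma=0.0,
        mobile_sigma=0.0,
        rotation_path=(0.0,) * 10,
        seed=7,
    )
    return (spec, *lb.gen_assembly_trajectory(spec))


def make_chain_structure(chains: dict[str, int], label: str = "fixture"):
    """Complete chains with one P atom per residue, numbered 1..n."""
    chain_ids, res_nums, names = [], [], []
    for chain, n in chains.items():
        for r in range(1, n + 1):
            chain_ids.append(chain)
            res_nums.append(r)
            names.append("UAGC"[r % 4])
    n_atoms = len(chain_ids)
    rng = np.random.default_rng(1)
    return lb.Structure(
        chain_ids=chain_ids,
        residue_numbers=res_nums,
        residue_names=names,
        atom_names=["P"] * n_atoms,
        coords=rng.normal(scale=30, size=(n_atoms, 3)),
        label=label,
    )


def brute_force_mfpt(profile, D: float, n_grid: int = 10_000) -> float:
    """Independent dense-trapezoid double-sum oracle for the MFPT integral."""
    x = np.linspace(0.0, profile.L, n_grid + 1)
    f = profile.F(x)
    em = np.exp(-f)
    inner = np.concatenate(
        [[0.0], np.cumsum(0.5 * (em[1:] + em[:-1]) * np.diff(x))]
    )
    return float(np.trapezoid(np.exp(f) * inner / D, x))
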