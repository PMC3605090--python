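"""Synthetic inputs with known ground truth.

Two generators stand in for data that would otherwise require microsecond
all-atom simulation of a multi-million-atom system:

* a geometric multi-domain assembly — a jittered rigid "fixed" core, a rigid
  "moving" core following a prescribed rotation path about a known axis, and
  independently mobile peripheral residues performing Gaussian random walks —
  emulating the rigid-core-plus-flexible-periphery character of the ribosomal
  subunits (no attempt is made to mimic real rRNA geometry or sequence);
* one-dimensional overdamped (Euler–Maruyama) Langevin motion on a prescribed
  free-energy profile with known diffusion coefficient, realizing the
  diffusive-dynamics premise behind the MSD and MFPT machinery.

Every generator is deterministic per seed and returns its ground truth
(memberships, per-frame angles, D, first-passage samples) alongside the data,
so tests never have to re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .kinetics import FreeEnergyProfile
from .rotation import AngleSeries
from .structures import Structure, Trajectory

__all__ = [
    "AssemblySpec",
    "LangevinSpec",
    "AssemblyTruth",
    "HarmonicWell",
    "gen_assembly_trajectory",
    "gen_langevin",
    "sample_first_passages",
    "gen_fixture_pdb",
    "write_structure_pdb",
    "write_trajectory_pdb",
]

_NUC = ("U", "A", "G", "C")
#: heavy-atom names given to each synthetic residue (one P for pair searches)
_RES_ATOMS = ("P", "C1'")


@dataclass(frozen=True)
class AssemblySpec:
    """Geometry and noise of the synthetic two-domain assembly.

    ``rotation_path`` lists the moving core's rotation angle (degrees, about
    ``axis`` through the moving core's centroid) for every frame.  Jitter
    sigmas are per-axis Gaussian in Å.  Mobile residues random-walk with
    per-frame, per-axis step ``mobile_sigma``.
    """

    n_fixed_core: int = 30
    n_moving_core: int = 30
    n_mobile: int = 10
    core_jitter_sigma: float = 0.2
    mobile_sigma: float = 3.0
    rotation_path: tuple[float, ...] = (0.0, 10.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0
    time_step: float = 1.0  # ns between frames
    domain_extent: float = 30.0  # Å scale of each rigid domain

    def __post_init__(self):
        if min(self.n_fixed_core, self.n_moving_core) < 3:
            raise ValueError("core domains need at least 3 residues each")
        if self.n_mobile < 0:
            raise ValueError("n_mobile must be >= 0")
        if self.core_jitter_sigma < 0 or self.mobile_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if len(self.rotation_path) < 1:
            raise ValueError("rotation_path must have at least one frame")
        if abs(np.linalg.norm(self.axis)) < 1e-12:
            raise ValueError("axis must be non-zero")


@dataclass(frozen=True)
class AssemblyTruth:
    """Ground truth emitted next to a generated assembly trajectory."""

    fixed_core_keys: tuple[tuple[str, int], ...]
    moving_core_keys: tuple[tuple[str, int], ...]
    mobile_keys: tuple[tuple[str, int], ...]
    rotation_path: tuple[float, ...]  # degrees per frame
    axis: tuple[float, float, float]

    def as_dict(self) -> dict[str, Any]:
        return {
            "fixed_core": [list(k) for k in self.fixed_core_keys],
            "moving_core": [list(k) for k in self.moving_core_keys],
            "mobile": [list(k) for k in self.mobile_keys],
            "rotation_path_deg": list(self.rotation_path),
            "axis": list(self.axis),
        }


@dataclass(frozen=True)
class HarmonicWell:
    """F(x) = (κ/2)·(x − center)² in k_BT, on [0, L] — a confining potential
    for basin-dynamics studies (Boltzmann variance k_BT/κ, relaxation time
    1/(κD)).  Duck-type compatible with the Langevin integrator."""

    L: float
    center: float
    kappa: float  # k_BT per unit²

    def F(self, x):
        arr = np.asarray(x, float)
        out = 0.5 * self.kappa * (arr - self.center) ** 2
        return float(out) if np.ndim(x) == 0 else out

    def dF(self, x):
        arr = np.asarray(x, float)
        out = self.kappa * (arr - self.center)
        return float(out) if np.ndim(x) == 0 else out


@dataclass(frozen=True)
class LangevinSpec:
    """Overdamped 1-D Langevin run: profile (or flat), D, step and length.

    The step guard D·max|F′|·dt < 0.1·sqrt(2·D·dt) keeps the deterministic
    drift per step well below the thermal step, so the Euler–Maruyama
    discretization error is negligible against the statistical tolerances
    used downstream.
    """

    profile: FreeEnergyProfile | None  # None = flat, unbounded
    D: float
    dt: float       # ns per integration step
    n_steps: int
    x0: float = 0.0
    seed: int = 0
    reflecting: bool = True  # reflect at [0, L] when a profile is present

    def __post_init__(self):
        if self.D <= 0 or self.dt <= 0 or self.n_steps < 1:
            raise ValueError("D, dt must be > 0 and n_steps >= 1")
        if self.profile is not None:
            self._check_step_guard()

    def _check_step_guard(self):
        prof = self.profile
        xs = np.linspace(0, prof.L, 2001)
        max_grad = float(np.max(np.abs(prof.dF(xs))))
        drift_step = self.D * max_grad * self.dt
        noise_step = math.sqrt(2.0 * self.D * self.dt)
        if drift_step >= 0.1 * noise_step:
            # D·|F'|·dt = 0.1·sqrt(2 D dt)  =>  dt = 0.02 / (D·|F'|²)
            dt_max = 0.02 / (self.D * max_grad**2)
            raise ValueError(
                f"time step too large for drift-dominated-step guard: "
                f"use dt < {dt_max:.3g} ns"
            )


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)


def _domain_reference(rng: np.random.Generator, n_res: int, extent: float,
                      center: np.ndarray) -> np.ndarray:
    """Reference coordinates for a rigid domain: one site per residue spread
    uniformly in a cube, with the second atom offset ~1.6 Å from the P."""
    sites = rng.uniform(-extent / 2, extent / 2, size=(n_res, 3)) + center
    offsets = rng.normal(0.0, 1.0, size=(n_res, 3))
    offsets = 1.6 * offsets / np.linalg.norm(offsets, axis=1, keepdims=True)
    coords = np.empty((n_res * len(_RES_ATOMS), 3))
    coords[0::2] = sites
    coords[1::2] = sites + offsets
    return coords


def gen_assembly_trajectory(
    spec: AssemblySpec,
) -> tuple[Structure, Trajectory, AssemblyTruth]:
    """Generate the synthetic assembly: topology, trajectory, ground truth.

    Chain A holds the fixed core residues (numbered from 1) followed by half
    of the mobile residues; chain B holds the moving core residues and the
    remaining mobile residues.  Each residue carries a P and a C1' atom.
    The moving core is rotated about ``spec.axis`` through its own centroid
    by ``rotation_path[t]`` degrees at frame t, then jittered; mobile atoms
    accumulate independent Gaussian random-walk steps (untethered, so their
    rmsf grows without bound and cleanly separates from the cores).
    """
    rng = np.random.default_rng(spec.seed)
    n_f, n_m = spec.n_fixed_core, spec.n_moving_core
    n_mob_a = spec.n_mobile // 2
    n_mob_b = spec.n_mobile - n_mob_a
    n_frames = len(spec.rotation_path)

    fixed_ref = _domain_reference(rng, n_f, spec.domain_extent,
                                  np.array([0.0, 0.0, 0.0]))
    moving_center = np.array([spec.domain_extent * 1.5, 0.0, 0.0])
    moving_ref = _domain_reference(rng, n_m, spec.domain_extent, moving_center)
    mobile_ref = rng.uniform(-spec.domain_extent, spec.domain_extent * 2.5,
                             size=((n_mob_a + n_mob_b) * len(_RES_ATOMS), 3))

    # topology bookkeeping
    chain_ids, res_nums, res_names, atom_names = [], [], [], []

    def add_residues(chain: str, start: int, count: int):
        for r in range(count):
            for name in _RES_ATOMS:
                chain_ids.append(chain)
                res_nums.append(start + r)
                res_names.append(_NUC[(start + r) % 4])
                atom_names.append(name)

    add_residues("A", 1, n_f)
    add_residues("A", n_f + 1, n_mob_a)
    add_residues("B", 1, n_m)
    add_residues("B", n_m + 1, n_mob_b)

    na = len(_RES_ATOMS)
    fixed_slice = slice(0, n_f * na)
    mob_a_slice = slice(n_f * na, (n_f + n_mob_a) * na)
    moving_slice = slice((n_f + n_mob_a) * na, (n_f + n_mob_a + n_m) * na)
    mob_b_slice = slice((n_f + n_mob_a + n_m) * na, None)

    axis = np.asarray(spec.axis, float)
    axis = axis / np.linalg.norm(axis)
    centroid = moving_ref.mean(axis=0)

    n_atoms = len(chain_ids)
    coords = np.empty((n_frames, n_atoms, 3))
    mobile_pos = mobile_ref.copy()
    for t, ang in enumerate(spec.rotation_path):
        frame = np.empty((n_atoms, 3))
        frame[fixed_slice] = fixed_ref + rng.normal(
            0, spec.core_jitter_sigma, size=fixed_ref.shape)
        rot = _rotation_matrix(axis, ang)
        moved = (moving_ref - centroid) @ rot.T + centroid
        frame[moving_slice] = moved + rng.normal(
            0, spec.core_jitter_sigma, size=moving_ref.shape)
        if t > 0:
            mobile_pos = mobile_pos + rng.normal(
                0, spec.mobile_sigma, size=mobile_pos.shape)
        frame[mob_a_slice] = mobile_pos[: n_mob_a * na]
        frame[mob_b_slice] = mobile_pos[n_mob_a * na:]
        coords[t] = frame

    topology = Structure(
        chain_ids=chain_ids,
        residue_numbers=res_nums,
        residue_names=res_names,
        atom_names=atom_names,
        coords=coords[0],
        b_factors=np.zeros(n_atoms),
        label="synthetic-assembly",
    )
    traj = Trajectory(topology=topology, coords=coords, time_step=spec.time_step)
    truth = AssemblyTruth(
        fixed_core_keys=tuple(("A", i + 1) for i in range(n_f)),
        moving_core_keys=tuple(("B", i + 1) for i in range(n_m)),
        mobile_keys=tuple(
            [("A", n_f + 1 + i) for i in range(n_mob_a)]
            + [("B", n_m + 1 + i) for i in range(n_mob_b)]
        ),
        rotation_path=tuple(float(a) for a in spec.rotation_path),
        axis=tuple(float(a) for a in axis),
    )
    return topology, traj, truth


def gen_langevin(spec: LangevinSpec) -> tuple[AngleSeries, dict[str, Any]]:
    """Euler–Maruyama trajectory x_{t+dt} = x_t − D·F′(x_t)·dt + sqrt(2D·dt)·η.

    F is in k_BT so the mobility is D itself (overdamped convention).  With a
    profile and ``reflecting`` the walker is reflected at the domain edges
    [0, L]; a flat spec diffuses freely from ``x0``.  Returns the series plus
    a ground-truth record (D, dt, profile parameters, seed).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_steps
    x = np.empty(n + 1)
    x[0] = spec.x0
    noise = math.sqrt(2.0 * spec.D * spec.dt) * rng.standard_normal(n)
    if spec.profile is None:
        np.cumsum(noise, out=x[1:])
        x[1:] += spec.x0
    else:
        prof = spec.profile
        L = prof.L
        xi = spec.x0
        for t in range(n):
            xi = xi - spec.D * prof.dF(xi) * spec.dt + noise[t]
            if spec.reflecting:
                # reflect into [0, L] (handles multiple folds)
                xi = math.fmod(xi, 2.0 * L)
                if xi < 0:
                    xi = -xi
                if xi > L:
                    xi = 2.0 * L - xi
            x[t + 1] = xi
    times = np.arange(n + 1) * spec.dt
    series = AngleSeries(
        coordinate_label="langevin", times=times, values=x, units="units"
    )
    truth: dict[str, Any] = {
        "D": spec.D, "dt": spec.dt, "n_steps": n, "x0": spec.x0,
        "seed": spec.seed,
    }
    if spec.profile is not None:
        prof = spec.profile
        truth["profile"] = {
            "L": prof.L,
            "x_ts": getattr(prof, "x_ts", None),
            "barrier": getattr(prof, "barrier", None),
            "family": getattr(prof, "family", type(prof).__name__),
        }
    return series, truth


def sample_first_passages(
    profile: FreeEnergyProfile,
    D: float,
    dt: float,
    n_walkers: int,
    seed: int = 0,
    max_steps: int = 50_000_000,
) -> np.ndarray:
    """First passage times from x = 0 (reflecting) to x = L (absorbing).

    Simulates ``n_walkers`` independent overdamped walkers in parallel and
    returns their first-passage times; the empirical mean is the stochastic
    oracle for the MFPT quadrature.
    """
    rng = np.random.default_rng(seed)
    L = profile.L
    x = np.zeros(n_walkers)
    t_now = 0.0
    fpt = np.full(n_walkers, np.nan)
    alive = np.arange(n_walkers)
    step = math.sqrt(2.0 * D * dt)
    for _ in range(max_steps):
        if alive.size == 0:
            break
        t_now += dt
        xa = x[alive]
        xa = xa - D * np.asarray(profile.dF(xa)) * dt \
            + step * rng.standard_normal(xa.size)
        np.abs(xa, out=xa)  # reflect at 0
        done = xa >= L
        if done.any():
            fpt[alive[done]] = t_now
            keep = ~done
            x[alive[keep]] = xa[keep]
            alive = alive[keep]
        else:
            x[alive] = xa
    if alive.size:
        raise RuntimeError("walkers did not all absorb within max_steps")
    return fpt


# ---------------------------------------------------------------------------
# PDB fixtures
# ---------------------------------------------------------------------------

def write_structure_pdb(structure: Structure, coords: np.ndarray | None = None) -> str:
    """Serialize a structure (optionally with replacement coordinates) to PDB
    text via biotite.  Deterministic: identical input gives identical bytes."""
    import biotite.structure.io.pdb as pdb

    arr = _as_atom_array_template(structure)
    arr.coord = np.asarray(
        structure.coords if coords is None else coords, dtype=np.float32
    )
    pdb_file = pdb.PDBFile()
    pdb.set_structure(pdb_file, arr)
    return "\n".join(pdb_file.lines) + "\n"


def _as_atom_array_template(structure: Structure):
    import biotite.structure as struc

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = np.array([str(c) for c in structure.chain_ids], dtype="U4")
    arr.res_id = structure.residue_numbers.astype(int)
    arr.res_name = np.array([str(r) for r in structure.residue_names], dtype="U5")
    arr.atom_name = np.array([str(a) for a in structure.atom_names], dtype="U6")
    arr.element = np.array([str(e) for e in structure.elements], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation(
        "b_factor",
        np.zeros(n) if structure.b_factors is None else structure.b_factors,
    )
    return arr


def write_trajectory_pdb(trajectory: Trajectory) -> str:
    """Serialize a trajectory as deterministic multi-model PDB text."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    template = _as_atom_array_template(trajectory.topology)
    stack = struc.stack([template] * trajectory.n_frames)
    stack.coord = np.asarray(trajectory.coords, dtype=np.float32)
    pdb_file = pdb.PDBFile()
    pdb.set_structure(pdb_file, stack)
    return "\n".join(pdb_file.lines) + "\n"


def gen_fixture_pdb(spec: AssemblySpec, frame_index: int = 0) -> str:
    """PDB text for one frame of a generated assembly (round-trips through
    ``read_structure`` at PDB coordinate precision, 1e-3 Å)."""
    topology, traj, _ = gen_assembly_trajectory(spec)
    if not (0 <= frame_index < traj.n_frames):
        raise ValueError("frame index out of range")
    return write_structure_pdb(topology, coords=traj.coords[frame_index])
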