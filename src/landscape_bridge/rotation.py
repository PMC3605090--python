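"""Collective rotation coordinates from rigid-core geometry.

The intersubunit ("ratchet") rotation of the 30S body and the swivel of the
30S head are measured as signed angles of a single phosphate-pair vector,
evaluated on *idealized* coordinates: for each frame the reference core is
rigidly fitted onto the frame's core atoms, and the angle is read off the
fitted (internally rigid) copy.  This discards internal fluctuations so that
the coordinate reports only the collective rotation of the group.

The pair itself is chosen by exhaustive search: among all P-P vectors of the
moving core, the one whose direction changes most between the classical and
the rotated endpoint model (both expressed in the fixed core's frame of
reference) defines the rotation plane; the angle is measured in that plane,
counter-clockwise positive when viewed down the plane normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .cores import CoreSet
from .structures import (
    ResidueKey,
    Structure,
    Trajectory,
    apply_transform,
    superpose,
)

__all__ = [
    "RotationAxis",
    "LandmarkDistance",
    "AngleSeries",
    "idealize",
    "find_max_rotation_pair",
    "compute_angle",
    "landmark_distance",
    "landmark_from_selections",
    "angle_series",
    "axis_to_dict",
    "axis_from_dict",
    "R_ELBOW_PRESET",
]

#: Stand-in preset for the tRNA elbow-position coordinate.  The exact atom
#: selections used in the literature are given only by citation (an external
#: definition), so this preset is a geometric stand-in: the centroid of the
#: P atoms at the D/T-loop junction of the tRNA against a large-subunit
#: landmark.  Override the selections for your structure's chain naming and
#: numbering.
R_ELBOW_PRESET = {
    "label": "R_elbow",
    "selection_a": "V:8,48",    # tRNA elbow region P atoms (chain V)
    "selection_b": "A:2300",    # 23S rRNA reference landmark P atom
    "atom_name": "P",
    "reduction": "centroid",
    "provenance": "external definition (stand-in)",
}


@dataclass(frozen=True)
class AngleSeries:
    """Per-frame values of one collective coordinate on a uniform time grid."""

    coordinate_label: str
    times: np.ndarray  # ns
    values: np.ndarray  # degrees (angles) or Å (distances)
    units: str = "degrees"

    def __post_init__(self):
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
                raise ValueError("times must be uniformly spaced")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def time_step(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RotationAxis:
    """Everything needed to evaluate a rotation coordinate on any frame.

    The fixed core defines the frame of reference (e.g. the 23S core for body
    rotation, the 16S-body core for head swivel); the moving core carries the
    pair.  Reference coordinates are stored for both so the axis is
    self-contained.  ``pair`` indexes into ``moving_keys``/``moving_reference``.
    """

    label: str
    fixed_keys: tuple[tuple[ResidueKey, str], ...]   # (residue, atom name)
    fixed_reference: np.ndarray                      # (n_fixed, 3)
    moving_keys: tuple[tuple[ResidueKey, str], ...]
    moving_reference: np.ndarray                     # (n_moving, 3)
    pair: tuple[int, int]
    plane_normal: np.ndarray                         # unit
    reference_vector: np.ndarray                     # unit, in plane
    pair_angle_change: float = 0.0                   # ° between endpoint models

    def __post_init__(self):
        n = np.asarray(self.plane_normal, float)
        r = np.asarray(self.reference_vector, float)
        if abs(np.linalg.norm(n) - 1) > 1e-10 or abs(np.linalg.norm(r) - 1) > 1e-10:
            raise ValueError("plane_normal and reference_vector must be unit length")
        if abs(float(n @ r)) > 1e-10:
            raise ValueError("reference_vector must be perpendicular to plane_normal")
        object.__setattr__(self, "plane_normal", n)
        object.__setattr__(self, "reference_vector", r)
        object.__setattr__(self, "fixed_reference",
                           np.asarray(self.fixed_reference, float))
        object.__setattr__(self, "moving_reference",
                           np.asarray(self.moving_reference, float))


@dataclass(frozen=True)
class LandmarkDistance:
    """Distance between the centroids of two atom selections (e.g. the tRNA
    elbow relative to a large-subunit landmark).  Selections are lists of
    (residue key, atom name)."""

    label: str
    selection_a: tuple[tuple[ResidueKey, str], ...]
    selection_b: tuple[tuple[ResidueKey, str], ...]

    def __post_init__(self):
        if not self.selection_a or not self.selection_b:
            raise ValueError("both landmark selections must be non-empty")


def _atom_entry_indices(
    structure: Structure, entries: tuple[tuple[ResidueKey, str], ...]
) -> np.ndarray:
    """Indices of (residue, atom-name) entries, in entry order."""
    lookup: dict[tuple[ResidueKey, str], int] = {}
    res_of_atom = structure.residue_of_atom()
    for i in range(structure.n_atoms):
        lookup[(res_of_atom[i], str(structure.atom_names[i]))] = i
    missing = [e for e in entries if e not in lookup]
    if missing:
        raise ValueError(f"atoms absent from structure, e.g. {missing[:5]}")
    return np.array([lookup[e] for e in entries], dtype=np.intp)


def _core_atom_entries(
    structure: Structure, core: CoreSet, heavy_only: bool = True
) -> tuple[tuple[tuple[ResidueKey, str], ...], np.ndarray]:
    idx = structure.atom_indices(residues=core.members, heavy_only=heavy_only)
    if len(idx) < 3:
        raise ValueError(f"core '{core.region_label}' resolves to < 3 atoms")
    res_of_atom = structure.residue_of_atom()
    entries = tuple(
        (res_of_atom[i], str(structure.atom_names[i])) for i in idx
    )
    return entries, idx


def idealize(
    frame_core_coords: np.ndarray, reference_coords: np.ndarray
) -> np.ndarray:
    """Rigidly fit the reference core onto a frame's core atoms.

    Returns the reference coordinates transformed by the least-squares
    superposition onto the frame — the frame's *average orientation* with all
    internal fluctuations discarded.  The output is exactly rigid: its
    internal distances are those of the reference.
    """
    fit = superpose(reference_coords, frame_core_coords)
    return apply_transform(reference_coords, fit)


def _signed_angle(v: np.ndarray, ref: np.ndarray, normal: np.ndarray) -> float:
    """Signed angle (°) from ref to the in-plane projection of v, CCW about normal."""
    v = np.asarray(v, float)
    proj = v - (v @ normal) * normal
    norm = np.linalg.norm(proj)
    if norm < 1e-6 * np.linalg.norm(v):
        raise ValueError("pair vector is (near-)parallel to the rotation axis")
    proj = proj / norm
    ang = np.degrees(np.arctan2(float(np.cross(ref, proj) @ normal),
                                float(ref @ proj)))
    return float(ang)


def find_max_rotation_pair(
    classical: Structure,
    rotated: Structure,
    moving_core: CoreSet,
    fixed_core: CoreSet,
    label: str = "theta",
    min_angle_deg: float = 1e-3,
) -> RotationAxis:
    """Build a rotation coordinate from two endpoint structural models.

    Both models are first expressed in the fixed core's frame (the rotated
    model is superposed onto the classical model over the fixed core), then
    each moving core is idealized against the classical moving-core
    coordinates.  Every unordered pair of P atoms in the moving core is scored
    by the angle between its vector in the two idealized models; the
    maximizing pair defines the rotation plane (normal = unit cross product of
    the two orientations) and the classical orientation sets the in-plane
    reference vector (angle 0).  Ties are broken toward the larger inter-atom
    distance, then lexicographic atom keys.
    """
    fixed_entries, fixed_idx_c = _core_atom_entries(classical, fixed_core)
    fixed_ref = classical.coords[fixed_idx_c]

    # rotated model into the fixed-core frame
    fixed_idx_r = _atom_entry_indices(rotated, fixed_entries)
    fit = superpose(rotated.coords[fixed_idx_r], fixed_ref)
    rotated_coords = apply_transform(rotated.coords, fit)

    moving_entries, moving_idx_c = _core_atom_entries(classical, moving_core)
    moving_idx_r = _atom_entry_indices(rotated, moving_entries)
    moving_ref = classical.coords[moving_idx_c]

    # idealize both moving cores (classical idealizes onto itself exactly)
    ideal_c = idealize(classical.coords[moving_idx_c], moving_ref)
    ideal_r = idealize(rotated_coords[moving_idx_r], moving_ref)

    p_local = [i for i, (res, name) in enumerate(moving_entries) if name == "P"]
    if len(p_local) < 2:
        raise ValueError("moving core must contain at least two P atoms")

    best = None  # (angle, distance, keys, (i, j), v_c, v_r)
    for i, j in combinations(p_local, 2):
        v_c = ideal_c[j] - ideal_c[i]
        v_r = ideal_r[j] - ideal_r[i]
        nc, nr = np.linalg.norm(v_c), np.linalg.norm(v_r)
        if nc == 0 or nr == 0:
            continue
        cosang = np.clip(float(v_c @ v_r) / (nc * nr), -1.0, 1.0)
        ang = float(np.degrees(np.arccos(cosang)))
        key = (ang, nc, (moving_entries[i], moving_entries[j]))
        if best is None or (
            ang > best[0] + 1e-12
            or (abs(ang - best[0]) <= 1e-12 and nc > best[1] + 1e-12)
            or (abs(ang - best[0]) <= 1e-12 and abs(nc - best[1]) <= 1e-12
                and key[2] < best[2])
        ):
            best = (ang, nc, key[2], (i, j), v_c, v_r)

    if best is None or best[0] < min_angle_deg:
        raise ValueError(
            "no rotation detected: all P-pair angle changes below "
            f"{min_angle_deg} degrees (models indistinguishable)"
        )
    ang, _, _, pair, v_c, v_r = best
    normal = np.cross(v_c, v_r)
    normal = normal / np.linalg.norm(normal)
    ref_vec = v_c - (v_c @ normal) * normal
    ref_vec = ref_vec / np.linalg.norm(ref_vec)
    return RotationAxis(
        label=label,
        fixed_keys=fixed_entries,
        fixed_reference=fixed_ref,
        moving_keys=moving_entries,
        moving_reference=moving_ref,
        pair=pair,
        plane_normal=normal,
        reference_vector=ref_vec,
        pair_angle_change=ang,
    )


def compute_angle(
    frame_coords: np.ndarray,
    topology: Structure,
    axis: RotationAxis,
    idealization: str = "core",
    fit_group: tuple[tuple[tuple[ResidueKey, str], ...], np.ndarray] | None = None,
) -> float:
    """Signed rotation angle (°) of one frame along a rotation coordinate.

    Steps: (1) superpose the frame onto the axis's fixed-core reference to
    remove global motion; (2) idealize the moving core; (3) project the
    winning pair's vector into the rotation plane; (4) return the
    counter-clockwise-positive angle between projection and reference vector.
    The result is invariant under any global proper rigid transform of the
    input frame, because step (1) removes it.

    ``idealization`` selects the averaging variant (mainly for diagnostics —
    the default is the recommended estimator):

    * ``"core"`` — fit the moving-core reference onto the frame's core atoms
      and read the pair vector off the fitted rigid copy (default);
    * ``"none"`` — read the pair vector directly from the frame's raw atom
      positions, so individual atomic fluctuations pass straight into the
      angle;
    * ``"group"`` — like ``"core"`` but fitting over an alternative atom
      group given as ``fit_group`` = (entries, reference coordinates), e.g.
      all candidate residues instead of the converged core.  The pair atoms
      must be members of the group.
    """
    frame_coords = np.asarray(frame_coords, float)
    fixed_idx = _atom_entry_indices(topology, axis.fixed_keys)
    moving_idx = _atom_entry_indices(topology, axis.moving_keys)
    group_idx = None
    if idealization == "group":
        if fit_group is None:
            raise ValueError("idealization='group' requires fit_group")
        group_idx = _atom_entry_indices(topology, fit_group[0])
    return _angle_with_indices(
        frame_coords, axis, fixed_idx, moving_idx,
        idealization=idealization, fit_group=fit_group, group_idx=group_idx,
    )


def _angle_with_indices(
    frame_coords: np.ndarray,
    axis: RotationAxis,
    fixed_idx: np.ndarray,
    moving_idx: np.ndarray,
    idealization: str = "core",
    fit_group=None,
    group_idx: np.ndarray | None = None,
) -> float:
    fit = superpose(frame_coords[fixed_idx], axis.fixed_reference)
    i, j = axis.pair
    if idealization == "core":
        frame_moving = apply_transform(frame_coords[moving_idx], fit)
        ideal = idealize(frame_moving, axis.moving_reference)
        v = ideal[j] - ideal[i]
    elif idealization == "none":
        frame_moving = apply_transform(frame_coords[moving_idx], fit)
        v = frame_moving[j] - frame_moving[i]
    elif idealization == "group":
        entries, reference = fit_group
        pair_entries = (axis.moving_keys[i], axis.moving_keys[j])
        try:
            gi, gj = (entries.index(e) for e in pair_entries)
        except ValueError as exc:
            raise ValueError("pair atoms not in idealization group") from exc
        frame_group = apply_transform(frame_coords[group_idx], fit)
        ideal = idealize(frame_group, np.asarray(reference, float))
        v = ideal[gj] - ideal[gi]
    else:
        raise ValueError("idealization must be 'core', 'none' or 'group'")
    return _signed_angle(v, axis.reference_vector, axis.plane_normal)


def landmark_distance(
    frame_coords: np.ndarray, topology: Structure, definition: LandmarkDistance
) -> float:
    """Euclidean distance (Å) between the centroids of the two selections."""
    idx_a = _atom_entry_indices(topology, definition.selection_a)
    idx_b = _atom_entry_indices(topology, definition.selection_b)
    frame_coords = np.asarray(frame_coords, float)
    a = frame_coords[idx_a].mean(axis=0)
    b = frame_coords[idx_b].mean(axis=0)
    return float(np.linalg.norm(a - b))


def landmark_from_selections(
    structure: Structure,
    selection_a: str,
    selection_b: str,
    atom_name: str = "P",
    label: str = "landmark",
) -> LandmarkDistance:
    """Build a landmark distance from textual residue selections, taking the
    named atom of every selected residue (see :data:`R_ELBOW_PRESET` for the
    shipped stand-in preset)."""
    from .structures import select_residues

    def entries(spec: str):
        sel = select_residues(structure, spec)
        return tuple((key, atom_name) for key in sel.resolved)

    return LandmarkDistance(
        label=label,
        selection_a=entries(selection_a),
        selection_b=entries(selection_b),
    )


def axis_to_dict(axis: RotationAxis) -> dict:
    """Self-contained JSON-able form of a rotation axis (for reuse on other
    trajectories or deposited models)."""
    def entries(keys):
        return [[k[0][0], k[0][1], k[1]] for k in keys]

    return {
        "label": axis.label,
        "fixed_keys": entries(axis.fixed_keys),
        "fixed_reference": axis.fixed_reference.tolist(),
        "moving_keys": entries(axis.moving_keys),
        "moving_reference": axis.moving_reference.tolist(),
        "pair": list(axis.pair),
        "plane_normal": axis.plane_normal.tolist(),
        "reference_vector": axis.reference_vector.tolist(),
        "pair_angle_change": axis.pair_angle_change,
    }


def axis_from_dict(data: dict) -> RotationAxis:
    """Inverse of :func:`axis_to_dict`."""
    def entries(raw):
        return tuple(((str(c), int(r)), str(a)) for c, r, a in raw)

    return RotationAxis(
        label=data["label"],
        fixed_keys=entries(data["fixed_keys"]),
        fixed_reference=np.asarray(data["fixed_reference"], float),
        moving_keys=entries(data["moving_keys"]),
        moving_reference=np.asarray(data["moving_reference"], float),
        pair=(int(data["pair"][0]), int(data["pair"][1])),
        plane_normal=np.asarray(data["plane_normal"], float),
        reference_vector=np.asarray(data["reference_vector"], float),
        pair_angle_change=float(data["pair_angle_change"]),
    )


def angle_series(
    trajectory: Trajectory,
    axis: RotationAxis | LandmarkDistance,
    stride: int = 1,
    idealization: str = "core",
    fit_group=None,
) -> AngleSeries:
    """Evaluate a rotation or landmark coordinate on every ``stride``-th frame."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = trajectory.coords[::stride]
    times = trajectory.times[::stride]
    topo = trajectory.topology
    if isinstance(axis, RotationAxis):
        fixed_idx = _atom_entry_indices(topo, axis.fixed_keys)
        moving_idx = _atom_entry_indices(topo, axis.moving_keys)
        group_idx = None
        if idealization == "group":
            if fit_group is None:
                raise ValueError("idealization='group' requires fit_group")
            group_idx = _atom_entry_indices(topo, fit_group[0])
        values = [
            _angle_with_indices(
                f, axis, fixed_idx, moving_idx,
                idealization=idealization, fit_group=fit_group,
                group_idx=group_idx,
            )
            for f in frames
        ]
        units = "degrees"
        label = axis.label
    else:
        values = [landmark_distance(f, topo, axis) for f in frames]
        units = "angstrom"
        label = axis.label
    return AngleSeries(
        coordinate_label=label,
        times=np.asarray(times, float),
        values=np.asarray(values, float),
        units=units,
    )
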