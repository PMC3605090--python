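"""Structures, trajectories, residue selections, superposition and fluctuations.

Coordinates are handled as plain ``float64`` arrays in Å.  A :class:`Structure`
is a flat, ordered table of atoms (the order of the source file is preserved);
a :class:`Trajectory` is a stack of coordinate frames congruent with a topology
``Structure`` on a uniform time grid.  PDB parsing and writing are delegated to
biotite; everything downstream operates on the arrays held here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "ResidueSelection",
    "SuperpositionResult",
    "read_structure",
    "read_trajectory",
    "select_residues",
    "superpose",
    "apply_transform",
    "per_residue_rmsf",
    "bfactor_to_rmsf",
]

#: residue key = (chain_id, residue_number)
ResidueKey = tuple[str, int]


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: identity plus position (Å) and optional B-factor (Å²)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray
    element: str = ""
    b_factor: float | None = None

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


class Structure:
    """An ordered collection of atoms backed by parallel numpy arrays.

    Parameters mirror the PDB ATOM record fields.  Atom order is stable: it is
    the order of the source file (or of construction) and is preserved by all
    selections, which report indices into this order.
    """

    def __init__(
        self,
        chain_ids: Sequence[str],
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        atom_names: Sequence[str],
        coords: np.ndarray,
        elements: Sequence[str] | None = None,
        b_factors: Sequence[float] | None = None,
        label: str = "",
    ):
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        n = coords.shape[0]
        if n == 0:
            raise ValueError("empty structure (no atoms)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.residue_numbers = np.asarray(residue_numbers, dtype=np.int64)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.coords = coords
        if elements is None:
            elements = [_guess_element(a) for a in self.atom_names]
        self.elements = np.asarray(elements, dtype=object)
        self.b_factors = None if b_factors is None else np.asarray(b_factors, float)
        self.label = label
        for arr in (self.chain_ids, self.residue_numbers, self.residue_names,
                    self.atom_names, self.elements):
            if len(arr) != n:
                raise ValueError("field arrays must all have length n_atoms")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_atoms

    def __iter__(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield self[i]

    def __getitem__(self, i: int) -> AtomRecord:
        return AtomRecord(
            chain_id=str(self.chain_ids[i]),
            residue_number=int(self.residue_numbers[i]),
            residue_name=str(self.residue_names[i]),
            atom_name=str(self.atom_names[i]),
            position=self.coords[i],
            element=str(self.elements[i]),
            b_factor=None if self.b_factors is None else float(self.b_factors[i]),
        )

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements], dtype=bool)

    def residue_keys(self) -> list[ResidueKey]:
        """Unique residue keys in first-appearance order."""
        seen: dict[ResidueKey, None] = {}
        for c, r in zip(self.chain_ids, self.residue_numbers):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def atom_indices(
        self,
        residues: Sequence[ResidueKey] | None = None,
        atom_names: Sequence[str] | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Indices (in file order) of atoms matching the given filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residues is not None:
            keys = set(residues)
            mask &= np.array(
                [(str(c), int(r)) in keys
                 for c, r in zip(self.chain_ids, self.residue_numbers)]
            )
        if atom_names is not None:
            names = set(atom_names)
            mask &= np.array([a in names for a in self.atom_names])
        if heavy_only:
            mask &= self.heavy_mask
        return np.nonzero(mask)[0]

    def residue_of_atom(self) -> list[ResidueKey]:
        return [(str(c), int(r))
                for c, r in zip(self.chain_ids, self.residue_numbers)]

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """A copy of this structure with replacement coordinates (e.g. to
        treat one trajectory frame as a standalone model)."""
        return Structure(
            chain_ids=self.chain_ids,
            residue_numbers=self.residue_numbers,
            residue_names=self.residue_names,
            atom_names=self.atom_names,
            coords=np.asarray(coords, float),
            elements=self.elements,
            b_factors=self.b_factors,
            label=self.label if label is None else label,
        )


@dataclass
class Trajectory:
    """Uniformly spaced coordinate frames congruent with a topology structure.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``time_step`` is the ns
    between stored frames.  Non-uniform spacing is not representable; readers
    reject it rather than resampling.
    """

    topology: Structure
    coords: np.ndarray
    time_step: float  # ns

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} != topology atom count "
                f"{self.topology.n_atoms}"
            )
        if self.time_step <= 0:
            raise ValueError("time_step must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns, starting at 0."""
        return np.arange(self.n_frames) * self.time_step

    def __getitem__(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass(frozen=True)
class ResidueSelection:
    """A resolved set of residues, from inclusive ranges or 'all'.

    ``ranges`` keeps the parsed (chain, start, end) triplets for audit;
    ``resolved`` is the ordered tuple of residue keys actually present.
    """

    ranges: tuple[tuple[str, int, int], ...]
    resolved: tuple[ResidueKey, ...]

    @property
    def n_residues(self) -> int:
        return len(self.resolved)

    def __len__(self) -> int:
        return len(self.resolved)

    def __contains__(self, key: ResidueKey) -> bool:
        return key in set(self.resolved)


@dataclass(frozen=True)
class SuperpositionResult:
    """A proper rigid-body least-squares fit: y ≈ rotation @ x + translation."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å


def _guess_element(atom_name: str) -> str:
    """Element from a PDB-style atom name (P, C1', O5', N3, H5'' ...)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0].upper() == "H":
        return "H"
    return stripped[0].upper()


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _structure_from_atom_array(arr, label: str) -> Structure:
    b = arr.b_factor if "b_factor" in arr.get_annotation_categories() else None
    elements = [str(e) if e else _guess_element(str(a))
                for e, a in zip(arr.element, arr.atom_name)]
    return Structure(
        chain_ids=[str(c) for c in arr.chain_id],
        residue_numbers=arr.res_id,
        residue_names=[str(r) for r in arr.res_name],
        atom_names=[str(a) for a in arr.atom_name],
        coords=arr.coord,
        elements=elements,
        b_factors=b,
        label=label,
    )


def read_structure(path: str | Path, model: int | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure` (first model by default).

    Atom order follows the file.  Hydrogens are retained; downstream
    operations take a ``heavy_only`` flag to exclude them.  B-factors are
    carried when present.  Alternate locations beyond 'A' raise.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        arr = pdb.get_structure(
            pdb_file, model=1 if model is None else model,
            extra_fields=["b_factor"], altloc="first",
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise ValueError(f"PDB file {path} contains no atoms")
    return _structure_from_atom_array(arr, label=path.stem)


def read_trajectory(path: str | Path, time_step: float) -> Trajectory:
    """Read a multi-model PDB file as a trajectory on a uniform time grid.

    ``time_step`` is the ns between consecutive models.  Every model must have
    the same atom count as the first (the topology).
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb.get_structure(pdb_file, extra_fields=["b_factor"], altloc="first")
    if stack.stack_depth() == 0:
        raise ValueError(f"PDB file {path} contains no models")
    topo = _structure_from_atom_array(stack[0], label=path.stem)
    return Trajectory(topology=topo, coords=stack.coord, time_step=time_step)


# ---------------------------------------------------------------------------
# Residue selection
# ---------------------------------------------------------------------------

def _parse_selection_spec(spec: str) -> list[tuple[str | None, int | None, int | None]]:
    """Parse 'chain:start-end[,start-end...]' or 'start-end,...' or 'all'.

    Returns (chain, start, end) triplets; chain None means "sole chain",
    start/end None means every residue of the chain.
    """
    spec = spec.strip()
    if not spec:
        raise ValueError("empty selection spec")
    chain: str | None = None
    if ":" in spec:
        chain, spec = spec.split(":", 1)
        chain = chain.strip()
    if spec.strip().lower() == "all":
        return [(chain, None, None)]
    out = []
    for part in spec.split(","):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-", 1)
            start, end = int(lo), int(hi)
        else:
            start = end = int(part)
        if end < start:
            raise ValueError(f"range '{part}': end < start")
        out.append((chain, start, end))
    return out


def select_residues(structure: Structure, spec: str) -> ResidueSelection:
    """Resolve a textual residue-range spec against a structure.

    Ranges are inclusive on both ends and 1-based, matching PDB numbering
    (e.g. '5-920,1397-1540' on a complete small-subunit rRNA chain resolves
    916 + 144 = 1060 residues).  Every residue named by a range must exist;
    missing residues raise with the full list of missing keys.
    """
    parsed = _parse_selection_spec(spec)
    chains = sorted(set(str(c) for c in structure.chain_ids))
    present = set(structure.residue_keys())

    resolved: list[ResidueKey] = []
    ranges: list[tuple[str, int, int]] = []
    missing: list[ResidueKey] = []
    for chain, start, end in parsed:
        if chain is None:
            if len(chains) > 1 and start is not None:
                raise ValueError(
                    f"selection '{spec}' names no chain but structure has "
                    f"chains {chains}; use 'CHAIN:start-end'"
                )
            use_chains = chains
        else:
            if chain not in chains:
                raise ValueError(f"chain '{chain}' not in structure (has {chains})")
            use_chains = [chain]
        for ch in use_chains:
            if start is None:  # 'all' for this chain
                keys = [k for k in structure.residue_keys() if k[0] == ch]
                resolved.extend(keys)
                if keys:
                    nums = [k[1] for k in keys]
                    ranges.append((ch, min(nums), max(nums)))
                continue
            ranges.append((ch, start, end))
            for num in range(start, end + 1):
                key = (ch, num)
                if key in present:
                    resolved.append(key)
                else:
                    missing.append(key)
    if missing:
        raise ValueError(
            f"selection '{spec}': {len(missing)} residue(s) absent from "
            f"structure, e.g. {missing[:5]}"
        )
    # order-independent resolution: dedupe, keep structure order
    order = {k: i for i, k in enumerate(structure.residue_keys())}
    unique = sorted(set(resolved), key=order.__getitem__)
    return ResidueSelection(ranges=tuple(ranges), resolved=tuple(unique))


# ---------------------------------------------------------------------------
# Superposition (Kabsch, proper rotations only)
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference`` (mass-unweighted).

    Minimises the RMSD over proper rotations and translations (Kabsch with a
    determinant correction; reflections are never returned).  Requires at
    least 3 non-collinear points in each set.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point count mismatch: mobile {mobile.shape} vs reference "
            f"{reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("superposition needs >= 3 points of dimension 3")

    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    x = mobile - mob_c
    y = reference - ref_c

    # degenerate (collinear / coincident) mobile or reference geometry
    for pts, name in ((x, "mobile"), (y, "reference")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise ValueError(f"degenerate {name} geometry (collinear points)")

    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    fitted = x @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    translation = ref_c - rot @ mob_c
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd)


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    """Apply a superposition transform to an (n, 3) coordinate set."""
    return np.asarray(coords, float) @ result.rotation.T + result.translation


# ---------------------------------------------------------------------------
# Per-residue RMSF
# ---------------------------------------------------------------------------

def _aligned_frames(
    coords: np.ndarray, align_idx: np.ndarray, reference: str, max_iter: int = 10
) -> np.ndarray:
    """Superpose every frame onto the first-frame or iterated time-average
    configuration of the alignment atoms; returns transformed full frames."""
    frames = coords.copy()
    if reference == "first":
        ref = frames[0, align_idx]
        for t in range(frames.shape[0]):
            fit = superpose(frames[t, align_idx], ref)
            frames[t] = apply_transform(frames[t], fit)
        return frames
    if reference != "mean":
        raise ValueError("reference must be 'mean' or 'first'")
    # iterate: align to first, then re-align to the running mean until stable
    ref = frames[0, align_idx]
    for _ in range(max_iter):
        for t in range(frames.shape[0]):
            fit = superpose(frames[t, align_idx], ref)
            frames[t] = apply_transform(frames[t], fit)
        new_ref = frames[:, align_idx].mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_ref - ref) ** 2, axis=1))))
        ref = new_ref
        if shift < 1e-10:
            break
    return frames


def per_residue_rmsf(
    trajectory: Trajectory,
    selection: ResidueSelection,
    align_on: ResidueSelection | None = None,
    heavy_only: bool = True,
    reference: str = "mean",
) -> dict[ResidueKey, float]:
    """Root-mean-square fluctuation per residue, in Å.

    Each frame is first superposed onto the ``reference`` configuration
    ('mean': iterated time-average, the g_rmsf-style default; 'first': frame 0)
    of the ``align_on`` atoms (default: the selection itself).  The per-atom
    rmsf is the RMS deviation from the atom's mean position over the aligned
    frames; the residue value averages its (heavy, when ``heavy_only``) atoms.
    """
    if trajectory.n_frames < 2:
        raise ValueError("rmsf needs at least 2 frames")
    if align_on is None:
        align_on = selection
    topo = trajectory.topology
    align_idx = topo.atom_indices(residues=align_on.resolved, heavy_only=heavy_only)
    sel_idx = topo.atom_indices(residues=selection.resolved, heavy_only=heavy_only)
    if len(sel_idx) == 0:
        raise ValueError("empty residue selection")
    if len(align_idx) < 3:
        raise ValueError("alignment selection must cover >= 3 atoms")

    frames = _aligned_frames(trajectory.coords, align_idx, reference)
    sub = frames[:, sel_idx]  # (n_frames, n_sel, 3)
    mean_pos = sub.mean(axis=0)
    atom_rmsf = np.sqrt(np.mean(np.sum((sub - mean_pos) ** 2, axis=2), axis=0))

    res_of_atom = topo.residue_of_atom()
    out: dict[ResidueKey, list[float]] = {k: [] for k in selection.resolved}
    for j, idx in enumerate(sel_idx):
        out[res_of_atom[idx]].append(atom_rmsf[j])
    return {k: float(np.mean(v)) for k, v in out.items() if v}


def bfactor_to_rmsf(b: float | np.ndarray) -> float | np.ndarray:
    """Convert an isotropic crystallographic B-factor (Å²) to an rmsf (Å).

    Uses the isotropic convention B = 8π²⟨u²⟩/3, i.e. rmsf = sqrt(3B / 8π²).
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("negative B-factor")
    out = np.sqrt(3.0 * b_arr / (8.0 * np.pi**2))
    return float(out) if np.isscalar(b) or b_arr.ndim == 0 else out
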