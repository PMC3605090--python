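"""Rigid-core identification by iterative exclusion of high-rmsf residues.

Large subdomains of the ribosome (the 23S scaffold, the 16S body and head)
behave as nearly rigid bodies: their residues keep sub-Å internal fluctuations
while the whole group rotates.  To find such a "core" the algorithm starts
from a candidate residue set, repeatedly self-aligns the trajectory on the
surviving set, computes per-residue rmsf, and removes every residue at or
above a threshold — lowering the threshold through a descending schedule
until every survivor fluctuates below the final (1 Å by default) cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import (
    ResidueKey,
    ResidueSelection,
    Trajectory,
    per_residue_rmsf,
)

__all__ = ["ExclusionConfig", "CoreSet", "iterative_exclusion"]

DEFAULT_SCHEDULE = (5.0, 4.0, 3.0, 2.0, 1.5, 1.0)


@dataclass(frozen=True)
class ExclusionConfig:
    """Knobs for the iterative-exclusion run.

    ``threshold_schedule`` is the strictly decreasing sequence of rmsf cutoffs
    in Å (default 5, 4, 3, 2, 1.5, 1 Å); ``analysis_window_ns`` limits the
    trajectory span used (clipped to what is available); ``sampling_stride``
    subsamples frames; ``heavy_only`` restricts rmsf to non-hydrogen atoms.
    """

    threshold_schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    analysis_window_ns: float | None = 1000.0
    sampling_stride: int = 1
    heavy_only: bool = True
    rmsf_reference: str = "mean"

    def __post_init__(self):
        sched = tuple(float(t) for t in self.threshold_schedule)
        if len(sched) == 0:
            raise ValueError("empty threshold schedule")
        if any(t <= 0 for t in sched):
            raise ValueError("thresholds must be > 0")
        if len(sched) > 1 and not all(a > b for a, b in zip(sched, sched[1:])):
            raise ValueError("threshold schedule must be strictly decreasing")
        object.__setattr__(self, "threshold_schedule", sched)
        if self.sampling_stride < 1:
            raise ValueError("sampling_stride must be >= 1")


@dataclass(frozen=True)
class CoreSet:
    """The converged rigid core plus a full audit trail.

    ``iteration_log`` records one entry per rmsf pass as
    (threshold Å, n_removed, n_remaining); ``final_rmsf`` holds the last
    computed per-residue rmsf of the members, every value below the final
    schedule threshold.
    """

    region_label: str
    members: tuple[ResidueKey, ...]
    final_rmsf: dict[ResidueKey, float]
    iteration_log: tuple[tuple[float, int, int], ...]
    analysis_window_ns: float = 0.0

    @property
    def n_members(self) -> int:
        return len(self.members)

    def as_selection(self) -> ResidueSelection:
        return ResidueSelection(ranges=(), resolved=self.members)


def _clip_trajectory(trajectory: Trajectory, config: ExclusionConfig) -> Trajectory:
    coords = trajectory.coords[:: config.sampling_stride]
    dt = trajectory.time_step * config.sampling_stride
    if config.analysis_window_ns is not None:
        n_keep = int(np.floor(config.analysis_window_ns / dt)) + 1
        coords = coords[: max(n_keep, 2)]
    return Trajectory(topology=trajectory.topology, coords=coords, time_step=dt)


def iterative_exclusion(
    trajectory: Trajectory,
    candidates: ResidueSelection,
    config: ExclusionConfig | None = None,
    region_label: str = "",
) -> CoreSet:
    """Converge on the residues whose internal rmsf stays below the schedule.

    For each threshold ε (descending): repeatedly {align every frame on the
    current surviving set, compute per-residue rmsf, drop all residues with
    rmsf >= ε} until no residue of the set reaches ε, then advance to the next
    smaller ε.  Removal is strict — a removed residue is never re-admitted —
    so the retained set shrinks monotonically along the schedule and the loop
    terminates (each pass either removes a residue or advances the schedule).

    The "at or above" comparison guarantees the advertised final property
    exactly: every member's rmsf is strictly below the last threshold.

    Raises if the set empties or drops below 3 residues (the self-alignment
    would be degenerate) before the schedule completes.
    """
    if config is None:
        config = ExclusionConfig()
    if candidates.n_residues == 0:
        raise ValueError("empty candidate selection")
    traj = _clip_trajectory(trajectory, config)
    if traj.n_frames < 2:
        raise ValueError("trajectory must cover at least 2 sampled frames")

    current: tuple[ResidueKey, ...] = tuple(candidates.resolved)
    log: list[tuple[float, int, int]] = []
    rmsf: dict[ResidueKey, float] = {}

    for eps in config.threshold_schedule:
        while True:
            if len(current) == 0:
                raise ValueError("no rigid core under schedule (set emptied)")
            if len(current) < 3:
                raise ValueError(
                    "fewer than 3 residues remain; superposition degenerate — "
                    "no rigid core under schedule"
                )
            sel = ResidueSelection(ranges=(), resolved=current)
            rmsf = per_residue_rmsf(
                traj,
                sel,
                align_on=sel,
                heavy_only=config.heavy_only,
                reference=config.rmsf_reference,
            )
            doomed = {k for k, v in rmsf.items() if v >= eps}
            survivors = tuple(k for k in current if k not in doomed)
            log.append((eps, len(doomed), len(survivors)))
            if not doomed:
                break  # one clean pass at this threshold; advance schedule
            current = survivors

    final = {k: rmsf[k] for k in current}
    return CoreSet(
        region_label=region_label,
        members=current,
        final_rmsf=final,
        iteration_log=tuple(log),
        analysis_window_ns=(traj.n_frames - 1) * traj.time_step,
    )
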