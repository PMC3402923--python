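"""Peptide-binding stability from receptor–peptide complex trajectories.

A complex trajectory is analysed in the receptor's frame of reference:
every frame is superposed onto frame 0 using receptor Cα only, and the
peptide's Cα RMSD against its initial pose is the "movement" observable.
A stably docked peptide fluctuates about its pose with bounded movement; a
peptide free of the interaction wanders and its movement grows with time.
The three conditions mirror a docking-stability experiment: the docked
peptide, the docked peptide with its side chains neutralised (all-alanine,
probing sequence specificity), and the peptide pulled away and free.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .superpose import kabsch_fit


class DockingError(ValueError):
    """Raised for bad selections or condition sets."""


class Condition(str, Enum):
    DOCKED = "DOCKED"
    DOCKED_ALA = "DOCKED_ALA"
    FREE = "FREE"


@dataclass(frozen=True)
class ComplexTrajectory:
    """A trajectory whose residues split into receptor and peptide."""

    trajectory: Trajectory
    receptor_residues: frozenset[int]
    peptide_residues: frozenset[int]
    condition: Condition

    def __post_init__(self) -> None:
        if not self.receptor_residues or not self.peptide_residues:
            raise DockingError("receptor and peptide selections must be non-empty")
        if self.receptor_residues & self.peptide_residues:
            raise DockingError("receptor and peptide selections overlap")
        present = {int(r) for r in self.trajectory.residue_numbers}
        union = self.receptor_residues | self.peptide_residues
        if union != present:
            raise DockingError(
                "receptor + peptide selections must exactly cover the "
                f"trajectory residues ({len(union)} selected, {len(present)} present)"
            )


@dataclass(frozen=True)
class DockingStabilitySeries:
    """Per-frame peptide displacement for one condition."""

    condition: Condition
    time_ps: np.ndarray
    displacement: np.ndarray  # Å, >= 0
    metric: str = "rmsd"

    @property
    def mean_displacement(self) -> float:
        return float(np.mean(self.displacement))

    @property
    def max_displacement(self) -> float:
        return float(np.max(self.displacement))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ps": self.time_ps,
                "displacement": self.displacement,
                "condition": self.condition.value,
            }
        )


def peptide_displacement(
    cplx: ComplexTrajectory, metric: str = "rmsd"
) -> DockingStabilitySeries:
    """Peptide movement per frame, in the receptor's frame of reference.

    Each frame is fitted onto frame 0 over receptor Cα only; the peptide's
    displacement is then its Cα RMSD against the frame-0 pose
    (``metric="rmsd"``) or the distance between peptide centres of mass
    (``metric="com"``). Rigid motion of the whole complex cancels exactly.
    """
    if metric not in ("rmsd", "com"):
        raise ValueError(f"metric must be 'rmsd' or 'com', got {metric!r}")
    traj = cplx.trajectory
    if traj.n_frames < 2:
        raise DockingError("need at least 2 frames")
    numbers = traj.residue_numbers
    rec_mask = np.array([int(r) in cplx.receptor_residues for r in numbers])
    pep_mask = ~rec_mask
    ref = traj.frames[0].coords
    ref_pep = ref[pep_mask]
    displacements = []
    for frame in traj.frames[1:]:
        fit = kabsch_fit(frame.coords[rec_mask], ref[rec_mask])
        pep = frame.coords[pep_mask] @ fit.rotation.T + fit.translation
        if metric == "rmsd":
            d = float(np.sqrt(np.mean(np.sum((pep - ref_pep) ** 2, axis=1))))
        else:
            d = float(np.linalg.norm(pep.mean(axis=0) - ref_pep.mean(axis=0)))
        displacements.append(d)
    times = traj.times_ps[1:]
    return DockingStabilitySeries(
        condition=cplx.condition,
        time_ps=times,
        displacement=np.array(displacements),
        metric=metric,
    )


def compare_conditions(series: list[DockingStabilitySeries]) -> pd.DataFrame:
    """Rank conditions by mean peptide displacement.

    Returns one row per condition ordered from most to least mobile, with
    pairwise mean differences in ``df.attrs["pairwise"]`` as a
    ``{(cond_a, cond_b): mean_a - mean_b}`` mapping.
    """
    if len(series) < 2:
        raise DockingError("need at least 2 conditions to compare")
    labels = [s.condition.value for s in series]
    if len(set(labels)) != len(labels):
        raise DockingError(f"duplicate condition labels: {labels}")
    rows = [
        {
            "condition": s.condition.value,
            "mean_displacement": s.mean_displacement,
            "max_displacement": s.max_displacement,
            "n_frames": len(s.displacement),
        }
        for s in series
    ]
    df = pd.DataFrame(rows).sort_values(
        "mean_displacement", ascending=False, kind="mergesort"
    )
    df.insert(0, "rank", range(1, len(df) + 1))
    df = df.reset_index(drop=True)
    pairwise = {}
    for i, a in enumerate(series):
        for b in series[i + 1 :]:
            pairwise[(a.condition.value, b.condition.value)] = (
                a.mean_displacement - b.mean_displacement
            )
    df.attrs["pairwise"] = pairwise
    return df
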