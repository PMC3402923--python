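"""Per-residue Cα dynamics from MD trajectories.

The central observable is the per-residue RMSD against the *initial*
structure: for residue i,

    RMSD_i = sqrt( (1/T) * sum_{t=1..T} ||x_i(t) - x_i(0)||^2 )

over the T post-initial frames, after each frame has been rigidly
superposed onto frame 0 over all Cα. This deliberately measures deviation
from the starting conformation, not fluctuation about the time-average
(which would be an RMSF): a residue that drifts away and stays put scores
high here and low on an RMSF.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import StructureModel, read_models
from .superpose import kabsch_fit


class TrajectoryError(ValueError):
    """Raised for inconsistent frames or invalid trajectory parameters."""


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered Cα frames at a fixed sampling interval.

    Frame 0 is the initial structure; frame t sits at ``t *
    frame_interval_ps`` picoseconds.
    """

    frames: tuple[StructureModel, ...]
    frame_interval_ps: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryError("trajectory has no frames")
        if self.frame_interval_ps <= 0:
            raise TrajectoryError(
                f"frame interval must be positive, got {self.frame_interval_ps}"
            )
        first = self.frames[0]
        for i, frame in enumerate(self.frames[1:], start=1):
            if not np.array_equal(frame.residue_numbers, first.residue_numbers):
                raise TrajectoryError(
                    f"{self.label or 'trajectory'}: frame {i} residue numbering "
                    f"differs from frame 0"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def residue_numbers(self) -> np.ndarray:
        return self.frames[0].residue_numbers

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ps

    @property
    def duration_ps(self) -> float:
        return float((self.n_frames - 1) * self.frame_interval_ps)

    def coords_array(self) -> np.ndarray:
        """(n_frames, n_residues, 3) stacked coordinates."""
        return np.stack([f.coords for f in self.frames])


def read_trajectory(
    path: str | Path,
    frame_interval_ps: float,
    chain: str | None = None,
    label: str | None = None,
) -> Trajectory:
    """Read a MODEL/ENDMDL-delimited multi-model PDB as a trajectory."""
    frames = read_models(path, chain=chain)
    return Trajectory(
        frames=tuple(frames),
        frame_interval_ps=frame_interval_ps,
        label=label or Path(path).stem,
    )


@dataclass(frozen=True)
class ResidueDynamicsProfile:
    """Mean Cα RMSD from the initial structure, per residue."""

    residue_numbers: np.ndarray
    mean_rmsd: np.ndarray  # Å
    n_frames_used: int
    fit_scope: str  # "ca" or "none"
    label: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": self.residue_numbers, "mean_rmsd": self.mean_rmsd}
        )


def subsample_frames(traj: Trajectory, interval_ps: float = 25.0) -> Trajectory:
    """Retain frames at t = 0, interval, 2*interval, ...

    ``interval_ps`` must be a positive integer multiple of the stored
    frame interval. A 1000 ps trajectory stored every 1 ps subsampled at
    25 ps keeps 41 frames (t = 0 through 1000 inclusive).
    """
    if interval_ps <= 0:
        raise TrajectoryError(f"interval must be positive, got {interval_ps}")
    ratio = interval_ps / traj.frame_interval_ps
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-9:
        raise TrajectoryError(
            f"interval {interval_ps} ps is not a multiple of the stored "
            f"interval {traj.frame_interval_ps} ps"
        )
    if stride == 1:
        return traj
    return replace(
        traj, frames=traj.frames[::stride], frame_interval_ps=interval_ps
    )


def per_residue_rmsd(traj: Trajectory, fit: str = "ca") -> ResidueDynamicsProfile:
    """Per-residue Cα RMSD of every post-initial frame against frame 0.

    With ``fit="ca"`` each frame is first superposed onto frame 0 over all
    Cα, removing rigid-body drift and tumbling; ``fit="none"`` uses raw
    coordinates (useful when the generator guarantees no net motion).
    Frame 0 itself is excluded from the average — it would contribute an
    identical zero to every residue and deflate the profile.
    """
    if fit not in ("ca", "none"):
        raise ValueError(f"fit must be 'ca' or 'none', got {fit!r}")
    if traj.n_frames < 2:
        raise TrajectoryError("need at least 2 frames for a dynamics profile")
    ref = traj.frames[0].coords
    sq_sum = np.zeros(len(ref))
    n_used = 0
    for frame in traj.frames[1:]:
        coords = frame.coords
        if fit == "ca":
            res = kabsch_fit(coords, ref)
            coords = coords @ res.rotation.T + res.translation
        sq_sum += np.sum((coords - ref) ** 2, axis=1)
        n_used += 1
    return ResidueDynamicsProfile(
        residue_numbers=traj.residue_numbers.copy(),
        mean_rmsd=np.sqrt(sq_sum / n_used),
        n_frames_used=n_used,
        fit_scope=fit,
        label=traj.label,
    )


def compare_dynamics(
    a: ResidueDynamicsProfile,
    b: ResidueDynamicsProfile,
    report_threshold: float = 0.5,
) -> pd.DataFrame:
    """Residue-by-residue difference table, delta = rmsd_b - rmsd_a.

    Residues with ``|delta| > report_threshold`` Å are listed in
    ``df.attrs["flagged"]`` — these are the candidates for altered local
    dynamics (a variant loosening its neighbourhood, for instance).
    """
    if not np.array_equal(a.residue_numbers, b.residue_numbers):
        raise TrajectoryError("profiles cover different residue numbering")
    df = pd.DataFrame(
        {
            "residue": a.residue_numbers,
            "rmsd_a": a.mean_rmsd,
            "rmsd_b": b.mean_rmsd,
            "delta": b.mean_rmsd - a.mean_rmsd,
        }
    )
    df.attrs["flagged"] = [
        int(r) for r, d in zip(df["residue"], df["delta"])
        if abs(d) > report_threshold
    ]
    return df


def annotate_dynamics(
    profile: ResidueDynamicsProfile,
    tiers: pd.DataFrame | None,
) -> pd.DataFrame:
    """Merge a dynamics profile with conservation tiers.

    ``tiers`` is a conservation report with ``position`` and ``tier``
    columns; residues absent from it (or an empty/None table) are tiered
    NO_VARIANT. The per-tier mean RMSD summary is attached as
    ``df.attrs["tier_means"]``.
    """
    tier_map: dict[int, str] = {}
    if tiers is not None and len(tiers):
        tier_map = {
            int(p): str(t) for p, t in zip(tiers["position"], tiers["tier"])
        }
    rows = [
        {
            "residue": int(num),
            "mean_rmsd": float(rmsd),
            "tier": tier_map.get(int(num), "NO_VARIANT"),
        }
        for num, rmsd in zip(profile.residue_numbers, profile.mean_rmsd)
    ]
    df = pd.DataFrame(rows, columns=["residue", "mean_rmsd", "tier"])
    df.attrs["tier_means"] = (
        df.groupby("tier")["mean_rmsd"].mean().to_dict()
    )
    return df


def plot_profile(
    annotated: pd.DataFrame, path: str | Path, title: str = ""
) -> None:
    """Bar chart of per-residue RMSD coloured by conservation tier."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        "HMG_CONSERVED": "#c23b3b",
        "SOX_CONSERVED": "#7b3bc2",
        "NOT_CONSERVED": "#3bc24b",
        "NO_VARIANT": "#9a9a9a",
    }
    fig, ax = plt.subplots(figsize=(10, 3.2))
    ax.bar(
        annotated["residue"],
        annotated["mean_rmsd"],
        color=[colors.get(t, "#9a9a9a") for t in annotated["tier"]],
        width=0.85,
    )
    ax.set_xlabel("HMG-box residue")
    ax.set_ylabel("mean Cα RMSD (Å)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)
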