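#!/usr/bin/env python
"""Per-residue Cα dynamics, tiered by conservation.

Profiles the wild-type trajectory (RMSD of each residue from its
starting position, after whole-domain fitting), merges the conservation
tiers, and contrasts the wild-type profile with the variant trajectory —
the variant is expected to loosen dynamics around its own position.
"""

import importlib.util
from pathlib import Path

import pandas as pd

from resfunc.dynamics import (
    annotate_dynamics,
    compare_dynamics,
    per_residue_rmsd,
    plot_profile,
    read_trajectory,
)

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def ensure_study() -> Path:
    if not (STUDY / "run.yaml").exists():
        spec = importlib.util.spec_from_file_location(
            "build_study", Path(__file__).parent / "01_build_study.py"
        )
        module = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(module)
        module.build()
    return STUDY


def main() -> None:
    study = ensure_study()
    tiers_path = RESULTS / "conservation_report.tsv"
    if not tiers_path.exists():
        spec = importlib.util.spec_from_file_location(
            "conservation_step", Path(__file__).parent / "03_conservation.py"
        )
        module = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(module)
        module.main()
    tiers = pd.read_csv(tiers_path, sep="\t", comment="#")

    wildtype = per_residue_rmsd(read_trajectory(study / "traj_wildtype.pdb", 25.0))
    variant = per_residue_rmsd(read_trajectory(study / "traj_variant.pdb", 25.0))

    annotated = annotate_dynamics(wildtype, tiers)
    RESULTS.mkdir(exist_ok=True)
    annotated.to_csv(RESULTS / "dynamics_profile.tsv", sep="\t", index=False,
                     float_format="%.4f")
    figures = ROOT / "scratch" / "figures"
    figures.mkdir(parents=True, exist_ok=True)
    plot_profile(annotated, figures / "dynamics_profile.png",
                 title="per-residue Cα RMSD, wild type")

    means = annotated.attrs["tier_means"]
    print(f"profile over {wildtype.n_frames_used} frames (25 ps apart)")
    for tier in ("HMG_CONSERVED", "SOX_CONSERVED", "NOT_CONSERVED", "NO_VARIANT"):
        if tier in means:
            print(f"  mean Cα RMSD, {tier:>14}: {means[tier]:.2f} Å")

    comparison = compare_dynamics(wildtype, variant)
    comparison.to_csv(RESULTS / "dynamics_comparison.tsv", sep="\t", index=False,
                      float_format="%.4f")
    top = comparison.loc[comparison["delta"].idxmax()]
    print(
        f"variant vs wild type: largest increase at residue "
        f"{int(top['residue'])} (+{top['delta']:.2f} Å)"
    )


if __name__ == "__main__":
    main()
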