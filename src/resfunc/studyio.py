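"""Serialise a synthetic study to standard on-disk formats.

Everything the pipeline consumes — variant TSV, aligned FASTA, PDB
structures and multi-model PDB trajectories — is written in plain text,
together with a ``run.yaml`` config pointing at it all, so a study
directory is a complete, rerunnable pipeline input.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .catalog import write_variants
from .conservation import write_aligned_fasta
from .structures import write_models
from .synth import SyntheticStudy


def write_study(study: SyntheticStudy, out_dir: str | Path) -> Path:
    """Write every study input under ``out_dir``; returns the run.yaml path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_variants(study.catalog, out / "catalog.tsv")
    write_aligned_fasta(study.hmg, out / "hmg.fasta")
    write_aligned_fasta(study.sox, out / "sox.fasta")
    write_aligned_fasta(study.correspondence, out / "correspondence.fasta")

    struct_dir = out / "structures"
    struct_dir.mkdir(exist_ok=True)
    structure_paths = []
    for model in study.ensemble:
        path = struct_dir / f"{model.id}.pdb"
        write_models(model, path)
        structure_paths.append(str(path.relative_to(out)))

    write_models(list(study.wildtype_traj.frames), out / "traj_wildtype.pdb")
    write_models(list(study.variant_traj.frames), out / "traj_variant.pdb")

    complexes = []
    for name, cplx in study.complexes.items():
        path = out / f"complex_{name.lower()}.pdb"
        write_models(list(cplx.trajectory.frames), path)
        complexes.append(
            {
                "path": path.name,
                "condition": name,
                "receptor_chain": "A",
                "peptide_chain": "B",
            }
        )

    config = {
        "out_dir": "report",
        "catalog": "catalog.tsv",
        "hmg_msa": "hmg.fasta",
        "sox_msa": "sox.fasta",
        "reference_id": "SRY",
        "threshold": 0.90,
        "mode": "class",
        "structures": structure_paths,
        "correspondence": "correspondence.fasta",
        "structure_chain": "A",
        "trajectory": "traj_wildtype.pdb",
        "variant_trajectory": "traj_variant.pdb",
        "stored_interval_ps": study.wildtype_traj.frame_interval_ps,
        "interval_ps": study.wildtype_traj.frame_interval_ps,
        "fit": "ca",
        "complexes": complexes,
        "seed": study.seed,
    }
    config_path = out / "run.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return config_path
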