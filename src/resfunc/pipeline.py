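"""End-to-end orchestration: catalog → conservation → superposition →
dynamics → docking, merged into one per-residue annotation table.

Stage outputs are flat TSV files plus a JSON manifest (config hash, seed,
package version) — inspectable and diff-friendly. A run is a pure
function of its config and seed: rerunning with both unchanged reproduces
every output byte for byte, so no timestamps or wall-times appear in any
output file. Stages whose inputs are absent from the config are skipped
with a logged notice; a failing stage aborts the run, leaves earlier
outputs in place and drops a ``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace as dc_replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import load_variants, summarize_catalog, write_variants
from .conservation import (
    ConservationTier,
    conservation_report,
    read_aligned_fasta,
    write_conservation_report,
)
from .docking import ComplexTrajectory, Condition, compare_conditions, peptide_displacement
from .dynamics import (
    annotate_dynamics,
    compare_dynamics,
    per_residue_rmsd,
    read_trajectory,
    subsample_frames,
)
from .structures import clean_structure, write_models
from .superpose import superpose_ensemble

log = logging.getLogger("resfunc")

FLOAT_FMT = "%.6f"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class ComplexInput:
    path: str
    condition: str
    receptor_chain: str = "A"
    peptide_chain: str = "B"


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run. Paths are resolved against
    the config file's directory when loaded from YAML."""

    out_dir: str
    catalog: str | None = None
    hmg_msa: str | None = None
    sox_msa: str | None = None
    reference_id: str = "SRY"
    threshold: float = 0.90
    mode: str = "class"
    structures: list[str] = field(default_factory=list)
    correspondence: str | None = None
    structure_chain: str = "A"
    trajectory: str | None = None
    variant_trajectory: str | None = None
    stored_interval_ps: float = 25.0
    interval_ps: float = 25.0
    fit: str = "ca"
    complexes: list[ComplexInput] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        complexes = [ComplexInput(**c) for c in raw.pop("complexes", [])]
        config = cls(**raw, complexes=complexes)
        base = path.parent

        def resolve(p: str | None) -> str | None:
            return None if p is None else str((base / p).resolve()) if not Path(p).is_absolute() else p

        config.catalog = resolve(config.catalog)
        config.hmg_msa = resolve(config.hmg_msa)
        config.sox_msa = resolve(config.sox_msa)
        config.correspondence = resolve(config.correspondence)
        config.trajectory = resolve(config.trajectory)
        config.variant_trajectory = resolve(config.variant_trajectory)
        config.structures = [resolve(s) for s in config.structures]
        for cplx in config.complexes:
            cplx.path = resolve(cplx.path)
        if not Path(config.out_dir).is_absolute():
            config.out_dir = str((base / config.out_dir).resolve())
        return config

    def digest(self) -> str:
        """Content hash of the config with paths reduced to basenames, so
        the same study rerun from a different directory hashes the same."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        for key in ("catalog", "hmg_msa", "sox_msa", "correspondence",
                    "trajectory", "variant_trajectory"):
            if payload[key] is not None:
                payload[key] = Path(payload[key]).name
        payload["structures"] = [Path(s).name for s in payload["structures"]]
        for cplx in payload["complexes"]:
            cplx["path"] = Path(cplx["path"]).name
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def validate(self) -> None:
        for label, p in (
            ("catalog", self.catalog),
            ("hmg_msa", self.hmg_msa),
            ("sox_msa", self.sox_msa),
            ("correspondence", self.correspondence),
            ("trajectory", self.trajectory),
            ("variant_trajectory", self.variant_trajectory),
        ):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: {label} path {p} does not exist")
        for s in self.structures:
            if not Path(s).exists():
                raise PipelineError(f"config: structure path {s} does not exist")
        for c in self.complexes:
            if not Path(c.path).exists():
                raise PipelineError(f"config: complex path {c.path} does not exist")


@dataclass
class RunResult:
    out_dir: Path
    stages_run: list[str]
    summary: dict


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _load_complex(spec: ComplexInput, interval_ps: float) -> ComplexTrajectory:
    traj = read_trajectory(spec.path, interval_ps)
    numbers = traj.frames[0].residue_numbers
    chains = traj.frames[0].chains
    receptor = frozenset(
        int(n) for n, c in zip(numbers, chains) if c == spec.receptor_chain
    )
    peptide = frozenset(
        int(n) for n, c in zip(numbers, chains) if c == spec.peptide_chain
    )
    return ComplexTrajectory(
        trajectory=traj,
        receptor_residues=receptor,
        peptide_residues=peptide,
        condition=Condition(spec.condition),
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage whose inputs are configured; merge the results.

    Writes, under ``config.out_dir``: stage TSVs, the merged per-residue
    annotation table, ``manifest.json`` and ``summary.txt``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stages_run: list[str] = []
    summary: dict = {"seed": config.seed}
    records = None
    report = None
    profile_annotated = None
    reference_seq = None

    def stage(name: str):
        def runner(fn):
            nonlocal stages_run
            try:
                fn()
            except Exception as exc:
                failed_marker.write_text(f"stage {name} failed: {exc}\n")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            stages_run.append(name)
            log.info("stage %s done", name)
        return runner

    hmg = sox = None
    if config.hmg_msa and config.sox_msa:
        hmg = read_aligned_fasta(config.hmg_msa, "HMG", config.reference_id)
        sox = read_aligned_fasta(config.sox_msa, "SOX", config.reference_id)
        reference_seq = hmg.reference_ungapped

    if config.catalog:
        @stage("catalog")
        def _catalog():
            nonlocal records
            records = load_variants(config.catalog, reference=reference_seq)
            cs = summarize_catalog(records)
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "n_variants": cs.n_variants,
                            "n_positions": cs.n_positions,
                            "n_proteins": cs.n_proteins,
                        }
                    ]
                ),
                out / "catalog_summary.tsv",
            )
            write_variants(records, out / "catalog.tsv")
            summary["catalog"] = {
                "n_variants": cs.n_variants,
                "n_positions": cs.n_positions,
                "n_proteins": cs.n_proteins,
            }
            log.info("catalog: %d variants", cs.n_variants)
    else:
        log.info("stage catalog skipped (no catalog configured)")

    if records is not None and hmg is not None and sox is not None:
        @stage("conservation")
        def _conservation():
            nonlocal report
            report = conservation_report(
                records, hmg, sox, threshold=config.threshold, mode=config.mode
            )
            write_conservation_report(report, out / "conservation_report.tsv")
            summary["partition"] = report.attrs["partition"]
    else:
        log.info("stage conservation skipped (needs catalog + both alignments)")

    if config.structures and config.correspondence:
        @stage("superpose")
        def _superpose():
            corr = read_aligned_fasta(
                config.correspondence, "correspondence", config.reference_id
            )
            models = {}
            for path in config.structures:
                model = clean_structure(path, config.structure_chain)
                # structure ids must match alignment rows; use the file stem
                models[Path(path).stem] = model
            if config.reference_id not in models:
                raise PipelineError(
                    f"reference structure {config.reference_id!r} not among inputs"
                )
            reference = models[config.reference_id]
            mobiles = [
                dc_replace(m, id=mid) for mid, m in sorted(models.items())
            ]
            results = superpose_ensemble(mobiles, reference, corr)
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "structure": r.mobile_id,
                            "n_pairs": r.n_pairs,
                            "rmsd": r.rmsd,
                        }
                        for r in results
                    ]
                ),
                out / "superposition.tsv",
            )
            dev_rows = []
            for r in results:
                for num, dev in zip(
                    r.paired_residue_numbers, r.per_residue_deviation
                ):
                    dev_rows.append(
                        {"structure": r.mobile_id, "residue": int(num), "deviation": dev}
                    )
            _write_tsv(pd.DataFrame(dev_rows), out / "superposition_residues.tsv")
            write_models(
                [r.transformed for r in results], out / "superposed_ensemble.pdb"
            )
            summary["superposition"] = {
                "n_structures": len(results),
                "mean_rmsd": float(
                    pd.Series([r.rmsd for r in results]).mean()
                ),
            }
    else:
        log.info("stage superpose skipped (needs structures + correspondence)")

    if config.trajectory:
        @stage("dynamics")
        def _dynamics():
            nonlocal profile_annotated
            traj = read_trajectory(config.trajectory, config.stored_interval_ps)
            traj = subsample_frames(traj, config.interval_ps)
            profile = per_residue_rmsd(traj, fit=config.fit)
            profile_annotated = annotate_dynamics(profile, report)
            _write_tsv(profile_annotated, out / "dynamics_profile.tsv")
            summary["dynamics"] = {
                "n_frames_used": profile.n_frames_used,
                "tier_mean_rmsd": {
                    k: round(v, 6)
                    for k, v in profile_annotated.attrs["tier_means"].items()
                },
            }
            if config.variant_trajectory:
                vtraj = read_trajectory(
                    config.variant_trajectory, config.stored_interval_ps
                )
                vtraj = subsample_frames(vtraj, config.interval_ps)
                vprofile = per_residue_rmsd(vtraj, fit=config.fit)
                comparison = compare_dynamics(profile, vprofile)
                _write_tsv(comparison, out / "dynamics_comparison.tsv")
                top = comparison.loc[comparison["delta"].idxmax()]
                summary["dynamics"]["largest_delta_residue"] = int(top["residue"])
    else:
        log.info("stage dynamics skipped (no trajectory configured)")

    if config.complexes:
        @stage("docking")
        def _docking():
            series = []
            for spec in config.complexes:
                cplx = _load_complex(spec, config.stored_interval_ps)
                s = peptide_displacement(cplx)
                series.append(s)
                _write_tsv(
                    s.as_frame(),
                    out / f"docking_{s.condition.value.lower()}.tsv",
                )
            if len(series) >= 2:
                ranking = compare_conditions(series)
                _write_tsv(ranking, out / "docking_comparison.tsv")
                summary["docking"] = {
                    row["condition"]: round(float(row["mean_displacement"]), 6)
                    for _, row in ranking.iterrows()
                }
    else:
        log.info("stage docking skipped (no complexes configured)")

    # merged per-residue annotation
    if reference_seq is not None:
        @stage("merge")
        def _merge():
            tier_map = {}
            freq_map = {}
            if report is not None:
                for _, row in report.iterrows():
                    tier_map[int(row["position"])] = str(row["tier"])
                    freq_map[int(row["position"])] = (
                        float(row["identity_freq_hmg"]),
                        float(row["identity_freq_sox"]),
                    )
            rmsd_map = {}
            if profile_annotated is not None:
                rmsd_map = {
                    int(r): float(v)
                    for r, v in zip(
                        profile_annotated["residue"], profile_annotated["mean_rmsd"]
                    )
                }
            rows = []
            for pos in range(1, len(reference_seq) + 1):
                has_nv = pos in tier_map
                rows.append(
                    {
                        "position": pos,
                        "wt": reference_seq[pos - 1],
                        "has_NV": has_nv,
                        "tier": tier_map.get(pos, ConservationTier.NO_VARIANT.value),
                        "identity_freq_hmg": freq_map.get(pos, (float("nan"),) * 2)[0],
                        "identity_freq_sox": freq_map.get(pos, (float("nan"),) * 2)[1],
                        "mean_rmsd": rmsd_map.get(pos, float("nan")),
                    }
                )
            _write_tsv(pd.DataFrame(rows), out / "residue_annotation.tsv")

    manifest = {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "resfunc_version": __version__,
        "stages": stages_run,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
    lines = [f"resfunc run (seed {config.seed})", f"stages: {', '.join(stages_run)}"]
    if "catalog" in summary:
        c = summary["catalog"]
        lines.append(
            f"catalog: {c['n_variants']} variants at {c['n_positions']} "
            f"positions in {c['n_proteins']} proteins"
        )
    if "partition" in summary:
        p = summary["partition"]
        lines.append(
            "conservation partition: "
            f"{p.get('HMG_CONSERVED', 0)} HMG-conserved / "
            f"{p.get('SOX_CONSERVED', 0)} Sox-only / "
            f"{p.get('NOT_CONSERVED', 0)} not conserved"
        )
    if "docking" in summary:
        parts = ", ".join(f"{k}={v:.3f}" for k, v in summary["docking"].items())
        lines.append(f"mean peptide displacement (Å): {parts}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return RunResult(out_dir=out, stages_run=stages_run, summary=summary)
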