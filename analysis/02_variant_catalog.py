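#!/usr/bin/env python
"""Summarise the disease-variant catalog.

Loads the study's variant table, validates every wild-type residue
against the reference domain sequence, and writes the headline counts.
"""

import importlib.util
from pathlib import Path

import pandas as pd

from resfunc.catalog import load_variants, summarize_catalog
from resfunc.conservation import read_aligned_fasta

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
    reference = read_aligned_fasta(study / "hmg.fasta", "HMG", "SRY").reference_ungapped
    records = load_variants(study / "catalog.tsv", reference=reference)
    summary = summarize_catalog(records)
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {
                "n_variants": summary.n_variants,
                "n_positions": summary.n_positions,
                "n_proteins": summary.n_proteins,
            }
        ]
    ).to_csv(RESULTS / "catalog_summary.tsv", sep="\t", index=False)
    per_protein = (
        pd.DataFrame([r.__dict__ for r in records])
        .groupby("protein_name")
        .agg(n_variants=("position", "size"), n_positions=("position", "nunique"))
        .reset_index()
    )
    per_protein.to_csv(RESULTS / "catalog_by_protein.tsv", sep="\t", index=False)
    print(
        f"{summary.n_variants} natural variants at {summary.n_positions} "
        f"distinct box positions in {summary.n_proteins} proteins"
    )
    print(per_protein.to_string(index=False))


if __name__ == "__main__":
    main()
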