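#!/usr/bin/env python
"""Classify every variant position's conservation tier.

Maps the 33 variant positions onto the family (69 HMG) and subfamily
(20 Sox) alignments and classifies each at the 90% threshold in class
mode: family-conserved, Sox-only, or unconserved.
"""

import importlib.util
from pathlib import Path

from resfunc.catalog import load_variants
from resfunc.conservation import (
    conservation_report,
    read_aligned_fasta,
    write_conservation_report,
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
    records = load_variants(study / "catalog.tsv")
    hmg = read_aligned_fasta(study / "hmg.fasta", "HMG-human", "SRY")
    sox = read_aligned_fasta(study / "sox.fasta", "SOX-human", "SRY")
    report = conservation_report(records, hmg, sox, threshold=0.90, mode="class")
    RESULTS.mkdir(exist_ok=True)
    write_conservation_report(report, RESULTS / "conservation_report.tsv")
    partition = report.attrs["partition"]
    print(
        f"of {len(report)} variant positions: "
        f"{partition['HMG_CONSERVED']} conserved across the HMG family, "
        f"{partition['SOX_CONSERVED']} only within Sox "
        f"({partition['HMG_CONSERVED'] + partition['SOX_CONSERVED']} Sox-conserved in total), "
        f"{partition['NOT_CONSERVED']} in neither"
    )
    hmg_tier = report[report["tier"] == "HMG_CONSERVED"]["position"].tolist()
    print(f"family-conserved positions: {hmg_tier}")


if __name__ == "__main__":
    main()
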