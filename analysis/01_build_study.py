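#!/usr/bin/env python
"""Generate the synthetic HMG-box study into scratch/study.

Writes the variant catalog (44 substitutions, 33 box positions, 5
proteins), the 69-sequence HMG and 20-sequence Sox alignments, the
18-member structure ensemble, wild-type and variant 1000 ps trajectories
(25 ps sampling), and the three 1500 ps receptor-peptide complexes —
plus a run.yaml so the whole pipeline can be replayed from disk.
"""

from pathlib import Path

from resfunc.catalog import summarize_catalog
from resfunc.studyio import write_study
from resfunc.synth import synth_study

SEED = 0
STUDY_DIR = Path(__file__).resolve().parent.parent / "scratch" / "study"


def build(seed: int = SEED, out_dir: Path = STUDY_DIR) -> Path:
    study = synth_study(seed)
    config = write_study(study, out_dir)
    summary = summarize_catalog(study.catalog)
    print(
        f"study (seed {seed}): {summary.n_variants} variants at "
        f"{summary.n_positions} positions in {summary.n_proteins} proteins"
    )
    print(
        f"alignments: {study.hmg.n_sequences} HMG sequences "
        f"({study.sox.n_sequences} Sox), domain length "
        f"{len(study.reference_sequence)}"
    )
    print(f"inputs written under {out_dir}; pipeline config at {config}")
    return config


if __name__ == "__main__":
    build()
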