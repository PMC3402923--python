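"""Alignment-column conservation scoring at family and subfamily level.

Variant positions live on the reference domain's own 1-based numbering;
this module maps them into gapped alignment columns and classifies each
position into a conservation tier by comparing column conservation in a
family-wide alignment (all human HMG boxes) and a subfamily alignment
(human Sox) against a frequency threshold (default 90%).

Conservation can be scored on residue identity alone or on
physicochemical classes. In class mode the conservation value of a column
is ``max(identity frequency, best class frequency)`` — every residue is
implicitly its own singleton class — so class-mode conservation is never
below identity-mode conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

GAP = "-"

#: Physicochemical classes used for class-mode conservation. Overlaps are
#: allowed (histidine is both aromatic and basic); the best class wins.
DEFAULT_CLASSES: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("AVLIMFWYC"),
    "aromatic": frozenset("FWYH"),
    "polar-basic": frozenset("KRH"),
    "polar-acidic": frozenset("DE"),
}


class ConservationError(ValueError):
    """Raised for invalid alignments, columns or positions."""


class ConservationTier(str, Enum):
    """Tier of a variant position, in decreasing breadth of conservation."""

    HMG_CONSERVED = "HMG_CONSERVED"
    SOX_CONSERVED = "SOX_CONSERVED"
    NOT_CONSERVED = "NOT_CONSERVED"
    NO_VARIANT = "NO_VARIANT"


@dataclass(frozen=True)
class AlignedSet:
    """A named multiple sequence alignment with a designated reference row."""

    name: str
    sequences: tuple[tuple[str, str], ...]  # (id, gapped sequence), order kept
    reference_id: str

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ConservationError(f"{self.name}: alignment is empty")
        widths = {len(seq) for _, seq in self.sequences}
        if len(widths) != 1:
            raise ConservationError(
                f"{self.name}: gapped sequence lengths differ ({sorted(widths)})"
            )
        if self.reference_id not in {sid for sid, _ in self.sequences}:
            raise ConservationError(
                f"{self.name}: reference id {self.reference_id!r} not in alignment"
            )

    @property
    def width(self) -> int:
        return len(self.sequences[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def get(self, seq_id: str) -> str:
        for sid, seq in self.sequences:
            if sid == seq_id:
                return seq
        raise KeyError(seq_id)

    @property
    def reference_sequence(self) -> str:
        return self.get(self.reference_id)

    @property
    def reference_ungapped(self) -> str:
        return self.reference_sequence.replace(GAP, "")


def make_aligned_set(
    name: str, sequences: Iterable[tuple[str, str]], reference_id: str
) -> AlignedSet:
    return AlignedSet(name=name, sequences=tuple(sequences), reference_id=reference_id)


def read_aligned_fasta(
    path: str | Path, name: str, reference_id: str
) -> AlignedSet:
    """Read a gapped FASTA alignment into an :class:`AlignedSet`."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return make_aligned_set(name, records, reference_id)


def write_aligned_fasta(aligned: AlignedSet, path: str | Path, wrap: int = 60) -> None:
    with Path(path).open("w") as handle:
        for sid, seq in aligned.sequences:
            handle.write(f">{sid}\n")
            for start in range(0, len(seq), wrap):
                handle.write(seq[start : start + wrap] + "\n")


@dataclass(frozen=True)
class AlignmentColumnProfile:
    """Residue and class frequencies at one gapped alignment column."""

    column: int  # 1-based gapped column index
    residue_counts: Mapping[str, int]
    gap_count: int
    identity_freq: float
    class_freqs: Mapping[str, float]
    n_sequences: int = field(default=0)

    @property
    def non_gap_count(self) -> int:
        return self.n_sequences - self.gap_count

    @property
    def gap_fraction(self) -> float:
        return self.gap_count / self.n_sequences if self.n_sequences else 0.0

    @property
    def modal_residue(self) -> str:
        """Most common residue; ties broken by amino-acid alphabetical order."""
        if not self.residue_counts:
            return ""
        return min(self.residue_counts, key=lambda aa: (-self.residue_counts[aa], aa))

    def conservation(self, mode: str = "class") -> float:
        """Column conservation under ``identity`` or ``class`` scoring."""
        if mode == "identity":
            return self.identity_freq
        if mode == "class":
            best_class = max(self.class_freqs.values(), default=0.0)
            return max(self.identity_freq, best_class)
        raise ValueError(f"unknown conservation mode {mode!r}")

    def best_class(self) -> tuple[str, float]:
        if not self.class_freqs:
            return ("", 0.0)
        name = min(self.class_freqs, key=lambda c: (-self.class_freqs[c], c))
        return (name, self.class_freqs[name])


def map_position_to_column(
    aligned: AlignedSet, position: int, seq_id: str | None = None
) -> int:
    """Map a 1-based ungapped position of the reference row to its gapped column.

    Returns the 1-based gapped column holding the ``position``-th non-gap
    character of the reference (or of ``seq_id`` when given).
    """
    seq = aligned.get(seq_id) if seq_id is not None else aligned.reference_sequence
    if position < 1:
        raise ConservationError(f"position must be >= 1, got {position}")
    seen = 0
    for col, char in enumerate(seq, start=1):
        if char != GAP:
            seen += 1
            if seen == position:
                return col
    raise ConservationError(
        f"{aligned.name}: position {position} beyond ungapped length {seen} "
        f"of reference {aligned.reference_id!r}"
    )


def column_profile(
    aligned: AlignedSet,
    column: int,
    class_map: Mapping[str, frozenset[str]] | None = None,
) -> AlignmentColumnProfile:
    """Tally residues, gaps, identity and class frequencies at one column."""
    if class_map is None:
        class_map = DEFAULT_CLASSES
    if not 1 <= column <= aligned.width:
        raise ConservationError(
            f"{aligned.name}: column {column} outside gapped width {aligned.width}"
        )
    counts: dict[str, int] = {}
    gaps = 0
    for _, seq in aligned.sequences:
        char = seq[column - 1]
        if char == GAP:
            gaps += 1
        else:
            counts[char] = counts.get(char, 0) + 1
    non_gap = aligned.n_sequences - gaps
    identity = max(counts.values()) / non_gap if non_gap else 0.0
    class_freqs = {}
    if non_gap:
        for cname, members in class_map.items():
            in_class = sum(n for aa, n in counts.items() if aa in members)
            class_freqs[cname] = in_class / non_gap
    return AlignmentColumnProfile(
        column=column,
        residue_counts=counts,
        gap_count=gaps,
        identity_freq=identity,
        class_freqs=class_freqs,
        n_sequences=aligned.n_sequences,
    )


def classify_position(
    position: int,
    hmg: AlignedSet,
    sox: AlignedSet,
    threshold: float = 0.90,
    mode: str = "class",
    max_gap_fraction: float = 0.5,
    class_map: Mapping[str, frozenset[str]] | None = None,
) -> ConservationTier:
    """Classify one variant position against family and subfamily alignments.

    The position is mapped through each alignment's reference row. A column
    conserved at or above ``threshold`` in the family-wide set is
    HMG_CONSERVED; otherwise at-threshold conservation in the subfamily set
    gives SOX_CONSERVED; otherwise NOT_CONSERVED. Columns gapped in more
    than ``max_gap_fraction`` of the rows are never called conserved —
    frequency over a handful of non-gap rows is not evidence of family-level
    conservation.
    """
    tiers = []
    for aligned in (hmg, sox):
        col = map_position_to_column(aligned, position)
        prof = column_profile(aligned, col, class_map=class_map)
        too_gappy = prof.gap_fraction > max_gap_fraction
        tiers.append((not too_gappy) and prof.conservation(mode) >= threshold)
    hmg_ok, sox_ok = tiers
    if hmg_ok:
        return ConservationTier.HMG_CONSERVED
    if sox_ok:
        return ConservationTier.SOX_CONSERVED
    return ConservationTier.NOT_CONSERVED


def conservation_report(
    records: Sequence,
    hmg: AlignedSet,
    sox: AlignedSet,
    threshold: float = 0.90,
    mode: str = "class",
    class_map: Mapping[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Per-position conservation table for the distinct variant positions.

    One row per distinct box-relative variant position, with the tier and
    the identity / best-class frequencies in each alignment. The tier
    partition counts are attached as ``df.attrs["partition"]``.
    """
    positions = sorted({rec.position for rec in records})
    rows = []
    for pos in positions:
        tier = classify_position(
            pos, hmg, sox, threshold=threshold, mode=mode, class_map=class_map
        )
        row: dict[str, object] = {"position": pos, "tier": tier.value}
        for label, aligned in (("hmg", hmg), ("sox", sox)):
            col = map_position_to_column(aligned, pos)
            prof = column_profile(aligned, col, class_map=class_map)
            cname, cfreq = prof.best_class()
            row[f"identity_freq_{label}"] = prof.identity_freq
            row[f"best_class_{label}"] = cname
            row[f"best_class_freq_{label}"] = cfreq
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=[
            "position",
            "tier",
            "identity_freq_hmg",
            "identity_freq_sox",
            "best_class_hmg",
            "best_class_freq_hmg",
            "best_class_sox",
            "best_class_freq_sox",
        ],
    )
    partition = {tier.value: 0 for tier in ConservationTier}
    for _, row in df.iterrows():
        partition[str(row["tier"])] += 1
    df.attrs["partition"] = partition
    return df


def write_conservation_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write the report as TSV with the partition counts in a comment footer."""
    path = Path(path)
    with path.open("w") as handle:
        df.to_csv(handle, sep="\t", index=False, float_format="%.6f")
        partition = df.attrs.get("partition", {})
        if partition:
            parts = ", ".join(f"{k}={v}" for k, v in sorted(partition.items()))
            handle.write(f"# partition: {parts}\n")
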