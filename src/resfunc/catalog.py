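"""Disease-variant catalog for HMG-box positions.

A catalog row records one disease-associated amino-acid substitution at a
position numbered relative to the first residue of the protein's own HMG
box (1-based). Cross-protein comparison of positions happens only after
alignment-column mapping (see :mod:`resfunc.conservation`); here positions
are plain box-relative integers, which is how the clinical literature
reports them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Marker used for deletion variants in the ``var`` column.
DELETION = "-"

REQUIRED_FIELDS = ("protein", "accession", "position", "wt", "var", "phenotype")


class CatalogError(ValueError):
    """Raised for malformed catalog files or rows."""


class CatalogValidationError(CatalogError):
    """Raised when a row conflicts with the supplied reference sequence."""


@dataclass(frozen=True)
class VariantRecord:
    """One disease-associated substitution at an HMG-box position."""

    protein_name: str
    accession: str
    position: int  # 1-based, relative to the protein's own HMG box
    wt_residue: str
    var_residue: str  # one-letter amino acid, or "-" for a deletion
    phenotype: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CatalogError(f"position must be >= 1, got {self.position}")
        if self.wt_residue not in AMINO_ACIDS:
            raise CatalogError(f"invalid wild-type residue {self.wt_residue!r}")
        if self.var_residue not in AMINO_ACIDS and self.var_residue != DELETION:
            raise CatalogError(f"invalid variant residue {self.var_residue!r}")
        if self.wt_residue == self.var_residue:
            raise CatalogError(
                f"wild-type and variant residue are both {self.wt_residue!r} "
                f"at position {self.position}"
            )


@dataclass(frozen=True)
class CatalogSummary:
    n_variants: int
    n_positions: int
    n_proteins: int


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def load_variants(
    path: str | Path,
    reference: str | None = None,
) -> list[VariantRecord]:
    """Load a delimited variant table (comma or tab, auto-detected).

    Parameters
    ----------
    path:
        Text table whose header names the fields
        ``protein, accession, position, wt, var, phenotype``.
    reference:
        Optional ungapped domain sequence. When given, every row's
        wild-type residue is checked against ``reference[position - 1]``
        and the position is required to fall inside the sequence.

    Raises
    ------
    CatalogError
        For a missing/invalid header or a malformed row (the message names
        the offending file line).
    CatalogValidationError
        When a wild-type residue disagrees with the reference.
    """
    path = Path(path)
    with path.open(newline="") as handle:
        first = handle.readline()
        if not first.strip():
            raise CatalogError(f"{path}: empty file, expected a header line")
        delim = _detect_delimiter(first)
        header = [h.strip().lower() for h in first.strip().split(delim)]
        missing = [f for f in REQUIRED_FIELDS if f not in header]
        if missing:
            raise CatalogError(f"{path}: header is missing fields {missing}")
        reader = csv.reader(handle, delimiter=delim)
        idx = {name: header.index(name) for name in REQUIRED_FIELDS}

        records: list[VariantRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < len(header):
                raise CatalogError(
                    f"{path}, line {lineno}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )
            cell = {name: row[idx[name]].strip() for name in REQUIRED_FIELDS}
            try:
                position = int(cell["position"])
            except ValueError as exc:
                raise CatalogError(
                    f"{path}, line {lineno}: position {cell['position']!r} "
                    f"is not an integer"
                ) from exc
            try:
                record = VariantRecord(
                    protein_name=cell["protein"],
                    accession=cell["accession"],
                    position=position,
                    wt_residue=cell["wt"].upper(),
                    var_residue=cell["var"].upper(),
                    phenotype=cell["phenotype"],
                )
            except CatalogError as exc:
                raise CatalogError(f"{path}, line {lineno}: {exc}") from exc
            if reference is not None:
                if position > len(reference):
                    raise CatalogValidationError(
                        f"{path}, line {lineno}: position {position} outside "
                        f"reference of length {len(reference)}"
                    )
                expected = reference[position - 1].upper()
                if record.wt_residue != expected:
                    raise CatalogValidationError(
                        f"{path}, line {lineno}: wild-type {record.wt_residue} "
                        f"at position {position} does not match reference "
                        f"residue {expected}"
                    )
            records.append(record)
    return records


def write_variants(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Re-emit records as the canonical tab-separated table."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(REQUIRED_FIELDS)
        for rec in records:
            writer.writerow(
                [
                    rec.protein_name,
                    rec.accession,
                    rec.position,
                    rec.wt_residue,
                    rec.var_residue,
                    rec.phenotype,
                ]
            )


def summarize_catalog(
    records: Sequence[VariantRecord],
    per_protein_positions: bool = False,
) -> CatalogSummary:
    """Count variants, distinct positions and distinct proteins.

    Distinct positions pool the box-relative position value across proteins
    by default, because the shared box numbering is what makes positions
    comparable between family members; ``per_protein_positions=True``
    counts ``(protein, position)`` pairs instead.
    """
    if per_protein_positions:
        positions = {(r.protein_name, r.position) for r in records}
    else:
        positions = {r.position for r in records}
    proteins = {r.protein_name for r in records}
    return CatalogSummary(
        n_variants=len(records),
        n_positions=len(positions),
        n_proteins=len(proteins),
    )
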