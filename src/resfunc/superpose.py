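"""Least-squares rigid superposition (Kabsch) and ensemble fitting.

Residue correspondence for ensemble superposition comes from a sequence
alignment, never from raw PDB residue numbers (deposited numbering is
inconsistent across entries): Cα pairs are taken at alignment columns
where both the mobile structure and the reference are non-gapped, and the
optimal proper rotation/translation is found by reflection-corrected SVD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .conservation import GAP, AlignedSet
from .structures import StructureModel


class FitError(ValueError):
    """Raised for degenerate point sets (<3 pairs, collinear geometry)."""


class CorrespondenceError(ValueError):
    """Raised when a structure's sequence conflicts with its alignment row."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rigid transform of a mobile point set onto a target.

    The transform maps mobile coordinates as ``x -> rotation @ x +
    translation``. ``per_residue_deviation`` holds the post-fit distance of
    each pair, so ``rmsd**2`` equals the mean of its squares.
    """

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_pairs: int
    per_residue_deviation: np.ndarray  # (n_pairs,)
    mobile_id: str = ""
    transformed: StructureModel | None = None
    paired_residue_numbers: np.ndarray | None = None


def kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Fit ``mobile`` onto ``target`` by least squares over paired points.

    Both arrays are (n, 3) with n >= 3 non-collinear pairs. The returned
    rotation is always proper (determinant +1): a mirror image cannot be
    superposed to zero RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise FitError(
            f"paired (n,3) arrays required, got {mobile.shape} and {target.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise FitError(f"need >= 3 pairs, got {n}")
    centered = mobile - mobile.mean(axis=0)
    # rank < 2 means all points collinear: rotation about the line is free
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise FitError("degenerate geometry: mobile points are collinear")

    sup = SVDSuperimposer()
    sup.set(target, mobile)
    sup.run()
    rot_row, tran = sup.get_rotran()  # row-vector convention: x @ rot + tran
    rotation = rot_row.T
    translation = tran
    moved = mobile @ rot_row + tran
    deviations = np.linalg.norm(moved - target, axis=1)
    rmsd = float(np.sqrt(np.mean(deviations**2)))
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        rmsd=rmsd,
        n_pairs=n,
        per_residue_deviation=deviations,
    )


def _alignment_pairs(
    mobile_row: str, reference_row: str
) -> tuple[np.ndarray, np.ndarray]:
    """Ungapped indices (0-based) paired at mutually non-gap columns."""
    mob_idx, ref_idx = [], []
    i = j = 0
    for cm, cr in zip(mobile_row, reference_row):
        if cm != GAP and cr != GAP:
            mob_idx.append(i)
            ref_idx.append(j)
        if cm != GAP:
            i += 1
        if cr != GAP:
            j += 1
    return np.array(mob_idx, dtype=int), np.array(ref_idx, dtype=int)


def superpose_structure(
    mobile: StructureModel,
    reference: StructureModel,
    correspondence: AlignedSet,
    mobile_id: str | None = None,
    reference_id: str | None = None,
) -> SuperpositionResult:
    """Superpose one structure onto the reference via alignment-guided pairs."""
    mob_id = mobile_id or mobile.id
    ref_id = reference_id or correspondence.reference_id
    mob_row = correspondence.get(mob_id)
    ref_row = correspondence.get(ref_id)
    for row, model, label in ((mob_row, mobile, mob_id), (ref_row, reference, ref_id)):
        ungapped = row.replace(GAP, "")
        if ungapped != model.sequence:
            raise CorrespondenceError(
                f"{label}: structure sequence does not match its alignment row "
                f"({model.sequence[:10]}... vs {ungapped[:10]}...)"
            )
    mob_idx, ref_idx = _alignment_pairs(mob_row, ref_row)
    fit = kabsch_fit(mobile.coords[mob_idx], reference.coords[ref_idx])
    return SuperpositionResult(
        rotation=fit.rotation,
        translation=fit.translation,
        rmsd=fit.rmsd,
        n_pairs=fit.n_pairs,
        per_residue_deviation=fit.per_residue_deviation,
        mobile_id=mob_id,
        transformed=mobile.transformed(fit.rotation, fit.translation),
        paired_residue_numbers=mobile.residue_numbers[mob_idx],
    )


def superpose_ensemble(
    structures: list[StructureModel],
    reference: StructureModel,
    correspondence: AlignedSet,
    reference_id: str | None = None,
) -> list[SuperpositionResult]:
    """Superpose every structure of an ensemble onto the reference.

    Each structure is fitted independently, so the output does not depend
    on the order of the input list.
    """
    return [
        superpose_structure(s, reference, correspondence, reference_id=reference_id)
        for s in structures
    ]
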