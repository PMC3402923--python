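"""Synthetic study generator with known ground truth.

Every pipeline stage is testable without downloads: this module emits
alignments with controllable per-column conservation, ideal helical Cα
folds, trajectories as Gaussian per-residue fluctuation around a
reference (with optional rigid-body jitter), and receptor–peptide complex
trajectories under docked / alanine-docked / free regimes.

Seeding: one global seed fans out to per-generator child seeds through
fixed stream ids (``numpy`` ``SeedSequence`` spawn keys), so adding a new
generator never perturbs the output of existing ones.

:func:`synth_study` bundles the generators into the default synthetic
HMG-box study: 44 disease variants over 33 box positions in 5 proteins,
a 69-sequence human HMG family alignment containing a 20-sequence Sox
subfamily, an 18-member structure ensemble, wild-type and variant
1000 ps trajectories sampled every 25 ps, and three 1500 ps
receptor–peptide complexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .catalog import AMINO_ACIDS, VariantRecord
from .conservation import (
    DEFAULT_CLASSES,
    AlignedSet,
    ConservationTier,
    make_aligned_set,
)
from .docking import ComplexTrajectory, Condition
from .dynamics import Trajectory
from .structures import StructureModel, sequence_to_names

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Stream ids for seed fan-out; append-only, never renumber.
STREAM_MSA = 1
STREAM_TRAJ = 2
STREAM_COMPLEX = 3
STREAM_VARIANTS = 4
STREAM_STUDY = 5


class SpecError(ValueError):
    """Raised for unconstructible generator specifications."""


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Child generator for one stream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservationSpec:
    """Per-column conservation targets for a synthetic alignment.

    ``columns`` maps a 1-based column to ``(target, frequency)`` where
    ``target`` is either a one-letter residue or the name of a
    physicochemical class from ``class_map``; unspecified columns are
    drawn uniformly from the alphabet.
    """

    n_sequences: int
    length: int
    columns: Mapping[int, tuple[str, float]] = field(default_factory=dict)
    alphabet: str = ALPHABET
    class_map: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 1:
            raise SpecError("need at least one sequence and one column")
        for col, (target, freq) in self.columns.items():
            if not 1 <= col <= self.length:
                raise SpecError(f"column {col} outside length {self.length}")
            if not 1.0 / len(self.alphabet) <= freq <= 1.0:
                raise SpecError(
                    f"column {col}: target frequency {freq} not constructible "
                    f"over a {len(self.alphabet)}-letter alphabet"
                )
            if len(target) == 1:
                if target not in self.alphabet:
                    raise SpecError(f"column {col}: {target!r} not in alphabet")
            elif target not in self.class_map:
                raise SpecError(f"column {col}: unknown class {target!r}")

    def target_symbols(self, column: int) -> tuple[str, ...]:
        """Sorted symbols satisfying the column's target."""
        target, _ = self.columns[column]
        if len(target) == 1:
            return (target,)
        return tuple(sorted(self.class_map[target] & set(self.alphabet)))


def synth_msa(
    spec: ConservationSpec,
    seed: int,
    name: str = "synthetic",
    ids: Sequence[str] | None = None,
    id_prefix: str = "seq",
    reference_id: str | None = None,
    reference_overrides: Mapping[int, str] | None = None,
) -> AlignedSet:
    """Generate an ungapped alignment meeting the conservation spec.

    The first row is the reference: deterministically conserved at every
    specified column (class targets use the alphabetically first class
    member) so that downstream position mapping and wild-type lookups have
    a stable anchor. ``reference_overrides`` pins chosen reference residues
    at *unspecified* columns. Reproducible bit-for-bit under ``seed``.
    """
    rng = child_rng(seed, STREAM_MSA)
    if ids is None:
        ids = [f"{id_prefix}{i + 1:03d}" for i in range(spec.n_sequences)]
    if len(ids) != spec.n_sequences:
        raise SpecError(f"{len(ids)} ids for {spec.n_sequences} sequences")
    reference_overrides = dict(reference_overrides or {})
    alphabet = list(spec.alphabet)

    rows = []
    for row_index in range(spec.n_sequences):
        chars = []
        for col in range(1, spec.length + 1):
            if col in spec.columns:
                symbols = spec.target_symbols(col)
                _, freq = spec.columns[col]
                if row_index == 0:
                    chars.append(symbols[0])
                elif rng.random() < freq:
                    chars.append(symbols[rng.integers(len(symbols))])
                else:
                    others = [aa for aa in alphabet if aa not in symbols]
                    chars.append(others[rng.integers(len(others))])
            elif row_index == 0 and col in reference_overrides:
                chars.append(reference_overrides[col])
            else:
                chars.append(alphabet[rng.integers(len(alphabet))])
        rows.append((ids[row_index], "".join(chars)))
    return make_aligned_set(name, rows, reference_id or ids[0])


def synth_variant_table(
    msa: AlignedSet,
    positions: Sequence[int],
    seed: int,
    protein_name: str = "SYN1",
    accession: str = "SYN0001",
    phenotype: str = "synthetic phenotype",
) -> list[VariantRecord]:
    """One random non-wild-type substitution per requested position.

    Wild-type residues are read from the alignment's reference row
    (ungapped numbering); positions beyond the reference raise.
    """
    rng = child_rng(seed, STREAM_VARIANTS)
    reference = msa.reference_ungapped
    records = []
    for pos in positions:
        if not 1 <= pos <= len(reference):
            raise SpecError(
                f"position {pos} outside reference length {len(reference)}"
            )
        wt = reference[pos - 1]
        others = sorted(AMINO_ACIDS - {wt})
        var = others[rng.integers(len(others))]
        records.append(
            VariantRecord(
                protein_name=protein_name,
                accession=accession,
                position=int(pos),
                wt_residue=wt,
                var_residue=var,
                phenotype=phenotype,
            )
        )
    return records


# ---------------------------------------------------------------------------
# structures and trajectories
# ---------------------------------------------------------------------------

def synth_helix(
    n_residues: int,
    sequence: str | None = None,
    model_id: str = "helix",
    chain: str = "A",
    start_number: int = 1,
    rise: float = 1.5,
    twist_deg: float = 100.0,
    radius: float = 2.3,
) -> StructureModel:
    """Ideal α-helical Cα trace (1.5 Å rise, 100° twist, 2.3 Å radius).

    Deterministic — no seed. Poly-alanine unless a sequence is given.
    """
    if n_residues < 4:
        raise SpecError(f"need at least 4 residues for a helix, got {n_residues}")
    if sequence is not None and len(sequence) != n_residues:
        raise SpecError("sequence length does not match n_residues")
    i = np.arange(n_residues)
    theta = np.deg2rad(twist_deg) * i
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * i]
    )
    names = sequence_to_names(sequence) if sequence else ("ALA",) * n_residues
    return StructureModel(
        id=model_id,
        residue_numbers=np.arange(start_number, start_number + n_residues),
        residue_names=names,
        coords=coords,
        chains=(chain,) * n_residues,
    )


@dataclass(frozen=True)
class FluctuationSpec:
    """Gaussian per-residue fluctuation parameters for a trajectory.

    ``sigma`` is the per-coordinate standard deviation in Å of each
    residue's displacement from the reference, independent across frames
    (the analysed statistic is distribution-level, not kinetic).
    ``n_frames`` counts frames *including* the initial structure.
    ``rigid_jitter`` optionally adds a random whole-frame rotation (max
    degrees) about the centroid plus translation (max Å) per frame.
    """

    sigma: np.ndarray
    n_frames: int
    frame_interval_ps: float = 25.0
    rigid_jitter: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma < 0):
            raise SpecError("sigma values must be >= 0")
        if self.n_frames < 1:
            raise SpecError("need at least one frame")


def _random_rigid(
    rng: np.random.Generator, max_rot_deg: float, max_trans: float
) -> tuple[np.ndarray, np.ndarray]:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_rot_deg))
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    trans = direction * rng.uniform(0.0, max_trans)
    return rot, trans


def synth_trajectory(
    reference: StructureModel, spec: FluctuationSpec
) -> Trajectory:
    """Trajectory of independent Gaussian fluctuation around a reference.

    Frame 0 is the reference itself; each later frame displaces residue i
    by an isotropic Gaussian of scale ``sigma[i]``, then optionally
    applies a random rigid-body jitter to the whole frame.
    """
    if len(spec.sigma) != len(reference):
        raise SpecError(
            f"sigma length {len(spec.sigma)} != residue count {len(reference)}"
        )
    rng = child_rng(spec.seed, STREAM_TRAJ)
    frames = [reference]
    for t in range(1, spec.n_frames):
        coords = reference.coords + rng.normal(size=(len(reference), 3)) * (
            spec.sigma[:, None]
        )
        if spec.rigid_jitter is not None:
            rot, trans = _random_rigid(rng, *spec.rigid_jitter)
            centroid = coords.mean(axis=0)
            coords = (coords - centroid) @ rot.T + centroid + trans
        frames.append(
            StructureModel(
                id=f"{reference.id}@{t}",
                residue_numbers=reference.residue_numbers,
                residue_names=reference.residue_names,
                coords=coords,
                chains=reference.chains,
            )
        )
    return Trajectory(
        frames=tuple(frames),
        frame_interval_ps=spec.frame_interval_ps,
        label=reference.id,
    )


def tether_stationary_mean(sigma: float) -> float:
    """Mean length of an isotropic Gaussian 3-vector of scale ``sigma``.

    The stationary mean displacement of a rigid peptide whose pose offset
    is redrawn from N(0, sigma^2 I_3) each frame: E|g| = 2 sigma sqrt(2/pi).
    """
    return 2.0 * sigma * math.sqrt(2.0 / math.pi)


def synth_complex_trajectory(
    receptor: StructureModel,
    peptide: StructureModel,
    condition: Condition | str,
    params: Mapping[str, float] | None = None,
    seed: int = 0,
    n_frames: int = 61,
    frame_interval_ps: float = 25.0,
    offset: Sequence[float] = (12.0, 0.0, 0.0),
) -> ComplexTrajectory:
    """Receptor–peptide complex trajectory under one binding regime.

    The peptide is placed with its centroid ``offset`` from the
    receptor's. Per frame, the receptor fluctuates with a small Gaussian
    (``receptor_sigma``); the peptide moves rigidly by the condition's
    process: DOCKED and DOCKED_ALA redraw the pose offset from an
    isotropic Gaussian tether (``tether_sigma``, the alanine mutant's
    tether being weaker), FREE takes fixed-length random-walk steps
    (``step`` Å/frame). ``peptide_sigma`` adds internal peptide noise.
    """
    condition = Condition(condition)
    defaults: dict[str, float] = {"receptor_sigma": 0.2, "peptide_sigma": 0.0}
    if condition is Condition.DOCKED:
        defaults["tether_sigma"] = 0.5
    elif condition is Condition.DOCKED_ALA:
        defaults["tether_sigma"] = 1.5
    elif condition is Condition.FREE:
        defaults["step"] = 0.5
    merged = {**defaults, **dict(params or {})}
    unknown = set(merged) - set(defaults)
    if unknown:
        raise SpecError(f"unknown parameters for {condition.value}: {sorted(unknown)}")

    rng = child_rng(seed, STREAM_COMPLEX)
    rec_n = len(receptor)
    pep_pose = (
        peptide.coords
        - peptide.coords.mean(axis=0)
        + receptor.coords.mean(axis=0)
        + np.asarray(offset, dtype=float)
    )
    pep_numbers = np.arange(
        receptor.residue_numbers.max() + 101,
        receptor.residue_numbers.max() + 101 + len(peptide),
    )
    all_numbers = np.concatenate([receptor.residue_numbers, pep_numbers])
    all_names = receptor.residue_names + peptide.residue_names
    all_chains = ("A",) * rec_n + ("B",) * len(peptide)

    def make_frame(t: int, rec_coords: np.ndarray, pep_coords: np.ndarray):
        return StructureModel(
            id=f"complex@{t}",
            residue_numbers=all_numbers,
            residue_names=all_names,
            coords=np.vstack([rec_coords, pep_coords]),
            chains=all_chains,
        )

    frames = [make_frame(0, receptor.coords, pep_pose)]
    walk = np.zeros(3)
    for t in range(1, n_frames):
        rec = receptor.coords + rng.normal(size=(rec_n, 3)) * merged["receptor_sigma"]
        if condition is Condition.FREE:
            if merged["step"] > 0:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                walk = walk + merged["step"] * direction
            pose_offset = walk
        else:
            pose_offset = rng.normal(size=3) * merged["tether_sigma"]
        pep = pep_pose + pose_offset
        if merged["peptide_sigma"] > 0:
            pep = pep + rng.normal(size=pep.shape) * merged["peptide_sigma"]
        frames.append(make_frame(t, rec, pep))
    traj = Trajectory(
        frames=tuple(frames),
        frame_interval_ps=frame_interval_ps,
        label=f"complex-{condition.value.lower()}",
    )
    return ComplexTrajectory(
        trajectory=traj,
        receptor_residues=frozenset(int(r) for r in receptor.residue_numbers),
        peptide_residues=frozenset(int(r) for r in pep_numbers),
        condition=condition,
    )


# ---------------------------------------------------------------------------
# the default synthetic study
# ---------------------------------------------------------------------------

DOMAIN_LENGTH = 79

#: Variant positions conserved across the whole HMG family, with the
#: physicochemical character conserved there: aromatics packing the three
#: helices (9, 12, 40, 51), hydrophobics organising the fold and
#: non-specific DNA contact (6, 32, 43), and a basic DNA contact (48).
HMG_CONSERVED_POSITIONS: dict[int, str] = {
    6: "hydrophobic",
    9: "aromatic",
    12: "aromatic",
    32: "hydrophobic",
    40: "aromatic",
    43: "hydrophobic",
    48: "polar-basic",
    51: "aromatic",
}

#: Variant positions conserved only within the Sox subfamily (includes the
#: minor-groove DNA-specificity contacts 4 and 29), with the invariant
#: residue placed there in the Sox rows.
SOX_ONLY_POSITIONS: dict[int, str] = {
    4: "R",
    10: "Q",
    14: "E",
    18: "S",
    22: "T",
    25: "G",
    27: "K",
    29: "N",
    31: "P",
    35: "D",
    37: "H",
    41: "Q",
    47: "S",
    50: "K",
    54: "E",
    57: "T",
    61: "G",
    64: "N",
    67: "D",
}

#: Variant positions conserved in neither set; 16 and 45 are the
#: protein-interaction candidates (alanine in the reference).
NOT_CONSERVED_POSITIONS: tuple[int, ...] = (2, 16, 20, 45, 56, 63)

SOX_IDS = (
    "SRY", "SOX1", "SOX2", "SOX3", "SOX4", "SOX5", "SOX6", "SOX7",
    "SOX8", "SOX9", "SOX10", "SOX11", "SOX12", "SOX13", "SOX14",
    "SOX15", "SOX17", "SOX18", "SOX21", "SOX30",
)
N_NON_SOX = 49

#: Catalog proteins; almost all variants sit in Sox members, two in HMGB1.
CATALOG_PROTEINS = {
    "SRY": "Q05066",
    "SOX9": "P48436",
    "SOX10": "P56693",
    "SOX2": "P48431",
    "HMGB1": "P09429",
}

#: The wild-type vs variant dynamics comparison is run at this position
#: (an unconserved surface alanine whose variant loosens local dynamics).
FOCUS_VARIANT_POSITION = 16

SIGMA_CONSERVED = 0.3  # Å, per-coordinate, at conserved positions
SIGMA_FLEXIBLE = 1.0  # Å elsewhere
DYNAMICS_N_FRAMES = 41  # 1000 ps every 25 ps, t = 0 included
DOCKING_N_FRAMES = 61  # 1500 ps every 25 ps


def nv_positions() -> tuple[int, ...]:
    return tuple(
        sorted(
            set(HMG_CONSERVED_POSITIONS)
            | set(SOX_ONLY_POSITIONS)
            | set(NOT_CONSERVED_POSITIONS)
        )
    )


def true_tier(position: int) -> ConservationTier:
    if position in HMG_CONSERVED_POSITIONS:
        return ConservationTier.HMG_CONSERVED
    if position in SOX_ONLY_POSITIONS:
        return ConservationTier.SOX_CONSERVED
    if position in NOT_CONSERVED_POSITIONS:
        return ConservationTier.NOT_CONSERVED
    return ConservationTier.NO_VARIANT


@dataclass(frozen=True)
class SyntheticStudy:
    """One fully generated study with its ground truth."""

    seed: int
    catalog: tuple[VariantRecord, ...]
    hmg: AlignedSet
    sox: AlignedSet
    reference_sequence: str
    reference_structure: StructureModel
    ensemble: tuple[StructureModel, ...]
    correspondence: AlignedSet
    wildtype_traj: Trajectory
    variant_traj: Trajectory
    complexes: Mapping[str, ComplexTrajectory]
    sigma_profile: np.ndarray


def _study_catalog(
    reference: str, rng: np.random.Generator
) -> tuple[VariantRecord, ...]:
    """44 variants over the 33 ground-truth positions in 5 proteins.

    Eleven positions carry a second, distinct substitution. HMGB1 carries
    exactly two variants (positions 45 and 56); the focus position 16
    belongs to SOX9.
    """
    positions = nv_positions()
    assignment: dict[int, str] = {45: "HMGB1", 56: "HMGB1", 16: "SOX9"}
    rotation = ("SRY", "SOX9", "SOX10", "SOX2")
    others = [p for p in positions if p not in assignment]
    for i, pos in enumerate(others):
        assignment[pos] = rotation[i % len(rotation)]

    phenotypes = {
        "SRY": "gonadal dysgenesis-like (synthetic)",
        "SOX9": "campomelic dysplasia-like (synthetic)",
        "SOX10": "Waardenburg-like (synthetic)",
        "SOX2": "microphthalmia-like (synthetic)",
        "HMGB1": "carcinoma cell line-like (synthetic)",
    }

    def substitution(wt: str, exclude: set[str]) -> str:
        pool = sorted(AMINO_ACIDS - {wt} - exclude)
        return pool[rng.integers(len(pool))]

    records: list[VariantRecord] = []
    duplicated = [p for p in positions if assignment[p] not in ("HMGB1",)][:11]
    for pos in positions:
        protein = assignment[pos]
        wt = reference[pos - 1]
        var1 = substitution(wt, set())
        records.append(
            VariantRecord(
                protein_name=protein,
                accession=CATALOG_PROTEINS[protein],
                position=pos,
                wt_residue=wt,
                var_residue=var1,
                phenotype=phenotypes[protein],
            )
        )
        if pos in duplicated:
            records.append(
                VariantRecord(
                    protein_name=protein,
                    accession=CATALOG_PROTEINS[protein],
                    position=pos,
                    wt_residue=wt,
                    var_residue=substitution(wt, {var1}),
                    phenotype=phenotypes[protein],
                )
            )
    return tuple(records)


def synth_study(seed: int = 0) -> SyntheticStudy:
    """Generate the default synthetic HMG-box study.

    Ground truth: the 33 variant positions partition 8 / 19 / 6 across
    the HMG-conserved, Sox-only and unconserved tiers; conserved
    positions fluctuate less (sigma 0.3 Å vs 1.0 Å); the variant
    trajectory doubles sigma at position 16; the free peptide wanders
    while the docked one stays tethered.
    """
    rng = child_rng(seed, STREAM_STUDY)

    class_cols = {
        pos: (cls, 1.0) for pos, cls in HMG_CONSERVED_POSITIONS.items()
    }
    sox_cols = dict(class_cols)
    sox_cols.update(
        {pos: (aa, 1.0) for pos, aa in SOX_ONLY_POSITIONS.items()}
    )
    overrides = {16: "A", 45: "A"}  # unconserved surface alanines

    sox = synth_msa(
        ConservationSpec(n_sequences=len(SOX_IDS), length=DOMAIN_LENGTH, columns=sox_cols),
        seed=int(rng.integers(2**31)),
        name="SOX-human",
        ids=SOX_IDS,
        reference_id="SRY",
        reference_overrides=overrides,
    )
    non_sox = synth_msa(
        ConservationSpec(n_sequences=N_NON_SOX, length=DOMAIN_LENGTH, columns=class_cols),
        seed=int(rng.integers(2**31)),
        name="HMG-non-sox",
        id_prefix="HMG",
    )
    hmg = make_aligned_set(
        "HMG-human", tuple(sox.sequences) + tuple(non_sox.sequences), "SRY"
    )
    reference_sequence = sox.reference_ungapped

    catalog = _study_catalog(reference_sequence, rng)

    # 18-member structure ensemble: the reference fold plus rigidly moved,
    # locally perturbed copies sharing the reference sequence.
    reference_structure = synth_helix(
        DOMAIN_LENGTH, sequence=reference_sequence, model_id="SRY"
    )
    ensemble = [reference_structure]
    corr_rows = [("SRY", reference_sequence)]
    for i in range(17):
        rot, trans = _random_rigid(rng, 180.0, 20.0)
        noise = rng.normal(size=reference_structure.coords.shape) * 0.5
        coords = (reference_structure.coords + noise) @ rot.T + trans
        member_id = f"ENS{i + 1:02d}"
        ensemble.append(
            StructureModel(
                id=member_id,
                residue_numbers=reference_structure.residue_numbers,
                residue_names=reference_structure.residue_names,
                coords=coords,
            )
        )
        corr_rows.append((member_id, reference_sequence))
    correspondence = make_aligned_set("structure-correspondence", corr_rows, "SRY")

    # dynamics: conserved positions are stiff, others flexible; the
    # variant doubles sigma at the focus position
    conserved = set(HMG_CONSERVED_POSITIONS) | set(SOX_ONLY_POSITIONS)
    sigma = np.full(DOMAIN_LENGTH, SIGMA_FLEXIBLE)
    for pos in conserved:
        sigma[pos - 1] = SIGMA_CONSERVED
    sigma_variant = sigma.copy()
    sigma_variant[FOCUS_VARIANT_POSITION - 1] *= 2.0

    jitter = (5.0, 1.0)
    wildtype_traj = synth_trajectory(
        reference_structure,
        FluctuationSpec(
            sigma=sigma,
            n_frames=DYNAMICS_N_FRAMES,
            rigid_jitter=jitter,
            seed=int(rng.integers(2**31)),
        ),
    )
    variant_traj = synth_trajectory(
        reference_structure,
        FluctuationSpec(
            sigma=sigma_variant,
            n_frames=DYNAMICS_N_FRAMES,
            rigid_jitter=jitter,
            seed=int(rng.integers(2**31)),
        ),
    )

    peptide = synth_helix(12, model_id="CTE", chain="B")
    complexes = {}
    for condition in (Condition.DOCKED, Condition.DOCKED_ALA, Condition.FREE):
        complexes[condition.value] = synth_complex_trajectory(
            reference_structure,
            peptide,
            condition,
            seed=int(rng.integers(2**31)),
            n_frames=DOCKING_N_FRAMES,
        )

    return SyntheticStudy(
        seed=seed,
        catalog=catalog,
        hmg=hmg,
        sox=sox,
        reference_sequence=reference_sequence,
        reference_structure=reference_structure,
        ensemble=tuple(ensemble),
        correspondence=correspondence,
        wildtype_traj=wildtype_traj,
        variant_traj=variant_traj,
        complexes=complexes,
        sigma_profile=sigma,
    )
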