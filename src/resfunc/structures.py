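"""Cα structure models and PDB input/output.

The only coordinate representative used anywhere in this package is the
alpha carbon: superposition, per-residue dynamics and peptide displacement
are all Cα-level observables, so a structure is an ordered list of
(residue number, residue name, Cα coordinate) triples. Structures are read
from and written to plain PDB (ATOM / MODEL / ENDMDL records); multi-model
files serve both as NMR ensembles and as the trajectory dialect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.PDB.PDBIO import PDBIO
from Bio.SeqUtils import seq1, seq3


class StructureError(ValueError):
    """Raised for unusable coordinate files or residues."""


@dataclass(frozen=True)
class StructureModel:
    """Ordered Cα trace of one cleaned domain (coordinates in Å).

    ``chains`` carries one chain id per residue so a receptor–peptide
    complex can live in a single model; plain domains use one chain.
    """

    id: str
    residue_numbers: np.ndarray  # (n,) int, strictly increasing
    residue_names: tuple[str, ...]  # 3-letter codes
    coords: np.ndarray  # (n, 3) float, Å
    chains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        numbers = np.asarray(self.residue_numbers, dtype=int)
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "residue_numbers", numbers)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (len(numbers), 3):
            raise StructureError(
                f"{self.id}: coords shape {coords.shape} does not match "
                f"{len(numbers)} residues"
            )
        if len(self.residue_names) != len(numbers):
            raise StructureError(f"{self.id}: residue name/number length mismatch")
        if len(numbers) > 1 and not np.all(np.diff(numbers) > 0):
            raise StructureError(f"{self.id}: residue numbers not strictly increasing")
        if not self.chains:
            object.__setattr__(self, "chains", ("A",) * len(numbers))
        elif len(self.chains) != len(numbers):
            raise StructureError(f"{self.id}: chain annotation length mismatch")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    @property
    def sequence(self) -> str:
        """One-letter sequence; unknown residues become X."""
        return "".join(seq1(name, undef_code="X") for name in self.residue_names)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Apply ``x -> R x + t`` to every Cα."""
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return replace(self, coords=new)

    def subset(self, residue_numbers) -> "StructureModel":
        wanted = set(int(r) for r in residue_numbers)
        mask = np.array([int(r) in wanted for r in self.residue_numbers])
        return replace(
            self,
            residue_numbers=self.residue_numbers[mask],
            residue_names=tuple(n for n, m in zip(self.residue_names, mask) if m),
            coords=self.coords[mask],
            chains=tuple(c for c, m in zip(self.chains, mask) if m),
        )


def from_residues(
    model_id: str,
    residues,  # iterable of (number, 3-letter name, (x, y, z))
    chain: str = "A",
) -> StructureModel:
    numbers, names, coords = [], [], []
    for num, name, xyz in residues:
        numbers.append(num)
        names.append(name)
        coords.append(xyz)
    return StructureModel(
        id=model_id,
        residue_numbers=np.array(numbers, dtype=int),
        residue_names=tuple(names),
        coords=np.array(coords, dtype=float),
        chains=(chain,) * len(numbers),
    )


def sequence_to_names(sequence: str) -> tuple[str, ...]:
    """One-letter sequence to 3-letter residue names (X -> UNK)."""
    return tuple(
        "UNK" if aa == "X" else seq3(aa).upper() for aa in sequence.upper()
    )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_pdb(path: str | Path):
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return parser.get_structure(Path(path).stem, str(path))


def _model_to_structure_model(
    bio_model, model_id: str, chain: str | None
) -> StructureModel:
    """Extract standard amino acids with a Cα from one Bio.PDB model.

    Waters, ions, nucleic-acid chains and other heteroatoms are dropped.
    """
    chain_ids = [c.id for c in bio_model]
    if chain is not None and chain not in chain_ids:
        raise KeyError(
            f"{model_id}: chain {chain!r} not present (have {chain_ids})"
        )
    residues = []
    chains = []
    for bio_chain in bio_model:
        if chain is not None and bio_chain.id != chain:
            continue
        for res in bio_chain:
            if not is_aa(res, standard=True):
                continue  # water, ions, nucleotides, modified residues
            if "CA" not in res:
                raise StructureError(
                    f"{model_id}: residue {res.get_resname()} "
                    f"{res.id[1]} has no CA atom"
                )
            residues.append((res.id[1], res.get_resname(), res["CA"].coord))
            chains.append(bio_chain.id)
    if chain is None and residues:
        # keep only protein chains; numbering must stay strictly increasing,
        # so multi-chain models get per-residue chain ids
        pass
    numbers = np.array([r[0] for r in residues], dtype=int)
    coords = np.array([r[2] for r in residues], dtype=float).reshape(len(residues), 3)
    return StructureModel(
        id=model_id,
        residue_numbers=numbers,
        residue_names=tuple(r[1] for r in residues),
        coords=coords,
        chains=tuple(chains),
    )


def clean_structure(
    path: str | Path,
    chain: str,
    model_index: int = 1,
) -> StructureModel:
    """Clean a PDB file down to the bare domain's Cα trace.

    Retains only standard amino-acid residues of ``chain`` from model
    ``model_index`` (1-based file order; NMR ensembles default to the first
    reported member). Everything that is not part of the domain — waters,
    salts, nucleic acids, other protein chains — is discarded.
    """
    structure = _parse_pdb(path)
    models = list(structure)
    if not 1 <= model_index <= len(models):
        raise StructureError(
            f"{path}: model {model_index} requested, file has {len(models)}"
        )
    return _model_to_structure_model(
        models[model_index - 1], f"{Path(path).stem}:{chain}", chain
    )


def read_models(path: str | Path, chain: str | None = None) -> list[StructureModel]:
    """Read every model of a (possibly multi-model) PDB file."""
    structure = _parse_pdb(path)
    out = []
    for i, bio_model in enumerate(structure, start=1):
        out.append(
            _model_to_structure_model(bio_model, f"{Path(path).stem}#{i}", chain)
        )
    if not out:
        raise StructureError(f"{path}: no models found")
    return out


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_models(models, path: str | Path) -> None:
    """Write one or more Cα models as a (multi-model) PDB file."""
    if isinstance(models, StructureModel):
        models = [models]
    builder = StructureBuilder()
    builder.init_structure("resfunc")
    for serial, model in enumerate(models):
        builder.init_model(serial, serial)
        builder.init_seg("    ")
        current_chain = None
        for num, name, xyz, chain in zip(
            model.residue_numbers, model.residue_names, model.coords, model.chains
        ):
            if chain != current_chain:
                builder.init_chain(chain)
                current_chain = chain
            builder.init_residue(name, " ", int(num), " ")
            builder.init_atom(
                "CA", np.asarray(xyz, dtype=float), 0.0, 1.0, " ", " CA ", element="C"
            )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# NMR-ensemble agreement trimming
# ---------------------------------------------------------------------------

def ensemble_spread(models: list[StructureModel]) -> np.ndarray:
    """Per-residue Cα spread across ensemble members, after fitting each
    member onto the first over all Cα.

    Spread is the maximum deviation of any member's Cα from the
    member-mean position. All members must share the residue list.
    """
    from .superpose import kabsch_fit  # local import to avoid a cycle

    first = models[0]
    stacked = [first.coords]
    for model in models[1:]:
        if not np.array_equal(model.residue_numbers, first.residue_numbers):
            raise StructureError("ensemble members differ in residue numbering")
        fit = kabsch_fit(model.coords, first.coords)
        stacked.append(model.coords @ fit.rotation.T + fit.translation)
    arr = np.stack(stacked)  # (m, n, 3)
    mean = arr.mean(axis=0)
    return np.linalg.norm(arr - mean, axis=2).max(axis=0)


def trim_high_spread(
    models: list[StructureModel], threshold: float = 2.0
) -> list[StructureModel]:
    """Drop residues whose ensemble Cα spread exceeds ``threshold`` Å.

    Implements "regions of high agreement" selection for NMR ensembles;
    the default 2.0 Å keeps well-defined core regions and removes frayed
    termini. Returns models restricted to the agreeing residues.
    """
    spread = ensemble_spread(models)
    keep = models[0].residue_numbers[spread <= threshold]
    return [m.subset(keep) for m in models]
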