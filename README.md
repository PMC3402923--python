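# resfunc

Residue-function profiling of HMG-box domains.

The HMG box is a ~79-residue, three-helix, L-shaped domain that binds the
DNA minor groove; in the Sox subfamily of transcription factors (SRY,
SOX9, ...) single amino-acid substitutions in this box cause diseases
from gonadal dysgenesis to campomelic dysplasia. Knowing *which* box
position does *what* — structural packing, DNA contact, or
protein–protein interaction — requires combining several partial lines of
evidence. `resfunc` implements that integration as a reusable, tested
pipeline for structural bioinformaticians studying this (or any similar)
domain family:

1. **Variant catalog** — disease-associated substitutions at box-relative
   positions, validated against the reference domain sequence.
2. **Conservation tiers** — each variant position is mapped through a
   family-wide alignment (all human HMG boxes, one sequence per domain)
   and a subfamily alignment (the 20 human Sox), and classified at a
   ≥ 90% threshold: conserved family-wide, conserved only in Sox, or
   unconserved. Conservation can be scored on residue identity or on
   physicochemical classes (hydrophobic, aromatic, polar-basic,
   polar-acidic), since family-level constraints often preserve character
   rather than identity.
3. **Ensemble superposition** — structures are cleaned to bare Cα domain
   traces (waters, ions, DNA and extraneous chains dropped; NMR
   ensembles reduced to their first model, optionally trimmed to regions
   of high agreement) and fitted to the reference by alignment-guided
   Kabsch superposition.
4. **Per-residue dynamics** — from multi-model PDB trajectories, the
   RMSD of each residue's Cα from its *initial* position, averaged over
   frames after whole-domain fitting:
   `RMSD_i = sqrt( (1/T) Σ_t ‖x_i(t) − x_i(0)‖² )`.
   Note this is deviation from the start, not fluctuation about the mean
   (an RMSF) — a residue that drifts and settles elsewhere scores high
   here. Stiff, conserved positions score low.
5. **Docking stability** — for receptor–peptide complexes (e.g. the
   androgen-receptor C-terminal extension on SRY), the peptide's Cα
   displacement in the receptor's frame of reference, compared across
   docked, alanine-substituted and free regimes.
6. **Synthetic data** — generators for alignments with controllable
   column conservation, ideal helices, Gaussian-fluctuation trajectories
   and tethered/free complex trajectories, so every stage is testable
   against known ground truth without downloading anything.

## Worked example

The `analysis/` scripts run the whole study on synthetic data with known
ground truth (regenerated on demand under `scratch/study/`):

```bash
python analysis/01_build_study.py
python analysis/02_variant_catalog.py
python analysis/03_conservation.py
python analysis/05_residue_dynamics.py
python analysis/06_docking_stability.py
```

prints, among other things:

```
44 natural variants at 33 distinct box positions in 5 proteins
of 33 variant positions: 8 conserved across the HMG family, 19 only
  within Sox (27 Sox-conserved in total), 6 in neither
family-conserved positions: [6, 9, 12, 32, 40, 43, 48, 51]
  mean Cα RMSD,  HMG_CONSERVED: 0.54 Å
  mean Cα RMSD,  NOT_CONSERVED: 1.70 Å
variant vs wild type: largest increase at residue 16 (+1.68 Å)
        FREE: 2.93 Å   DOCKED_ALA: 2.48 Å   DOCKED: 0.81 Å
```

Reading: of the 33 disease-variant positions, 8 are constrained across
the entire family (packing/DNA-contact residues — and they are also the
stiffest in the dynamics profile, mean RMSD ≈ 0.5 Å), 19 more only
within Sox, and 6 in neither — those 6 (e.g. position 16) are candidates
for member-specific protein-interaction roles, consistent with the
variant trajectory loosening dynamics exactly there. The docked peptide
stays within ~0.8 Å of its pose while the free one wanders ~3 Å,
i.e. the modelled interaction is stable and sequence-dependent.

The same run is available as one command over a study directory:

```bash
resfunc synth --out scratch/study --seed 0
resfunc run --config scratch/study/run.yaml
```

## Layout

- `src/resfunc/` — the library: `catalog`, `conservation`, `structures`,
  `superpose`, `dynamics`, `docking`, `synth`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library; tables land
  in `results/`, bulky regenerable inputs in `scratch/`.
- `tests/` — unit, property and end-to-end suites (pytest + hypothesis).
- `docs/methods.md` — models, parameters, numerical choices, limitations.
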