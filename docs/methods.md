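# Methods

## Scope and data model

The package analyses one protein domain family on a shared, 1-based
"box-relative" coordinate system: position *p* means the *p*-th residue
of a protein's own HMG box. Positions become comparable across proteins
only after mapping through a multiple sequence alignment; nothing in the
package compares raw PDB residue numbers across entries, because
deposited numbering is inconsistent. The sole coordinate representative
is the Cα atom: superposition, dynamics and docking observables are all
Cα-level, which is the resolution at which backbone stiffness and pose
stability are meaningful and side-chain noise is not.

Proteins with several HMG boxes are expected to be pre-split into one
sequence per domain before alignment; the alignment reader does not
enforce this beyond the domain-scale length of its inputs.

## Variant catalog

A variant record is a single-position substitution (or deletion, encoded
`-`) with protein, accession, box position, wild-type and variant
residue, and free-text phenotype. Validation rejects silent
substitutions, non-amino-acid codes and, when a reference sequence is
supplied, wild-type residues that contradict it. Summary counting pools
*distinct positions across proteins* by default: the shared box numbering
is exactly what makes "33 variant positions in 5 proteins" a meaningful
statement; a flag switches to per-protein distinctness.

## Conservation tiers

For a variant position, the corresponding gapped column is located in
each alignment (the column holding the position-th non-gap character of
the reference row). Column conservation is:

- **identity mode** — the modal residue's frequency over non-gap rows;
- **class mode** (default) — `max(identity, best physicochemical class
  frequency)` with classes hydrophobic {A,V,L,I,M,F,W,Y,C}, aromatic
  {F,W,Y,H}, polar-basic {K,R,H}, polar-acidic {D,E}. Taking the max
  with identity makes every residue implicitly its own singleton class,
  so class-mode conservation is never below identity-mode — an invariant
  the tests enforce. Class mode is the default because family-level
  constraints at packing positions preserve character (any bulky
  hydrophobic will do) rather than identity.

Tier assignment at threshold *τ* = 0.90 ("conserved at 90% or greater"
reads as ≥): family-conserved if the family-wide column is ≥ τ; else
Sox-conserved if the subfamily column is ≥ τ; else unconserved. Columns
gapped in more than half the rows are never called conserved — a
frequency over a handful of non-gap rows is not family-level evidence.
Gaps are otherwise excluded from the denominator. Positions without any
variant record are tiered NO_VARIANT by the pipeline, not by the
classifier. Modal-residue ties break alphabetically (reporting only;
frequencies are unaffected).

## Superposition

`kabsch_fit` computes the least-squares proper rotation + translation
over paired points via reflection-corrected SVD (Biopython's
`SVDSuperimposer` under the hood, with degenerate-geometry checks — at
least 3 non-collinear pairs — and per-pair deviations added on top).
Reflections are forbidden: a mirror image cannot reach zero RMSD.
Ensemble superposition pairs Cα through alignment columns where both the
mobile structure and the reference are non-gapped, after verifying that
each structure's sequence matches its alignment row exactly. All paired
Cα enter the fit; no outlier rejection (whole-domain superposition is
the intended observable). The test suite checks the fit against an
independent brute-force nested Euler-angle grid search to 10⁻³ Å on
random small point sets.

Structure cleaning keeps standard amino acids of one chain of one model
(model 1 by default — the first reported NMR ensemble member); waters,
ions, nucleic acids and other chains are discarded. "Regions of high
agreement" in NMR ensembles are implemented as an optional trim that
drops residues whose Cα spread across members (after fitting each onto
the first) exceeds a threshold, default 2.0 Å — large enough to keep a
well-defined core, small enough to remove frayed termini.

## Per-residue dynamics

`RMSD_i = sqrt((1/T) Σ_{t=1..T} ‖x_i(t) − x_i(0)‖²)` over the T
post-initial frames; frame 0 is excluded (it contributes an identical
zero and would deflate every value). The reference is the *initial*
structure, not the time-average: the observable deliberately measures
departure from the starting conformation, not fluctuation about the mean
(an RMSF). Before measuring, each frame is superposed onto frame 0 over
all Cα (default); without a fit, centre-of-mass drift and tumbling
dominate and per-residue values are meaningless. `fit="none"` is kept
for oracle tests whose generators guarantee no net motion.

A Parseval-style identity of this definition — the mean over residues of
RMSD_i² equals the mean squared whole-structure deviation — is used as a
property test.

**Known bias of the fitted estimator.** Fitting a noisy frame onto a
noiseless reference absorbs part of the noise into the six rigid-body
degrees of freedom: per-residue RMSD is biased low by roughly a factor
`sqrt(1 − h_i)` where `h_i` is the residue's leverage in the fit
(≈ 2/N on average, larger at the extremities of elongated shapes). For
the 79-residue fixtures used here the worst-case bias is about 6%, which
is why scale-recovery checks allow 5% without fitting and 7% with it.
Heteroscedastic noise concentrated at high-leverage residues compounds
the effect; recovery checks with graded noise therefore run unfitted.

Subsampling keeps frames at t = 0, Δ, 2Δ, … and requires the analysis
interval to be an integer multiple of the stored one; 1000 ps stored
every 1 ps analysed every 25 ps gives 41 frames including t = 0.

## Docking stability

"Movement" of a docked peptide is its Cα RMSD against the frame-0 pose
*in the receptor's frame*: each frame is fitted onto frame 0 using
receptor Cα only, so rigid motion of the whole complex cancels exactly
and only relative peptide motion is measured. A centre-of-mass metric is
available behind a flag (insensitive to internal peptide deformation).
Conditions are ranked by mean displacement. Pose generation and binding
energetics are out of scope; the module consumes trajectories from any
source.

## Synthetic generators

Generators exist so that every stage can be tested against constructed
ground truth. They are deterministic given a seed; one global seed fans
out to per-generator child seeds through fixed `SeedSequence` spawn-key
stream ids (append-only), so adding a generator never perturbs existing
output.

- **Alignments**: per-column targets (residue or class, with a
  frequency); the first row is a deterministically conserved reference.
  Unspecified columns are uniform over the 20 amino acids.
- **Structures**: ideal α-helical Cα traces (rise 1.5 Å, twist 100°,
  radius 2.3 Å — standard helix geometry chosen as a convenient
  non-degenerate fold, not a claim about HMG geometry).
- **Trajectories**: frame 0 is the reference; later frames add
  independent isotropic Gaussian displacements per residue (σ_i),
  optionally followed by a random whole-frame rigid jitter. Displacements
  are independent across frames — the analysed statistic is
  distribution-level and needs no kinetics. Closed form: E‖ε‖² = 3σ²,
  so RMSD_i → σ_i·√3.
- **Complexes**: the receptor fluctuates with small σ; the peptide moves
  rigidly by regime — DOCKED/DOCKED_ALA redraw the pose offset from an
  isotropic Gaussian tether each frame (stationary mean displacement
  2σ√(2/π); the alanine mutant is simply a weaker tether, not
  chemistry), FREE takes fixed-length random-walk steps whose
  displacement grows with time.

### The default study

`synth_study(seed)` encodes the study conditions as ground truth:

- 79-residue domain; 69-sequence family alignment of which 20 are the
  Sox subfamily (SRY is the reference row of both).
- 33 variant positions: 8 family-conserved — aromatics 9, 12, 40, 51;
  hydrophobics 6, 32, 43; a basic 48 — as class-conserved columns
  (class frequency 1, identity < 1); 19 Sox-only conserved (invariant
  residues, including the DNA-specificity contacts 4 and 29); 6
  conserved in neither, including the surface alanines 16 and 45.
  Conserved columns are generated invariant (target frequency 1.0): what
  is known is *which* positions are conserved at ≥ 90%, not their exact
  frequencies, and encoding them as invariant makes the ground-truth
  partition exact rather than probabilistic. Unconserved columns are
  uniform draws, whose probability of spuriously reaching 90% is
  negligible at these set sizes.
- Catalog: 44 variants over those 33 positions in 5 proteins (11
  positions carry a second substitution); HMGB1 carries exactly two, at
  45 and 56; position 16 belongs to SOX9 with an A→V substitution.
- 18-member structure ensemble: the reference fold plus 17 rigidly
  displaced copies with 0.5 Å/coordinate local noise.
- Dynamics: 1000 ps at 25 ps (41 frames), σ = 0.3 Å at conserved
  positions vs 1.0 Å elsewhere, plus whole-frame jitter (≤ 5°, ≤ 1 Å)
  that the fitting stage must remove; the variant trajectory doubles σ
  at position 16.
- Docking: 1500 ps at 25 ps (61 frames); tether σ 0.5 Å (docked),
  1.5 Å (alanine-docked), random-walk step 0.5 Å/frame (free).

### What the generators do and do not emulate

The generators reproduce the *statistical shape* of the study — counts,
conservation structure, stiffness contrasts, tether-vs-walk regimes —
with known ground truth, so passing tests demonstrate that the analysis
code measures what it claims to measure. They do not emulate real
sequence phylogeny (columns are independent; no evolutionary
correlation), real protein geometry (helical toy folds), force-field
kinetics (no autocorrelation, no solvent) or real docking chemistry.
Results on real data therefore inherit the method's correctness from
these tests, but not any biological conclusion.

## Pipeline

Stages run in dependency order (catalog → conservation → superposition →
dynamics → docking → merge); a stage whose inputs are not configured is
skipped with a logged notice. Outputs are flat TSVs with a fixed float
format, a merged per-residue annotation table, a `manifest.json` (seed,
package version, config content hash with paths reduced to basenames so
relocation does not change it) and a plain-text summary. No output
contains a timestamp: identical config + seed reproduces the bundle byte
for byte, and the test suite hash-compares two full runs. A failing
stage aborts the run, names itself in the exception and leaves a
`FAILED` marker.

## Problem sizes

Test and acceptance runs use the study sizes above (69/20 sequences,
18 structures, 41- and 61-frame trajectories) plus 500-frame trajectories
for scale recovery, 100 random instances for the superposition oracle and
20 seed replicates for the docked-vs-free comparison; the whole suite
runs in about a minute on one CPU.

## Limitations

- Conservation is unweighted by phylogeny; heavily sampled subfamilies
  dominate column frequencies.
- The per-residue RMSD-from-start conflates drift and fluctuation by
  design; use an RMSF if fluctuation about the mean is wanted.
- The fitted-estimator absorption bias (above) means profiles of short
  or highly elongated chains read a few percent low at the ends.
- mmCIF, binary trajectory formats (DCD/XTC) and structural-alignment
  computation are out of scope; correspondence comes from a sequence
  alignment supplied by the caller.
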