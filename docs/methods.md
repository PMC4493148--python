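# Methods

`endock` is a self-contained toolkit for ensemble docking and
structure-based virtual screening: it docks small molecules into multiple
receptor structures with an empirical, grid-accelerated scoring function and
a multi-start Monte-Carlo search, ranks compounds by their mean score across
the ensemble, quantifies redocking accuracy by RMSD, and reports
protein–ligand contacts.  This note describes the model, its parameters, the
numerical choices, and what the synthetic test bed does and does not show.

## Structure model and preparation

Structures are handled in the PDBQT dialect (PDB extended with partial
charges, AutoDock atom types, and a ROOT/BRANCH/TORSDOF rotatable-bond
tree); plain PDB and Mol2 are converted on ingest (PDB through gemmi, Mol2
through RDKit with SMARTS-based rotatable-bond perception).  Receptor
preparation removes waters and non-metal hetero groups (counts recorded;
stripped ligands are returned on request, since a bound ligand defines the
search box).  Metal ions are *kept* in the parsed structure so that
`detect_metal_ions` can flag them: structures carrying metals are excluded
from ensembles because empirical scoring functions handle them poorly.
Alternate locations: altloc `A` or blank is kept, others dropped, for
deterministic preparation.  Hydrogens are retained when present; polar
hydrogens mark their parent heavy atom as a hydrogen-bond donor.

Atom types follow the AutoDock4/Vina table (`C`, aromatic `A`, `N`/`NA`,
`O`/`OA`, `S`/`SA`, `H`/`HD`, halogens, `P`, metals).  Hydrophobic =
{C, A, F, Cl, Br, I}; acceptors = {NA, OA, SA}; type-level donors are
non-acceptor nitrogens and metals.  Partial charges are read from PDBQT when
present and default to 0 otherwise (the scoring function below does not use
them; charge assignment is out of scope).

A pose is `(position, orientation, torsions)`: a rigid transform of the root
frame (origin = the first ROOT atom's reference position; orientation a unit
quaternion) followed by successive rotations of each BRANCH subtree about
its bond axis, applied in file (depth-first) order.  Coordinates are a
deterministic function of these parameters.

## Search box

The box is the smallest cube covering the bound ligand, extended by 10 Å:
the extension is added to the edge length (+5 Å per side).  The alternative
reading (+10 Å per side) is available via `mode="side"`.  This choice is a
documented convention; the screening results are insensitive to it for
ligands that bind in the middle of the site, because both boxes cover the
pocket with a generous margin.

## Scoring function

The score is the five-term empirical free-energy function of the Vina
family, evaluated on the *surface* distance `d = r − (R_a + R_b)` between
heavy-atom pairs (vdW radii from the xs typing table; hydrogens are not
scored centers):

| term        | shape                                   | weight     |
|-------------|-----------------------------------------|------------|
| gauss1      | exp(−(d/0.5)²)                          | −0.035579  |
| gauss2      | exp(−((d−3)/2)²)                        | −0.005156  |
| repulsion   | d² for d < 0, else 0                    | +0.840245  |
| hydrophobic | 1 for d≤0.5, 0 for d≥1.5, linear ramp   | −0.035069  |
| hbond       | 1 for d≤−0.7, 0 for d≥0, linear ramp    | −0.587439  |

Terms vanish identically beyond an 8 Å surface-distance cutoff.  The
hydrophobic term applies to hydrophobic–hydrophobic pairs, the hbond term to
donor–acceptor pairs (either direction).  The intra-molecular energy sums
the same terms over ligand heavy-atom pairs separated by three or more
bonds.  All weights are configurable through `ScoringParams`.

The reported score ("estimated binding free energy", kcal/mol, more negative
= stronger) is the inter-molecular energy of the pose divided by
`1 + w_rot · N_rot` with `w_rot = 0.05846`: the pose's own intra-molecular
energy is the reference, so it steers the search but cancels from the
report.  This normalization convention is documented here because the family
of tools using this functional form differ in their intra-reference; it is
configurable in one place (`normalized_score`).

## Grid maps

For each AutoDock type present in a ligand, the receptor field is
precomputed on a cubic lattice over the box (node spacing `spacing`, lattice
dimensions `floor(edge/spacing)+1` per axis, origin at the box's lower
corner) and poses are scored by trilinear interpolation.  The production
default spacing is 0.08 Å; tests and the synthetic studies use 0.25–0.5 Å as
an explicitly scaled-down setting (the per-module docs state this) to keep
memory and build time small.  Stored node values are clamped at ±10⁴
kcal/mol.  A requested lattice exceeding the configured memory budget raises
an error advising a coarser spacing.

Fidelity contract: in the smooth (non-clashing, `inter ≤ 0`) region the
interpolated inter-energy matches the direct pair sum to ≤ 0.05 kcal/mol
per ligand atom at 0.25 Å spacing, and the maximum error decreases
monotonically with spacing (measured at 1.0/0.5/0.25 Å).  Near steep
repulsive walls the trilinear error is larger; those poses carry strongly
penalized scores either way, so ranking is unaffected.  Atoms outside the
lattice are clamped to the boundary value and charged a quadratic
out-of-box penalty (5 kcal/mol/Å², configurable), which drives optimization
back inside; docking builds its lattice on a padded box (+2 Å) so the
penalty, not lattice clamping, governs at the sampling-box boundary.

## Monte-Carlo search

A docking run launches `n_tasks` independent tasks (default 256, mirroring
the production setting; the synthetic studies use 64) and pools their
minima.  Each task is basin-hopping with Metropolis acceptance:

1. Start from a random pose — orientation uniform on SO(3), torsions uniform
   in (−π, π], position drawn half uniform over the box and half from a
   normal centered on the box center (σ = edge/8).  The center bias reflects
   how the box is constructed: around the bound-ligand site.
2. Refine locally by derivative-free pattern search: every iteration
   evaluates ± moves along the three translation axes, three rotation axes
   and each torsion, takes the best improving neighbor, and halves the steps
   when none improves; it stops when the translation step falls below
   0.05 Å.  Rotation moves are re-centered on the ligand's heavy-atom
   centroid (rotating about the root-end atom swings the far end out of its
   contacts and stalls the descent).
3. Hop: perturb the current minimum (translation σ 1.0 Å, rotation σ 1.0
   rad, one torsion σ 1.5 rad), or with probability 0.25 redraw position
   (center-biased), orientation and torsions outright; refine; accept by the
   Metropolis rule at kT = 1.2 kcal/mol.  The budget is 6·(1+N_rot) hops.
4. The best minimum ever visited is the task's result (non-increasing by
   construction).

Tasks own independent RNG streams (`SeedSequence((seed, task_index))`), so
the result is identical whether tasks run sequentially or — as implemented —
advanced in lockstep with each refinement iteration batched into a single
vectorized energy call (the test suite asserts bit-identity of the two
routes).  Pooled minima are sorted by score, filtered to mutually distinct
poses (pairwise heavy-atom RMSD > 2 Å), capped at nine, and finally
"hop-polished": a few rounds of small correlated perturbation plus full
refinement per kept pose, which crosses the narrow ridges that axis-aligned
moves cannot, then re-sorted and re-filtered.

## Ensemble screening

Each compound is docked into every structure of the ensemble; the best
(lowest) score per structure is collected, and compounds are ranked
ascending by the arithmetic mean over successful structures.  The reported
spread is the sample (n−1) standard deviation.  Failed dockings are listed
and excluded from the mean rather than imputed; a compound failing more than
20% of structures is flagged.  Ties in the mean break by ascending std, then
compound id, making the ranking a total order invariant under input
permutation.  Score histograms use upper-bound-inclusive bins
(`u − w < s ≤ u`), so a mean of −10.46 falls in the (−10.5, −10.0] bin;
top-compound selection takes rows with mean ≤ the ceiling (default
−10 kcal/mol, boundary inclusive).  Per-(compound, structure) results are
cached on disk under a content-derived key (ids, seed, task count, weights),
with the per-pair seed derived independently of execution order, so
interrupted screens resume to byte-identical tables.

## Redocking evaluation

RMSD is the plain fixed-order heavy-atom root-mean-square deviation in the
shared docking frame: no superposition, no graph-symmetry correction
(matching the convention of the evaluation this package follows; a
symmetry-aware option is deliberately out of the default path, and the
caveat is that symmetric ligands can show inflated RMSD).  "Pose 1" is the
best-scoring pose (RMSD1), "pose m" the pose of minimum RMSD among the ≤ 9
returned (RMSDm); RMSDm ≤ RMSD1 by definition, which the record constructor
asserts.  Success counts use strict inequality at the threshold (default
2 Å).

## Interaction detection

Three geometric detectors with the customary interaction-fingerprint
cutoffs, all configurable, no angular criteria by default (the H-bond angle
filter is optional): hydrogen bonds = donor/acceptor heavy-atom pairs within
3.5 Å; hydrophobic contacts = apolar heavy-atom pairs within 4.5 Å,
aggregated to one contact per (ligand atom, residue) at minimum distance;
cation–π = cationic center to aromatic-ring centroid within 6.0 Å, both
directions (receptor Lys/Arg vs ligand rings; formally charged ligand
nitrogens vs Phe/Tyr/Trp/His rings, receptor rings located from residue
templates).  Backbone vs side-chain classification comes from PDB atom names
(N, CA, C, O, OXT).  Contacts carry labels of the form "backbone oxygen of
Leu83".

## Synthetic test bed

Real crystal structures cannot provide a *known* scoring minimum at
unit-test scale, so the generator builds cases where the ground truth is
known by construction:

- **Ligands** are zigzag heavy-atom chains (tetrahedral-like angles, 1.5 Å
  bonds) with a chosen number of rotatable bonds spread along the chain,
  polar substitutions (donor/acceptor alternation) at the head end to break
  end-to-end symmetry, and optionally an aromatic six-ring at the tail.
- **Pockets** for redocking are cages built *around* an embedded ligand
  conformation: several receptor atoms per ligand heavy atom at near-ideal
  contact distance (surface gap +0.2 Å for hydrophobic contacts), plus two
  hydrogen-bond anchor atoms per polar ligand atom at gap −0.5 Å (inside the
  hbond ramp).  Anchors make the embedded alignment uniquely favorable.
- **Verification**: each case is accepted only if the embedded pose (a)
  outscores 100 random poses and (b) survives a short multi-start search —
  no conformationally distinct minimum (RMSD ≥ 2 Å) may score below the
  refined embedded pose.  Failed constructions are rebuilt from a perturbed
  seed, with the attempt count recorded in the manifest.
- The standard redocking study (`study_specs`) holds 20 cases spanning the
  envelope the fixtures emulate: torsion counts cycling 0–3 and heavy-atom
  counts cycling 8–12, i.e. rigid through fully flexible small ligands.

Everything is byte-reproducible from the seed, and all emitted files pass
the package's own parsers.

What passing these tests shows: the kinematics, scoring, grids, search,
aggregation and bookkeeping are internally correct and the search reliably
finds a verified global minimum in a small, well-formed funnel.  What it
does not show: performance on real pockets — fixtures have no real
chemistry, no solvent, no receptor flexibility, far fewer atoms than a
protein, and a cage literally molded to one conformation.  Published-scale
benchmarks (redocking across dozens of crystal complexes, screens of
thousands of catalog compounds) require downloading those structures and
libraries and are out of desk scope.

## Problem sizes and defaults used in studies

The package defaults mirror the production configuration (256 tasks, nine
poses, 0.08 Å grids, +10 Å box).  The synthetic studies and test suite use
scaled-down settings chosen as this package's own study conditions: 64
tasks, 0.25–0.5 Å grids, 8–12 heavy-atom ligands with 0–3 torsions, and
two-structure ensembles for screening checks.

## Known limitations

- No electrostatics or desolvation terms; no charges in scoring.
- No receptor flexibility, protonation prediction or structure repair.
- Fixed-order RMSD inflates values for symmetric ligands.
- The Monte-Carlo schedule (hop sizes, kT, pattern-search steps) is this
  package's own; only the task count and pose cap are production contracts.
- Python/numpy throughput limits exhaustiveness; very flexible ligands
  (> ~6 torsions) would need larger budgets than the defaults.
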