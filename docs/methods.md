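# Methods

This note documents the models, parameters and design choices behind
`pepdock`, in the spirit of a methods section: what is computed, under what
assumptions, and what the synthetic benchmark does and does not show.

## Canonical conformers

Peptide conformers are built N→C by natural-extension-reference-frame
(NeRF) placement with Engh–Huber-style backbone geometry: bonds
N–CA 1.458, CA–C 1.525, C–N 1.329, C–O 1.231, CA–CB 1.530 Å; angles
N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°, CA–C–O 120.8°. The three
shipped dihedral templates are extended (φ, ψ) = (−139°, −135°), α-helix
(−57°, −47°) and polyproline II (−78°, 149°), all with trans peptide bonds
(ω = 180°). The builder is exact: measured interior dihedrals reproduce the
template to < 1e-4°, and rebuilding a conformer from its own measured
dihedrals superposes to < 1e-6 Å.

Cβ is placed with bond 1.53 Å, angle N–CA–CB 109.5° and torsion
(C, N, CA, CB) = +120°, frozen from ideal L-alanine coordinates; the
positive sign of that improper is the L-chirality check used in the tests.
Side chains beyond Cβ are *not* built: the rigid-body stage cannot exploit
rotamers, and the reduced representation keeps the energy model small. This
is a documented divergence from all-atom peptide building. Carbonyl O is
placed anti to the next amide nitrogen; the C-terminal O uses the template
ψ as its virtual reference. Proline φ is set like any other residue (no
ring closure), a known approximation that matters most for PPII templates.
Charged-termini flags add ±1 formal charges on the terminal N/C in the
electrostatics term only; no extra atoms are built.

With this geometry an ideal extended 10-mer has a per-residue Cα extension
(end-to-end distance over n − 1) of 3.435 Å, consistent with the canonical
3.46 Å figure for ideal extended chains within the tolerance expected from
unspecified builder geometry (±0.15 Å in the tests). PPII measures
≈ 3.1 Å/residue, the helix ≈ 1.6 Å/residue. The extension definition uses
the *end-to-end* distance, not the mean consecutive Cα–Cα distance: the
latter is ≈ 3.8 Å in any conformation and cannot discriminate.

## Classification

A residue is helical when (φ, ψ) ∈ [−100, −30] × [−80, −5] degrees and it
belongs to a run of ≥ 4 consecutive such residues; terminal residues
lacking φ or ψ are never helical. This dihedral-window rule replaces an
external secondary-structure program, which is unreliable on very short
chains; an optional hook accepts user-provided per-residue assignments
(H/G/I count as helical). A peptide is a *helix* when more than half its
residues are helical (tested first), otherwise *extended* when its
per-residue extension reaches 2.8 Å (= 0.8 × 3.46, as conventionally
printed; we use ≥, a measure-zero choice), otherwise *disordered*. At
length 10 the PPII build (≈ 3.1 Å/residue) classifies as extended.

Docking difficulty is the backbone RMSD between the bound peptide and its
ideal extended build after Kabsch superposition: easy ≤ 4 Å < medium
≤ 8 Å < difficult, upper bounds inclusive. Receptor flexibility is
quantified separately as the backbone RMSD of the bound-defined interface
(receptor residues within 10 Å of the peptide) between bound and unbound
forms; values above 2.0 Å flag a large binding-induced rearrangement.

## Restraints and the composite score

Active residues are receptor residues with any heavy atom within 5 Å of
the peptide in the reference complex; every peptide residue is passive.
This is a deliberately broad site definition — on the groove fixture the
active surface exceeds half the buried area by construction, mirroring the
broad-versus-true-interface relationship the protocol assumes. Each active
residue i contributes an ambiguous effective distance pooled over all of
its heavy-atom pairs with the peptide, d_eff(i) = (Σ d⁻⁶)^(−1/6),
penalised as k·max(0, d_eff − d₀)² with HADDOCK-convention defaults
k = 50 energy/Å² and d₀ = 2.0 Å (both unstated in the source protocol and
therefore exposed in `ScoringConfig`). Passive residues contribute no
restraint of their own. Random restraint removal is not implemented.

The pose score is the weighted sum

    total = 0.01·E_rest + 0.01·E_vdw + 1.0·E_elec + 1.0·E_desol − 0.01·BSA

with the weights frozen in one place (`pepdock.scoring.WEIGHTS`). The
component *forms* are simplified stand-ins parameterised by small editable
tables: 12-6 Lennard-Jones over intermolecular heavy-atom pairs
(per-element σ/ε, 8.5 Å truncated-shifted cutoff, and a soft core capping
distances at 0.6σ so clashes stay finite during minimisation); Coulomb
electrostatics with relative dielectric 10, backbone amide partial charges
(±0.25 on N/O) and formal side-chain charges on Cβ for Asp/Glu/Lys/Arg;
empirical desolvation as per-atom solvation parameter × SASA change upon
complexation (apolar burial favourable, polar penalised); and BSA =
SASA(A) + SASA(B) − SASA(AB). A full nonbonded force field is out of
scope; the score *weights*, not the component parameterisations, are the
method's defining constants.

## Solvent accessibility

SASA is an internal Shrake–Rupley implementation: deterministic Fibonacci
dot spheres, probe 1.4 Å, 960 dots/atom for analysis, element-based radii
C 1.70, N 1.55, O 1.52, S 1.80 Å; hydrogens are ignored throughout.
Relative accessibility divides a residue's side-chain and backbone SASA by
reference maxima computed once from an extended Gly-X-Gly tripeptide built
by the conformer module — self-consistent with this SASA implementation
rather than imported from an external table. A residue is "surface" when
either ratio exceeds 0.40 (strict).

Inside the docking loop the buried-surface terms are computed
incrementally: per-atom free areas and intramolecular occluder lists are
cached, the peptide's dot sphere co-rotates with the pose, and only atoms
within occlusion reach of the partner are re-evaluated (60 dots/atom by
default in the score, configurable). This makes the incremental BSA
*exactly* zero for separated molecules and non-negative for any pose,
while evaluating in ~2–6 ms.

## Sampling and minimisation

Each ensemble conformer is sampled the same number of times. A pose starts
at a uniformly random orientation with its centroid placed at receptor
radius + peptide radius + 3 Å along a random direction; the 180°-rotated
twin (about an axis perpendicular to the approach direction) is minimised
in parallel and the better start kept. Minimisation is rigid-body (6 DOF:
rotation vector + translation) Powell search in two stages: first on the
SASA-free surrogate (restraint + vdW + electrostatic terms, budget 120
evaluations per start), then on the full score (budget 40). If the search
fails to improve the full score relative to the start, the starting
placement is kept and the pose flagged unminimised — the returned score
never exceeds the start's. Randomness is counter-based
(`SeedSequence([seed, conformer, pose])`), so pose i is bit-reproducible
regardless of how many poses are requested.

Defaults mirror the protocol scale (2000 poses per conformer, top 400);
the tests and the acceptance script run the documented desk-scale setting
of 50 poses per conformer with top-30 selection, which this package treats
as its standard benchmark configuration. The source protocol's
five-trials-plus-flip inner loop is approximated by best-of-two starts
plus the minimiser budget — a recorded divergence.

## Assessment

All metrics pair atoms by (chain, residue number, insertion code, atom
name) with backbone = {N, CA, C, O}; carbonyl O is included in "backbone"
(a choice the quality classes are mildly sensitive to, flagged for
sensitivity testing). Interfaces are always defined on the reference
complex at 10 Å and reused for every model of a case. i-RMSD fits on the
pooled two-sided interface backbone (CAPRI convention) and measures on the
same atoms; l-RMSD fits on the full receptor backbone and measures the
peptide backbone with no second fit; l-i-RMSD fits on the receptor
interface and measures the peptide interface. Fnat uses residue–residue
contacts at a 5 Å heavy-atom cutoff (CAPRI convention; the threshold is a
parameter). Quality classes are peptide-adapted: high ≤ 1 Å < near-native
≤ 2 Å < not acceptable, boundaries inclusive.

## Clustering and ranking

Models are clustered on pairwise interface-ligand RMSD (peptide backbone
after fitting each pair on the receptor-interface backbone) with
Daura-style neighbour counting at a 5.0 Å cutoff — tighter than the
protein–protein convention because peptide interfaces are small. The
minimum cluster size of 4 is forced by the cluster score, the mean of the
four best member scores; ranking is ascending with ties broken by the
representative's id, and the algorithm is deterministic under input
permutation. A cluster is near-native when one of its four *best-scored*
members is near-native or better — a fifth-best near-native model does not
count.

## Synthetic benchmark: what it shows and what it does not

The fixture receptors are poly-alanine lattice slabs (5 Å spacing, two
base layers, small seeded jitter) with either a closed groove sized to a
chosen conformer or a flat convex patch; poly-Ala sidesteps side-chain
parameterisation in the simplified energies and is the documented test
regime. Groove-lining residues point their Cβ away from the slot so the
slot width is a controlled parameter; everything else is randomly oriented
per seed. Fixtures are deterministic to the PDB text. Decoys are random
rigid peptide perturbations whose magnitude is bisected against the
package's own i-RMSD until it lands mid-stratum (0.5 / 1.5 / 4.0 Å
targets), giving labelled ground truth whose labels must agree with the
assessment module — the central cross-module consistency test.

On these fixtures the pipeline at desk scale (50 poses per conformer, top
30) produces near-native models in essentially every seed, enriches
extended-origin poses (EF ≈ 1.4) on the extended groove and helix-origin
poses (EF ≈ 1.9, ~60% of the selection) on the helix groove. One geometric
caveat found during fixture design: a slot that admits the extended
conformer cannot sterically exclude polyproline II, whose lateral profile
is *narrower* than the extended strand's; only the helix can be excluded
by width. Extended-vs-PPII discrimination therefore rests on the score
(burial and restraint satisfaction of the snug reference-shaped slot), not
on sterics, and PPII remains competitive — consistent with PPII's known
role as a frequent bound conformation. Passing these tests shows the
machinery is correct and the selection logic directionally right; it does
not demonstrate performance on real, chemically heterogeneous complexes,
which would require benchmark structures and the flexible-refinement
stages that are out of scope here (the rigid stage stops where
semi-flexible and solvated refinement would begin).

## Numerical choices and degenerate inputs

Kabsch superposition uses SVD with a determinant correction (always a
proper rotation) and rejects < 3 points or nearly collinear sets; dihedral
measurement raises on coincident/collinear points and returns angles in
(−180, 180] with the IUPAC sign convention. Altloc resolution keeps the
highest occupancy (ties: first in file); waters are dropped; multi-model
files read MODEL 1 unless the ensemble reader is used. Score ties in
top-N selection and cluster ranking break by lower model id, making every
pipeline stage deterministic given a seed.
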