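# pepdock

Ensemble rigid-body protein–peptide docking with conformational selection,
peptide-adapted CAPRI assessment and cluster-based ranking.

## The problem

Peptides mediate a large share of protein interactions, but docking them is
hard: a free peptide has no single structure, and the bound conformation —
extended/β, α-helical, or polyproline II in the great majority of complexes —
is generally unknown in advance. A practical way around full flexible
folding is *conformational selection at the docking stage*: dock a small
canonical ensemble of ideal conformers simultaneously, represent each
equally in the sampling, and let the scoring function pick the conformation
that fits the binding site.

`pepdock` is a desk-scale toolkit implementing that protocol's rigid-body
core for structural bioinformaticians:

* **conformers** — build ideal peptide conformers from sequence by
  internal-coordinate chain extension with exact template dihedrals:
  extended (φ, ψ) = (−139°, −135°), α-helix (−57°, −47°), polyproline II
  (−78°, 149°), all ω = 180°; plus ±10° flat-bottom dihedral restraints to
  preserve helices in downstream refinement.
* **classify** — peptide conformational classes (helix / extended /
  disordered; extended means a per-residue Cα extension ≥ 2.8 Å = 0.8 × 3.46 Å)
  and docking difficulty (easy / medium / difficult at bound-vs-extended
  backbone RMSD ≤ 4 / ≤ 8 / > 8 Å).
* **scoring** — ambiguous interaction restraints (AIRs) from a broad
  binding-site definition (receptor residues within 5 Å of the peptide are
  *active*, peptide residues *passive*, pooled effective distances
  d_eff = (Σ d⁻⁶)^(−1/6)), and the rigid-body composite score

  ```
  score = 0.01·E_rest + 0.01·E_vdw + 1.0·E_elec + 1.0·E_desol − 0.01·BSA
  ```

* **docking** — ensemble rigid-body sampling (equal poses per conformer,
  random placement plus the 180°-flipped start, two-stage derivative-free
  minimisation), top-N selection, and enrichment factors
  EF(c) = selected fraction × 3 quantifying conformational selection.
* **assess** — peptide-adapted CAPRI metrics against a reference complex:
  i-RMSD (pooled 10 Å interface backbone), l-RMSD, l-i-RMSD, Fnat; quality
  classes high (i-RMSD ≤ 1 Å), near-native (≤ 2 Å), not acceptable.
* **clustering** — Daura-style neighbour-counting clustering at a 5.0 Å
  interface-ligand RMSD cutoff; clusters scored by the mean of their four
  best members and judged near-native by those same four.
* **fixtures** — deterministic synthetic receptors (lattice slabs with
  grooves sized to a chosen conformer) and i-RMSD-calibrated decoy sets, so
  the whole pipeline runs and is tested without any downloads.

## Worked example

`examples/03_dock_with_conformational_selection.py` docks the canonical
three-conformer ensemble of an 8-mer into a receptor whose groove is sized
for a helix, then reports what the score selected:

```
8 active receptor residues within 5 A of the peptide drive the docking; ...

conformer  selected  fraction  enrichment factor
extended          0      0.00      0.00
helix             9      0.75      2.25
ppii              3      0.25      0.75
```

Each conformer contributed 20 of the 60 sampled poses, so a fraction of
0.75 for helix-origin poses among the top 12 means an enrichment factor of
2.25: scoring recovered the bound conformation from the ensemble without
being told which it was. The other examples build ensembles
(`01`), classify bound peptides (`02`), and assess/cluster decoys with the
CAPRI-style metrics (`04`). A thin CLI (`pepdock ensemble|classify|dock|
assess|cluster|fixtures`) wraps the same calls for shell use.

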