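"""Build the canonical three-conformer ensemble for a peptide sequence.

Bound peptides mostly adopt one of three backbone conformations; docking
starts from all three and lets scoring pick the right one. This script
builds them for a 9-mer, prints their per-residue extension, and writes a
3-model PDB ensemble.
"""

from pepdock import canonical_ensemble, write_pdb
from pepdock.conformers import measure_backbone_dihedrals, per_residue_extension

SEQUENCE = "KLAAALEHH"

ensemble = canonical_ensemble(SEQUENCE)
write_pdb([c.structure for c in ensemble], "ensemble.pdb")

print(f"sequence: {SEQUENCE}\n")
print("conformer  phi (deg)  psi (deg)  extension (A/residue)")
for conformer in ensemble:
    dihedrals = measure_backbone_dihedrals(conformer.structure)
    phi = next(p for p, _ in dihedrals if p is not None)
    psi = next(p for _, p in dihedrals if p is not None)
    ext = per_residue_extension(conformer.structure)
    print(f"{conformer.conformer_id:9s}  {phi:9.1f}  {psi:9.1f}  {ext:8.2f}")

print(
    "\nThe extension column is the end-to-end CA distance per residue: the\n"
    "ideal extended chain reaches ~3.46 A/residue, polyproline II ~3.1 and\n"
    "the alpha-helix ~1.6; 80% of the extended value (2.8 A) is the cut\n"
    "used to call a bound peptide 'extended'. Wrote ensemble.pdb (3 models)."
)
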