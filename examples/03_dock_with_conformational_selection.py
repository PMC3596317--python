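"""Ensemble rigid-body docking with conformational-selection accounting.

Builds a receptor with a helix-sized groove, docks the three-conformer
ensemble into it under ambiguous interaction restraints, and reports which
starting conformation the composite score selects into the top of the
ranking (the enrichment factor EF = selected fraction x 3; EF > 1 means
the conformer is over-represented relative to its 1/3 prior share).

Takes a couple of minutes on one CPU.
"""

from pepdock import (
    FixtureSpec,
    canonical_ensemble,
    define_airs,
    make_complex,
    sample_poses,
    select_top,
    selection_stats,
)

reference, receptor, sequence = make_complex(
    FixtureSpec(sequence="AAAAAAAA", template="helix",
                groove_width=10.0, seed=1))
airs = define_airs(reference, "A", "B", cutoff=5.0)
print(f"{len(airs.active)} active receptor residues within 5 A of the "
      f"peptide drive the docking; all {len(airs.passive)} peptide "
      f"residues are passive.\n")

ensemble = canonical_ensemble(sequence, chain_id="B")
poses = sample_poses(receptor, ensemble, airs, n_per_conformer=20, seed=42)
top = select_top(poses, 12)
stats = selection_stats(top)

print("conformer  selected  fraction  enrichment factor")
for cid in ("extended", "helix", "ppii"):
    print(f"{cid:9s}  {stats.counts[cid]:8d}  {stats.fractions[cid]:8.2f}"
          f"  {stats.enrichment[cid]:8.2f}")
print(
    "\nThe peptide is bound helically in the reference, and the score\n"
    "selects helix-origin poses well above their 1/3 prior share: the\n"
    "rigid-body stage recovers the relevant conformation before any\n"
    "flexible refinement would run."
)
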