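"""Assess docked models against the reference and rank them by cluster.

Generates labelled decoys around a reference complex, computes the
peptide-adapted CAPRI metrics (i-RMSD, l-RMSD, l-i-RMSD, Fnat) for each,
clusters them on interface-ligand RMSD and ranks clusters by the mean of
their four best member scores.
"""

from pepdock import (
    FixtureSpec,
    assess_model,
    cluster_models,
    interface_selection,
    make_complex,
    make_decoy_set,
    pairwise_matrix,
    rank_clusters,
)
from pepdock.structmodel import chain_selection

reference, _, _ = make_complex(FixtureSpec(sequence="AAAAAAAA", seed=1))
interfaces = interface_selection(reference, "A", "B", cutoff=10.0)

decoys = make_decoy_set(
    reference, {"high": 4, "near_native": 4, "not_acceptable": 4}, seed=7)

print("model  i-RMSD  l-RMSD  l-i-RMSD   Fnat  quality")
reports = {}
for i, (model, label, _) in enumerate(decoys):
    rep = assess_model(model, reference, "A", "B", interfaces, model_id=i)
    reports[i] = rep
    print(f"{i:5d}  {rep.i_rmsd:6.2f}  {rep.l_rmsd:6.2f}  {rep.l_i_rmsd:8.2f}"
          f"  {rep.fnat:5.2f}  {rep.quality}")

models = [m for m, _, _ in decoys]
matrix = pairwise_matrix(models, interfaces[0],
                         chain_selection(reference, "B"))
# stand-in scores: better (lower) for geometrically better models
scores = {i: reports[i].i_rmsd + 0.1 * i for i in reports}
raw, unclustered = cluster_models(matrix, cutoff=5.0, min_size=4)
ranked = rank_clusters(raw, scores)

print(f"\n{len(ranked)} cluster(s), {len(unclustered)} unclustered model(s)")
for k, cluster in enumerate(ranked, 1):
    qualities = [reports[m].quality for m in cluster.members[:4]]
    print(f"  rank {k}: members {cluster.members} "
          f"score {cluster.cluster_score:.2f} top-4 qualities {qualities}")

print(
    "\nQuality classes follow the peptide-adapted cuts: i-RMSD <= 1 A is\n"
    "high (sub-angstrom), <= 2 A near-native, above that not acceptable.\n"
    "A cluster counts as near-native when one of its four best-scored\n"
    "members is near-native or better."
)
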