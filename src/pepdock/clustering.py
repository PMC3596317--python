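"""RMSD clustering of docked models and cluster-based ranking.

Single-model scores of docked poses are noisy (the electrostatic term in
particular); averaging over structurally coherent groups is considerably
more robust. Models are clustered on a pairwise interface-ligand RMSD
matrix (peptide backbone RMSD after fitting each pair on the
receptor-interface backbone) with a 5.0 Å cutoff — tighter than the
protein-protein convention because peptide interfaces are small — using
Daura-style neighbour counting. Each cluster is scored by the mean of its
four best member scores, which also forces the minimum cluster size of 4,
and clusters are ranked by that score. A cluster counts as near-native
when one of its four best-scored members is of near-native quality or
better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assess import ACCEPTABLE_QUALITIES, QualityReport
from .structmodel import (
    PairingError,
    PepdockError,
    Selection,
    Structure,
    apply_transform,
    kabsch_superpose,
    rmsd_no_fit,
)
from .assess import _paired_coords

__all__ = [
    "Cluster",
    "pairwise_matrix",
    "cluster_models",
    "rank_clusters",
    "cluster_success",
]


@dataclass
class Cluster:
    """Member model ids ordered by score (best first), the top-4 mean
    cluster score, and the best-scored member as representative."""

    members: list[int]
    cluster_score: float
    representative: int


def pairwise_matrix(models: list[Structure],
                    receptor_interface: Selection,
                    peptide_selection: Selection) -> np.ndarray:
    """Symmetric matrix of pairwise interface-ligand RMSDs (Å).

    Entry (i, j) fits model j onto model i on the receptor-interface
    backbone, then measures the peptide backbone RMSD.
    """
    if len(models) < 2:
        raise PepdockError("need at least 2 models for a pairwise matrix")
    n = len(models)
    rec, pep = [], []
    for m in models:
        rm, _ = _paired_coords(m, models[0], receptor_interface)
        pm, _ = _paired_coords(m, models[0], peptide_selection)
        rec.append(rm)
        pep.append(pm)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rot, trans, _ = kabsch_superpose(rec[j], rec[i])
            d = rmsd_no_fit(apply_transform(pep[j], rot, trans), pep[i])
            mat[i, j] = mat[j, i] = d
    return mat


def cluster_models(matrix: np.ndarray, cutoff: float = 5.0,
                   min_size: int = 4,
                   model_ids: list[int] | None = None
                   ) -> tuple[list[list[int]], list[int]]:
    """Daura-style neighbour-counting clustering of a distance matrix.

    Repeatedly seeds a cluster at the unassigned model with the most
    unassigned neighbours within ``cutoff`` (ties: lower model id), removes
    it with its neighbours, and stops when the best remaining cluster would
    fall below ``min_size``. Returns raw member-id lists plus the
    unclustered ids; the partition is deterministic.
    """
    matrix = np.asarray(matrix, float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T, atol=1e-8):
        raise PepdockError("pairwise matrix must be square and symmetric")
    ids = list(range(n)) if model_ids is None else list(model_ids)
    remaining = sorted(range(n), key=lambda i: ids[i])
    clusters: list[list[int]] = []
    while remaining:
        best_seed, best_members = None, None
        for i in remaining:
            members = [j for j in remaining if matrix[i, j] <= cutoff]
            if best_members is None or len(members) > len(best_members):
                best_seed, best_members = i, members
        if len(best_members) < min_size:
            break
        clusters.append(sorted((ids[j] for j in best_members)))
        taken = set(best_members)
        remaining = [j for j in remaining if j not in taken]
    unclustered = sorted(ids[j] for j in remaining)
    return clusters, unclustered


def rank_clusters(raw_clusters: list[list[int]],
                  model_scores: dict[int, float]) -> list[Cluster]:
    """Score clusters by the mean of their four best member scores and sort
    ascending (ties: lower representative id)."""
    out = []
    for members in raw_clusters:
        missing = [m for m in members if m not in model_scores]
        if missing:
            raise PairingError(f"no score for models {missing}")
        ordered = sorted(members, key=lambda m: (model_scores[m], m))
        top4 = [model_scores[m] for m in ordered[:4]]
        out.append(Cluster(members=ordered,
                           cluster_score=float(np.mean(top4)),
                           representative=ordered[0]))
    out.sort(key=lambda c: (c.cluster_score, c.representative))
    return out


def cluster_success(ranked_clusters: list[Cluster],
                    reports: dict[int, QualityReport],
                    top_k: int) -> bool:
    """True iff one of the top ``top_k`` clusters has an acceptable model
    (near-native or better) among its four best-scored members."""
    for cluster in ranked_clusters[:top_k]:
        for model_id in cluster.members[:4]:
            report = reports.get(model_id)
            if report is not None and report.quality in ACCEPTABLE_QUALITIES:
                return True
    return False
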