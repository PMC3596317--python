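"""Ensemble rigid-body docking with conformational-selection accounting.

Each member of the canonical peptide ensemble (extended / helix / PPII) is
sampled the same number of times: a random orientation is placed on a
sphere around the receptor, its 180°-flipped twin is evaluated too, and the
better start is minimised rigidly (six degrees of freedom) against the
composite score. Because every conformer is represented equally in the
pool, the score alone decides which conformation survives the top-N
selection — the enrichment factor of a conformer, EF(c) = fraction(c) × k
for a k-member ensemble, measures how strongly scoring selects it.

Minimisation is a two-stage derivative-free local search (Powell): first on
the SASA-free surrogate (restraint + van der Waals + electrostatic terms),
then on the full composite score. A pose never ends worse than its start:
if the search fails to improve the total, the starting placement is kept
and the pose flagged unminimised.

Randomness is counter-based: pose (conformer c, index i) draws from a
dedicated substream seeded by ``(seed, c, i)``, so any single pose is
reproducible regardless of how many are generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .conformers import PeptideConformer
from .scoring import (
    AirRestraintSet,
    PoseScorer,
    ScoreComponents,
    ScoringConfig,
    DEFAULT_CONFIG,
)
from .structmodel import PepdockError, Structure

__all__ = [
    "DockPose",
    "SelectionStats",
    "sample_poses",
    "select_top",
    "selection_stats",
    "poses_to_structures",
    "write_pose_table",
]


@dataclass
class DockPose:
    """One rigid-body placement of a conformer on the receptor."""

    receptor: Structure
    conformer: PeptideConformer
    rotation: np.ndarray
    translation: np.ndarray
    score: ScoreComponents
    model_id: int
    seed: int
    minimized: bool = True

    @property
    def conformer_id(self) -> str:
        return self.conformer.conformer_id

    def peptide_structure(self) -> Structure:
        return self.conformer.structure.transformed(self.rotation,
                                                    self.translation)

    def complex_structure(self) -> Structure:
        return self.receptor.merged_with(self.peptide_structure())


@dataclass(frozen=True)
class SelectionStats:
    """Per-conformer accounting of a top-N selection."""

    counts: dict
    fractions: dict
    enrichment: dict

    @property
    def n_selected(self) -> int:
        return sum(self.counts.values())


def _radius(coords: np.ndarray) -> float:
    centroid = coords.mean(axis=0)
    return float(np.linalg.norm(coords - centroid, axis=1).max())


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def _perpendicular(v: np.ndarray) -> np.ndarray:
    basis = np.eye(3)[np.argmin(np.abs(v))]
    p = np.cross(v, basis)
    return p / np.linalg.norm(p)


def sample_poses(receptor: Structure, ensemble: list[PeptideConformer],
                 airs: AirRestraintSet, n_per_conformer: int, seed: int,
                 config: ScoringConfig = DEFAULT_CONFIG,
                 stage_a_budget: int = 120, stage_b_budget: int = 40
                 ) -> list[DockPose]:
    """Generate ``n_per_conformer`` minimised rigid-body poses per ensemble
    member (equal representation before selection).

    ``stage_a_budget`` / ``stage_b_budget`` cap the number of score
    evaluations of the surrogate and full-score stages of the per-pose
    minimisation.
    """
    if n_per_conformer < 1:
        raise PepdockError("n_per_conformer must be >= 1")
    rec_coords = receptor.heavy_coords()
    rec_centroid = rec_coords.mean(axis=0)
    rec_radius = _radius(rec_coords)
    poses: list[DockPose] = []
    model_id = 0
    for ci, conformer in enumerate(ensemble):
        scorer = PoseScorer(receptor, conformer.structure, airs, config,
                            (conformer.charged_nter, conformer.charged_cter))
        local = scorer.pep.coords
        pep_centroid = local.mean(axis=0)
        centered = local - pep_centroid
        pep_radius = _radius(local)
        place_dist = rec_radius + pep_radius + 3.0

        def world(rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
            return centered @ rotation.T + translation

        for pi in range(n_per_conformer):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), ci, pi]))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            t0 = rec_centroid + place_dist * direction
            r0 = _random_rotation(rng)
            flip = Rotation.from_rotvec(
                np.pi * _perpendicular(direction)).as_matrix()
            starts = [r0, flip @ r0]

            def cheap_objective(x, base_r):
                rot = Rotation.from_rotvec(x[:3]).as_matrix() @ base_r
                return scorer.cheap_score(world(rot, t0 + x[3:]))

            def full_objective(x, base_r):
                rot = Rotation.from_rotvec(x[:3]).as_matrix() @ base_r
                return scorer.total(world(rot, t0 + x[3:]), rot)

            best = None
            for base_r in starts:
                res = minimize(cheap_objective, np.zeros(6), args=(base_r,),
                               method="Powell",
                               options={"maxfev": stage_a_budget,
                                        "xtol": 1e-2, "ftol": 1e-3})
                if best is None or res.fun < best[0]:
                    best = (res.fun, res.x, base_r)
            _, x_a, base_r = best
            start_total = full_objective(np.zeros(6), base_r)
            res = minimize(full_objective, x_a, args=(base_r,),
                           method="Powell",
                           options={"maxfev": stage_b_budget,
                                    "xtol": 1e-2, "ftol": 1e-3})
            x_final, minimized = res.x, True
            final_total = full_objective(x_final, base_r)
            if not np.isfinite(final_total) or final_total > start_total:
                x_final, minimized = np.zeros(6), False
            rot = Rotation.from_rotvec(x_final[:3]).as_matrix() @ base_r
            trans = (t0 + x_final[3:]) - rot @ pep_centroid
            components = scorer.components(world(rot, t0 + x_final[3:]), rot)
            poses.append(DockPose(receptor, conformer, rot, trans,
                                  components, model_id, int(seed), minimized))
            model_id += 1
    return poses


def select_top(poses: list[DockPose], n: int) -> list[DockPose]:
    """The ``n`` best poses by total score (ascending; ties broken by lower
    model id)."""
    if n > len(poses):
        raise PepdockError(f"cannot select top {n} from {len(poses)} poses")
    ranked = sorted(poses, key=lambda p: (p.score.total, p.model_id))
    return ranked[:n]


def selection_stats(top_poses: list[DockPose],
                    conformer_ids: tuple[str, ...] = ("extended", "helix", "ppii")
                    ) -> SelectionStats:
    """Counts, fractions and enrichment factors per starting conformer among
    a selection; EF(c) = fraction(c) × k for k conformers."""
    k = len(conformer_ids)
    counts = {cid: 0 for cid in conformer_ids}
    for pose in top_poses:
        if pose.conformer_id not in counts:
            raise PepdockError(f"unexpected conformer id {pose.conformer_id!r}")
        counts[pose.conformer_id] += 1
    n = len(top_poses)
    fractions = {cid: (counts[cid] / n if n else 0.0) for cid in conformer_ids}
    enrichment = {cid: fractions[cid] * k for cid in conformer_ids}
    return SelectionStats(counts, fractions, enrichment)


def poses_to_structures(poses: list[DockPose]) -> list[Structure]:
    """Full complex structures (receptor + placed peptide) per pose."""
    return [p.complex_structure() for p in poses]


def write_pose_table(poses: list[DockPose], path: str | Path) -> None:
    """TSV sidecar with per-pose provenance and score components."""
    import pandas as pd

    rows = [{
        "model_id": p.model_id,
        "conformer": p.conformer_id,
        "seed": p.seed,
        "minimized": p.minimized,
        "e_rest": p.score.e_rest,
        "e_vdw": p.score.e_vdw,
        "e_elec": p.score.e_elec,
        "e_desol": p.score.e_desol,
        "bsa": p.score.bsa,
        "total": p.score.total,
    } for p in poses]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
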