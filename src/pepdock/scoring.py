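"""Ambiguous interaction restraints and the rigid-body composite score.

The docking stage is driven by ambiguous interaction restraints (AIRs): a
broad binding-site definition in which every receptor residue within 5 Å of
the peptide in the reference complex is *active* (enforced to be at the
interface) and every peptide residue is *passive* (allowed to be). Each
active residue contributes one effective distance pooled over all of its
heavy-atom pairs with the peptide,

    d_eff(i) = ( sum_pairs d^-6 )^(-1/6),

penalised harmonically above an upper bound.

Poses are ranked by the rigid-body composite score

    total = 0.01 E_rest + 0.01 E_vdw + 1.0 E_elec + 1.0 E_desol − 0.01 BSA

whose weights are frozen here in one place (``WEIGHTS``) and are not meant
to be tuned. The component energy forms (12-6 Lennard-Jones, Coulomb with a
distance-independent relative dielectric, SASA-based desolvation) are
deliberately simple, parameterised by small editable tables in
:class:`ScoringConfig`; the *weights* of the composite are the method's
defining constants, the component parameterisation is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structmodel import (
    PepdockError,
    Selection,
    Structure,
    chain_selection,
    residues_within,
    sasa_of_atoms,
)

__all__ = [
    "WEIGHTS",
    "ScoreComponents",
    "AirRestraintSet",
    "ScoringConfig",
    "NoInterfaceError",
    "define_airs",
    "air_energy",
    "vdw_energy",
    "elec_energy",
    "desolvation_energy",
    "buried_surface_area",
    "rigid_score",
    "PoseScorer",
    "write_airs_table",
    "write_airs_cns",
]

#: Composite-score weights (rigid-body stage). Frozen; change at your peril.
WEIGHTS = {"e_rest": 0.01, "e_vdw": 0.01, "e_elec": 1.0, "e_desol": 1.0,
           "bsa": -0.01}

COULOMB_CONSTANT = 332.0637  # kcal Å / (mol e²)


class NoInterfaceError(PepdockError):
    """Raised when no receptor residue lies within the AIR cutoff."""


@dataclass(frozen=True)
class ScoreComponents:
    e_rest: float
    e_vdw: float
    e_elec: float
    e_desol: float
    bsa: float

    @property
    def total(self) -> float:
        return (WEIGHTS["e_rest"] * self.e_rest
                + WEIGHTS["e_vdw"] * self.e_vdw
                + WEIGHTS["e_elec"] * self.e_elec
                + WEIGHTS["e_desol"] * self.e_desol
                + WEIGHTS["bsa"] * self.bsa)


@dataclass(frozen=True)
class AirRestraintSet:
    """Active/passive residue selections plus the effective-distance
    restraint parameters. Random restraint removal is not implemented:
    every active residue is always enforced."""

    active: Selection
    passive: Selection
    upper_bound: float = 2.0
    force_constant: float = 50.0

    def __post_init__(self) -> None:
        if len(self.active) == 0:
            raise NoInterfaceError("AIR set has no active residues")


@dataclass(frozen=True)
class ScoringConfig:
    """Editable parameter tables for the component energies.

    Energies are on a kcal/mol-like scale; distances in Å; areas in Å².
    """

    lj_sigma: dict = field(default_factory=lambda: {
        "C": 3.40, "N": 3.25, "O": 3.00, "S": 3.60})
    lj_epsilon: dict = field(default_factory=lambda: {
        "C": 0.10, "N": 0.17, "O": 0.21, "S": 0.25})
    #: atomic solvation parameters (kcal/mol/Å²): apolar burial favourable,
    #: polar burial penalised
    solvation: dict = field(default_factory=lambda: {
        "C": 0.0151, "S": 0.0129, "N": -0.0060, "O": -0.0060})
    #: formal side-chain charges, placed on CB of the reduced representation
    residue_charges: dict = field(default_factory=lambda: {
        "ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0})
    #: backbone amide partial charges (stand-in dipole)
    backbone_charge_n: float = 0.25
    backbone_charge_o: float = -0.25
    dielectric: float = 10.0
    nonbonded_cutoff: float = 8.5
    air_upper_bound: float = 2.0
    air_force_constant: float = 50.0
    probe: float = 1.4
    #: dots per atom for the SASA terms inside the score (coarser than the
    #: 960-dot analysis default, for speed in the docking inner loop)
    sasa_points: int = 60

    def to_file(self, path: str | Path) -> None:
        lines = []
        for table in ("lj_sigma", "lj_epsilon", "solvation", "residue_charges"):
            for k, v in getattr(self, table).items():
                lines.append(f"{table}.{k} = {v}")
        for key in ("backbone_charge_n", "backbone_charge_o", "dielectric",
                    "nonbonded_cutoff", "air_upper_bound",
                    "air_force_constant", "probe", "sasa_points"):
            lines.append(f"{key} = {getattr(self, key)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ScoringConfig":
        cfg = cls()
        tables = {t: dict(getattr(cfg, t))
                  for t in ("lj_sigma", "lj_epsilon", "solvation",
                            "residue_charges")}
        scalars: dict[str, float] = {}
        for raw in Path(path).read_text().splitlines():
            raw = raw.split("#")[0].strip()
            if not raw:
                continue
            key, _, value = raw.partition("=")
            key = key.strip()
            value = value.strip()
            if "." in key and key.split(".")[0] in tables:
                table, entry = key.split(".", 1)
                tables[table][entry] = float(value)
            else:
                scalars[key] = float(value)
        if "sasa_points" in scalars:
            scalars["sasa_points"] = int(scalars["sasa_points"])
        return replace(cfg, **tables, **scalars)


DEFAULT_CONFIG = ScoringConfig()


# ---------------------------------------------------------------------------
# molecule arrays
# ---------------------------------------------------------------------------


class MoleculeArrays:
    """Flat per-heavy-atom parameter arrays for one molecule, the working
    representation of the energy kernels."""

    def __init__(self, structure: Structure, config: ScoringConfig,
                 charged_nter: bool = False, charged_cter: bool = False):
        atoms = structure.heavy_atoms()
        if not atoms:
            raise PepdockError("molecule has no heavy atoms")
        self.structure = structure
        self.keys = [(cid, r.seq_id, r.insertion_code, a.name)
                     for cid, r, a in atoms]
        self.coords = np.array([a.coords for _, _, a in atoms])
        n = len(atoms)
        self.radii = np.empty(n)
        self.sigma = np.empty(n)
        self.epsilon = np.empty(n)
        self.solv = np.empty(n)
        self.charge = np.zeros(n)
        from .structmodel import VDW_RADII

        for i, (cid, res, atom) in enumerate(atoms):
            el = atom.element
            if el not in config.lj_sigma or el not in VDW_RADII:
                raise PepdockError(
                    f"no parameters for element {el!r} (atom {atom.name} "
                    f"of {res.name}{res.seq_id})")
            self.radii[i] = VDW_RADII[el]
            self.sigma[i] = config.lj_sigma[el]
            self.epsilon[i] = config.lj_epsilon[el]
            self.solv[i] = config.solvation[el]
            if atom.name == "N":
                self.charge[i] = config.backbone_charge_n
            elif atom.name == "O":
                self.charge[i] = config.backbone_charge_o
            elif atom.name == "CB":
                self.charge[i] = config.residue_charges.get(res.name, 0.0)
        # charged termini add +1 on the first amide N, -1 on the last C
        first_chain = structure.chains[0]
        if charged_nter:
            tgt = (first_chain.chain_id, first_chain.residues[0].seq_id,
                   first_chain.residues[0].insertion_code, "N")
            self.charge[self.keys.index(tgt)] += 1.0
        if charged_cter:
            tgt = (first_chain.chain_id, first_chain.residues[-1].seq_id,
                   first_chain.residues[-1].insertion_code, "C")
            self.charge[self.keys.index(tgt)] += 1.0
        self.index_of = {k: i for i, k in enumerate(self.keys)}

    def residue_indices(self, triple: tuple[str, int, str]) -> np.ndarray:
        cid, seq_id, icode = triple
        idx = [i for i, (c, s, ic, _) in enumerate(self.keys)
               if (c, s, ic) == (cid, seq_id, icode)]
        if not idx:
            raise PepdockError(f"residue {triple} not found in molecule")
        return np.asarray(idx)


# ---------------------------------------------------------------------------
# AIR definition and energy
# ---------------------------------------------------------------------------


def define_airs(complex_reference: Structure, receptor_chain: str,
                peptide_chain: str, cutoff: float = 5.0,
                config: ScoringConfig = DEFAULT_CONFIG) -> AirRestraintSet:
    """Ambiguous restraints from a reference complex: active = receptor
    residues with any heavy atom within ``cutoff`` Å of the peptide chain,
    passive = every peptide residue.

    This deliberately broad definition marks the approximate binding region
    without singling out the exact pocket.
    """
    receptor_sel = chain_selection(complex_reference, receptor_chain)
    peptide_sel = chain_selection(complex_reference, peptide_chain)
    active = residues_within(complex_reference, receptor_sel, peptide_sel, cutoff)
    if len(active) == 0:
        raise NoInterfaceError(
            f"no receptor residue within {cutoff} Å of chain {peptide_chain}")
    return AirRestraintSet(active=active, passive=peptide_sel,
                           upper_bound=config.air_upper_bound,
                           force_constant=config.air_force_constant)


def _air_energy_arrays(active_groups: list[np.ndarray], rec_coords: np.ndarray,
                       pep_coords: np.ndarray, upper_bound: float,
                       force_constant: float) -> float:
    total = 0.0
    for idx in active_groups:
        d2 = np.sum((rec_coords[idx][:, None, :] - pep_coords[None, :, :]) ** 2,
                    axis=2)
        inv6 = np.sum(d2 ** -3)
        d_eff = inv6 ** (-1.0 / 6.0)
        excess = d_eff - upper_bound
        if excess > 0:
            total += force_constant * excess * excess
    return total


def air_energy(receptor: Structure, peptide: Structure,
               airs: AirRestraintSet,
               config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Effective-distance restraint energy of a pose (zero when every active
    residue is satisfied)."""
    rec = MoleculeArrays(receptor, config)
    pep = MoleculeArrays(peptide, config)
    groups = [rec.residue_indices(t) for t in airs.active.triples]
    # passive selection restricts which peptide atoms pool into d_eff
    pep_idx = [i for i, (c, s, ic, _) in enumerate(pep.keys)
               if (c, s, ic) in set(airs.passive.triples)]
    return _air_energy_arrays(groups, rec.coords, pep.coords[pep_idx],
                              airs.upper_bound, airs.force_constant)


# ---------------------------------------------------------------------------
# nonbonded terms
# ---------------------------------------------------------------------------


def _nonbonded_pairs(a: MoleculeArrays, b: MoleculeArrays, cutoff: float
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tree = cKDTree(a.coords)
    pairs = tree.query_ball_point(b.coords, cutoff)
    ia, ib = [], []
    for j, neigh in enumerate(pairs):
        ia.extend(neigh)
        ib.extend([j] * len(neigh))
    ia = np.asarray(ia, dtype=int)
    ib = np.asarray(ib, dtype=int)
    if len(ia) == 0:
        return ia, ib, np.zeros(0)
    d = np.linalg.norm(a.coords[ia] - b.coords[ib], axis=1)
    return ia, ib, d


def _vdw_from_pairs(a: MoleculeArrays, b: MoleculeArrays, ia, ib, d,
                    cutoff: float) -> float:
    if len(ia) == 0:
        return 0.0
    sigma = 0.5 * (a.sigma[ia] + b.sigma[ib])
    eps = np.sqrt(a.epsilon[ia] * b.epsilon[ib])
    d = np.maximum(d, 0.6 * sigma)  # soft core: cap the clash penalty
    sr6 = (sigma / d) ** 6
    sc6 = (sigma / cutoff) ** 6
    # truncated and shifted so the potential vanishes at the cutoff
    return float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)
                        - 4.0 * eps * (sc6 * sc6 - sc6)))


def _elec_from_pairs(a: MoleculeArrays, b: MoleculeArrays, ia, ib, d,
                     dielectric: float) -> float:
    if len(ia) == 0:
        return 0.0
    qq = a.charge[ia] * b.charge[ib]
    mask = qq != 0.0
    if not mask.any():
        return 0.0
    d = np.maximum(d[mask], 1.0)
    return float(np.sum(COULOMB_CONSTANT * qq[mask] / (dielectric * d)))


def vdw_energy(receptor: Structure, peptide: Structure,
               config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Intermolecular 12-6 Lennard-Jones energy (truncated-shifted)."""
    a = MoleculeArrays(receptor, config)
    b = MoleculeArrays(peptide, config)
    ia, ib, d = _nonbonded_pairs(a, b, config.nonbonded_cutoff)
    return _vdw_from_pairs(a, b, ia, ib, d, config.nonbonded_cutoff)


def elec_energy(receptor: Structure, peptide: Structure,
                config: ScoringConfig = DEFAULT_CONFIG,
                peptide_charged_termini: tuple[bool, bool] = (False, False)
                ) -> float:
    """Intermolecular Coulomb energy with a uniform relative dielectric."""
    a = MoleculeArrays(receptor, config)
    b = MoleculeArrays(peptide, config, *peptide_charged_termini)
    ia, ib, d = _nonbonded_pairs(a, b, config.nonbonded_cutoff)
    return _elec_from_pairs(a, b, ia, ib, d, config.dielectric)


# ---------------------------------------------------------------------------
# buried surface and desolvation
# ---------------------------------------------------------------------------


def _delta_sasa(a: MoleculeArrays, b: MoleculeArrays, config: ScoringConfig
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-atom SASA change (complex − free) for both molecules.

    Only atoms within occlusion range of the partner can change, so the
    free-state and complex-state areas are recomputed just for those; the
    free state is evaluated at the *current* orientation so that separated
    molecules give exactly zero change at any dot density.
    """
    reach = float(a.radii.max() + b.radii.max() + 2.0 * config.probe)
    tree_b = cKDTree(b.coords)
    cand_a = np.asarray(sorted({i for i, neigh in enumerate(
        tree_b.query_ball_point(a.coords, reach)) if neigh}), dtype=int)
    tree_a = cKDTree(a.coords)
    cand_b = np.asarray(sorted({i for i, neigh in enumerate(
        tree_a.query_ball_point(b.coords, reach)) if neigh}), dtype=int)
    if len(cand_a) == 0 and len(cand_b) == 0:
        return (np.zeros(0), cand_a, np.zeros(0), cand_b)
    all_coords = np.vstack([a.coords, b.coords])
    all_radii = np.concatenate([a.radii, b.radii])
    na = len(a.coords)
    kw = dict(probe=config.probe, n_points=config.sasa_points)
    free_a = sasa_of_atoms(a.coords, a.radii, cand_a, **kw) if len(cand_a) else np.zeros(0)
    free_b = sasa_of_atoms(b.coords, b.radii, cand_b, **kw) if len(cand_b) else np.zeros(0)
    bound_a = sasa_of_atoms(all_coords, all_radii, cand_a, **kw) if len(cand_a) else np.zeros(0)
    bound_b = sasa_of_atoms(all_coords, all_radii, cand_b + na, **kw) if len(cand_b) else np.zeros(0)
    return bound_a - free_a, cand_a, bound_b - free_b, cand_b


def buried_surface_area(receptor: Structure, peptide: Structure,
                        config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """BSA = SASA(receptor) + SASA(peptide) − SASA(complex), in Å²."""
    a = MoleculeArrays(receptor, config)
    b = MoleculeArrays(peptide, config)
    da, _, db, _ = _delta_sasa(a, b, config)
    return float(-(da.sum() + db.sum()))


def desolvation_energy(receptor: Structure, peptide: Structure,
                       config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Empirical desolvation: per-atom solvation parameter times the SASA
    change upon complexation."""
    a = MoleculeArrays(receptor, config)
    b = MoleculeArrays(peptide, config)
    da, ca, db, cb = _delta_sasa(a, b, config)
    e = 0.0
    if len(ca):
        e += float(np.sum(a.solv[ca] * da))
    if len(cb):
        e += float(np.sum(b.solv[cb] * db))
    return e


def rigid_score(receptor: Structure, peptide: Structure,
                airs: AirRestraintSet,
                config: ScoringConfig = DEFAULT_CONFIG,
                peptide_charged_termini: tuple[bool, bool] = (False, False)
                ) -> ScoreComponents:
    """All five components of the rigid-body composite score for one pose."""
    scorer = PoseScorer(receptor, peptide, airs, config,
                        peptide_charged_termini)
    return scorer.components(scorer.pep.coords)


# ---------------------------------------------------------------------------
# pose scorer (hot path for docking)
# ---------------------------------------------------------------------------


class PoseScorer:
    """Precomputes the receptor- and peptide-side arrays once, then scores
    arbitrary rigid placements of the peptide (passed as transformed
    coordinate arrays).

    The buried-surface terms are computed incrementally: per-atom free
    SASAs and intramolecular occluder lists are cached (they are invariant
    under rigid motion of the peptide, provided the peptide's dot sphere is
    rotated along with it), so each evaluation only recomputes the bound
    state of the handful of atoms that can touch the partner. This keeps
    BSA exactly zero for separated molecules and non-negative always.
    """

    def __init__(self, receptor: Structure, peptide: Structure,
                 airs: AirRestraintSet,
                 config: ScoringConfig = DEFAULT_CONFIG,
                 peptide_charged_termini: tuple[bool, bool] = (False, False)):
        from .structmodel import _unit_sphere

        self.config = config
        self.airs = airs
        self.rec = MoleculeArrays(receptor, config)
        self.pep = MoleculeArrays(peptide, config, *peptide_charged_termini)
        self.active_groups = [self.rec.residue_indices(t)
                              for t in airs.active.triples]
        passive = set(airs.passive.triples)
        self._passive_idx = np.asarray(
            [i for i, (c, s, ic, _) in enumerate(self.pep.keys)
             if (c, s, ic) in passive], dtype=int)
        self._rec_tree = cKDTree(self.rec.coords)
        self._sphere = _unit_sphere(config.sasa_points)
        p = config.probe
        #: largest centre-centre distance at which two atoms can occlude
        self._reach = float(self.rec.radii.max() + self.pep.radii.max() + 2 * p)
        self._rec_free = self._free_sasa(self.rec)
        self._pep_free = self._free_sasa(self.pep)
        self._rec_intra = self._pad_intra(self._intra_lists(self.rec),
                                          len(self.rec.coords))
        self._pep_intra = self._pad_intra(self._intra_lists(self.pep),
                                          len(self.pep.coords))

    def _free_sasa(self, mol: MoleculeArrays) -> np.ndarray:
        return sasa_of_atoms(mol.coords, mol.radii, probe=self.config.probe,
                             n_points=self.config.sasa_points)

    def _intra_lists(self, mol: MoleculeArrays) -> list[np.ndarray]:
        tree = cKDTree(mol.coords)
        reach = 2.0 * mol.radii.max() + 2.0 * self.config.probe
        out = []
        for i, neigh in enumerate(tree.query_ball_point(mol.coords, reach)):
            out.append(np.asarray([j for j in neigh if j != i], dtype=int))
        return out

    def _pairs(self, pep_coords: np.ndarray):
        neigh = self._rec_tree.query_ball_point(pep_coords,
                                                self.config.nonbonded_cutoff)
        ia, ib = [], []
        for j, nb in enumerate(neigh):
            ia.extend(nb)
            ib.extend([j] * len(nb))
        ia = np.asarray(ia, dtype=int)
        ib = np.asarray(ib, dtype=int)
        d = (np.linalg.norm(self.rec.coords[ia] - pep_coords[ib], axis=1)
             if len(ia) else np.zeros(0))
        return ia, ib, d

    def restraint_energy(self, pep_coords: np.ndarray) -> float:
        return _air_energy_arrays(self.active_groups, self.rec.coords,
                                  pep_coords[self._passive_idx],
                                  self.airs.upper_bound,
                                  self.airs.force_constant)

    def cheap_score(self, pep_coords: np.ndarray) -> float:
        """Weighted sum of the SASA-free components (restraints, vdw,
        electrostatics) — the surrogate minimised in the first stage."""
        ia, ib, d = self._pairs(pep_coords)
        e_vdw = _vdw_from_pairs(self.rec, self.pep, ia, ib, d,
                                self.config.nonbonded_cutoff)
        e_elec = _elec_from_pairs(self.rec, self.pep, ia, ib, d,
                                  self.config.dielectric)
        e_rest = self.restraint_energy(pep_coords)
        return (WEIGHTS["e_rest"] * e_rest + WEIGHTS["e_vdw"] * e_vdw
                + WEIGHTS["e_elec"] * e_elec)

    @staticmethod
    def _pad_intra(lists: list[np.ndarray], n_atoms: int) -> np.ndarray:
        """Pad per-atom intramolecular occluder index lists into one int
        array; the pad value ``n_atoms`` addresses a dummy far-away row."""
        width = max((len(l) for l in lists), default=0)
        out = np.full((len(lists), max(width, 1)), n_atoms, dtype=int)
        for i, l in enumerate(lists):
            out[i, :len(l)] = l
        return out

    @staticmethod
    def _pad_groups(keys: np.ndarray, values: np.ndarray, pad: int
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Group ``values`` by ``keys`` (cross-pair lists per candidate),
        returning unique keys and a padded value array."""
        order = np.argsort(keys, kind="stable")
        keys, values = keys[order], values[order]
        uniq, starts = np.unique(keys, return_index=True)
        counts = np.diff(np.append(starts, len(keys)))
        out = np.full((len(uniq), counts.max()), pad, dtype=int)
        for r, (s, c) in enumerate(zip(starts, counts)):
            out[r, :c] = values[s:s + c]
        return uniq, out

    def _bound_areas(self, cand: np.ndarray, own_ext: np.ndarray,
                     own_radii_ext: np.ndarray, intra_pad: np.ndarray,
                     sphere: np.ndarray, other_ext: np.ndarray,
                     other_radii_ext: np.ndarray, cross_pad: np.ndarray
                     ) -> np.ndarray:
        """Batched Shrake-Rupley areas of candidate atoms in the complex:
        occluders are the (padded) intramolecular lists plus the (padded)
        cross-molecule contacts; padded entries sit at a far dummy point."""
        p = self.config.probe
        ri = own_radii_ext[cand] + p
        pts = own_ext[cand][:, None, :] + ri[:, None, None] * sphere[None]
        occ = np.concatenate([own_ext[intra_pad[cand]],
                              other_ext[cross_pad]], axis=1)
        orad = np.concatenate([own_radii_ext[intra_pad[cand]],
                               other_radii_ext[cross_pad]], axis=1) + p
        pts2 = np.einsum("cpk,cpk->cp", pts, pts)
        occ2 = np.einsum("cok,cok->co", occ, occ)
        dot = pts @ occ.transpose(0, 2, 1)
        buried = (pts2[:, :, None] + occ2[:, None, :] - 2.0 * dot
                  ) < (orad ** 2)[:, None, :]
        frac = 1.0 - buried.any(axis=2).mean(axis=1)
        return 4.0 * np.pi * ri * ri * frac

    def _interface_delta(self, pep_coords: np.ndarray, ia, ib, d,
                         rotation: np.ndarray | None
                         ) -> tuple[float, float]:
        """(BSA, desolvation energy) from the per-atom SASA change of the
        atoms in occlusion range of the partner."""
        thr = self.rec.radii[ia] + self.pep.radii[ib] + 2 * self.config.probe \
            if len(ia) else np.zeros(0)
        close = d < thr if len(ia) else np.zeros(0, dtype=bool)
        if not len(ia) or not close.any():
            return 0.0, 0.0
        ia_c, ib_c = ia[close], ib[close]
        far = np.array([[1e6, 1e6, 1e6]])
        rec_ext = np.vstack([self.rec.coords, far])
        pep_ext = np.vstack([pep_coords, far])
        rec_radii_ext = np.append(self.rec.radii, -self.config.probe)
        pep_radii_ext = np.append(self.pep.radii, -self.config.probe)
        pep_sphere = self._sphere if rotation is None \
            else self._sphere @ np.asarray(rotation, float).T
        cand_a, cross_a = self._pad_groups(ia_c, ib_c, len(pep_coords))
        cand_b, cross_b = self._pad_groups(ib_c, ia_c, len(self.rec.coords))
        bound_a = self._bound_areas(cand_a, rec_ext, rec_radii_ext,
                                    self._rec_intra, self._sphere,
                                    pep_ext, pep_radii_ext, cross_a)
        bound_b = self._bound_areas(cand_b, pep_ext, pep_radii_ext,
                                    self._pep_intra, pep_sphere,
                                    rec_ext, rec_radii_ext, cross_b)
        delta_a = bound_a - self._rec_free[cand_a]
        delta_b = bound_b - self._pep_free[cand_b]
        bsa = -(delta_a.sum() + delta_b.sum())
        desol = float(np.sum(self.rec.solv[cand_a] * delta_a)
                      + np.sum(self.pep.solv[cand_b] * delta_b))
        return float(bsa), desol

    def components(self, pep_coords: np.ndarray,
                   rotation: np.ndarray | None = None) -> ScoreComponents:
        """Score components of the peptide placed at ``pep_coords``.

        ``rotation`` is the rigid rotation taking the scorer's stored
        peptide frame onto ``pep_coords``; when given, the SASA dot sphere
        co-rotates so the buried-area terms are exactly rigid-motion
        consistent. When omitted the identity is assumed (coordinates in
        the stored frame, as for a reference pose).
        """
        ia, ib, d = self._pairs(pep_coords)
        e_vdw = _vdw_from_pairs(self.rec, self.pep, ia, ib, d,
                                self.config.nonbonded_cutoff)
        e_elec = _elec_from_pairs(self.rec, self.pep, ia, ib, d,
                                  self.config.dielectric)
        e_rest = self.restraint_energy(pep_coords)
        bsa, e_desol = self._interface_delta(pep_coords, ia, ib, d, rotation)
        return ScoreComponents(e_rest, e_vdw, e_elec, e_desol, bsa)

    def total(self, pep_coords: np.ndarray,
              rotation: np.ndarray | None = None) -> float:
        return self.components(pep_coords, rotation).total


class MoleculeView:
    """A MoleculeArrays with substituted coordinates (rigid placement)."""

    def __init__(self, base: MoleculeArrays, coords: np.ndarray):
        self.coords = np.asarray(coords, float)
        self.radii = base.radii
        self.sigma = base.sigma
        self.epsilon = base.epsilon
        self.solv = base.solv
        self.charge = base.charge
        self.keys = base.keys


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_airs_table(airs: AirRestraintSet, path: str | Path) -> None:
    lines = ["role\tchain\tseq_id\ticode",
             *(f"active\t{c}\t{s}\t{ic}" for c, s, ic in airs.active.triples),
             *(f"passive\t{c}\t{s}\t{ic}" for c, s, ic in airs.passive.triples)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_airs_cns(airs: AirRestraintSet, path: str | Path) -> None:
    """CNS-style ambiguous ``assign`` statements, one per active residue."""
    lines = []
    pep_sel = " or ".join(f"(segid {c} and resid {s})"
                          for c, s, _ in airs.passive.triples)
    for c, s, _ in airs.active.triples:
        lines.append(f"assign (segid {c} and resid {s}) ({pep_sel}) "
                     f"{airs.upper_bound:.1f} {airs.upper_bound:.1f} 0.0")
    Path(path).write_text("\n".join(lines) + "\n")
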