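"""Peptide conformational classes and docking-difficulty classes.

Bound peptides are sorted into three conformational classes — helix,
extended, disordered — and each docking case into a difficulty class —
easy, medium, difficult — from the backbone RMSD between the bound peptide
and its ideal extended build:

* helix: more than half of the residues in a helical conformation;
* extended: per-residue Cα extension ≥ 2.8 Å (80% of the 3.46 Å ideal);
* disordered: everything else;
* easy / medium / difficult at bound-vs-extended RMSD ≤ 4 / ≤ 8 / > 8 Å.

Secondary structure is assigned by a dihedral-window rule (a run of ≥ 4
consecutive residues with helical φ/ψ) rather than by an external program,
which is known to be unreliable on very short chains; a hook accepts
user-provided per-residue assignments instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import conformers
from .structmodel import (
    PairingError,
    Structure,
    chain_selection,
    kabsch_superpose,
    residues_within,
    BACKBONE_ATOMS,
)

__all__ = [
    "PeptideClass",
    "DifficultyClass",
    "EXTENSION_CUTOFF",
    "HELIX_PHI_WINDOW",
    "HELIX_PSI_WINDOW",
    "assign_helical_residues",
    "classify_peptide",
    "classify_difficulty",
    "difficulty_from_rmsd",
    "receptor_conformational_change",
    "LARGE_CHANGE_CUTOFF",
]

#: Extendedness cut in Å/residue: 80% of the ideal 3.46 Å extension,
#: rounded as conventionally printed (0.8 × 3.46 = 2.8).
EXTENSION_CUTOFF = 2.8

HELIX_PHI_WINDOW = (-100.0, -30.0)
HELIX_PSI_WINDOW = (-80.0, -5.0)
MIN_HELIX_RUN = 4

#: Receptor interface rearrangements above this RMSD (Å) flag a case as a
#: large conformational change.
LARGE_CHANGE_CUTOFF = 2.0


@dataclass(frozen=True)
class PeptideClass:
    label: str  # helix | extended | disordered
    helical_fraction: float
    extension: float


@dataclass(frozen=True)
class DifficultyClass:
    label: str  # easy | medium | difficult
    rmsd_to_extended: float


def assign_helical_residues(peptide: Structure,
                            external: str | None = None) -> list[bool]:
    """Flag residues in a helical conformation.

    A residue is helical iff its (φ, ψ) falls in the helical window
    (φ ∈ [−100, −30], ψ ∈ [−80, −5]) and it belongs to a run of at least
    four consecutive such residues. Terminal residues missing φ or ψ are
    never helical.

    ``external`` optionally supplies a per-residue secondary-structure
    string (e.g. from DSSP/STRIDE); characters in ``"HGI"`` count as
    helical and bypass the dihedral rule.
    """
    residues = peptide.chains[0].residues
    if external is not None:
        if len(external) != len(residues):
            raise PairingError("external assignment length mismatch")
        return [ch in "HGI" for ch in external]
    dihedrals = conformers.measure_backbone_dihedrals(peptide)
    in_window = []
    for phi, psi in dihedrals:
        ok = (phi is not None and psi is not None
              and HELIX_PHI_WINDOW[0] <= phi <= HELIX_PHI_WINDOW[1]
              and HELIX_PSI_WINDOW[0] <= psi <= HELIX_PSI_WINDOW[1])
        in_window.append(ok)
    flags = [False] * len(residues)
    i = 0
    while i < len(in_window):
        if in_window[i]:
            j = i
            while j < len(in_window) and in_window[j]:
                j += 1
            if j - i >= MIN_HELIX_RUN:
                for k in range(i, j):
                    flags[k] = True
            i = j
        else:
            i += 1
    return flags


def classify_peptide(peptide: Structure,
                     external_ss: str | None = None) -> PeptideClass:
    """Assign the conformational class of a (bound) peptide chain.

    The helix test runs first; peptides failing it are extended when the
    per-residue Cα extension reaches :data:`EXTENSION_CUTOFF`, otherwise
    disordered.
    """
    residues = peptide.chains[0].residues
    if len(residues) < 3:
        raise PairingError("peptide must have at least 3 residues")
    flags = assign_helical_residues(peptide, external_ss)
    frac = sum(flags) / len(flags)
    ext = conformers.per_residue_extension(peptide)
    if frac > 0.5:
        label = "helix"
    elif ext >= EXTENSION_CUTOFF:
        label = "extended"
    else:
        label = "disordered"
    return PeptideClass(label, frac, ext)


def difficulty_from_rmsd(rmsd: float) -> str:
    """easy / medium / difficult from the bound-vs-extended backbone RMSD
    (boundaries at 4 and 8 Å, upper bounds inclusive)."""
    if rmsd <= 4.0:
        return "easy"
    if rmsd <= 8.0:
        return "medium"
    return "difficult"


def _paired_backbone(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
    res_a = a.chains[0].residues
    res_b = b.chains[0].residues
    if len(res_a) != len(res_b):
        raise PairingError(f"residue count mismatch: {len(res_a)} vs {len(res_b)}")
    pa, pb = [], []
    for ra, rb in zip(res_a, res_b):
        for name in BACKBONE_ATOMS:
            aa, ab = ra.atom(name), rb.atom(name)
            if aa is not None and ab is not None:
                pa.append(aa.coords)
                pb.append(ab.coords)
    return np.array(pa), np.array(pb)


def classify_difficulty(bound_peptide: Structure, sequence: str) -> DifficultyClass:
    """Difficulty class of a docking case from the backbone RMSD between the
    bound peptide conformation and its ideal extended build."""
    residues = bound_peptide.chains[0].residues
    if len(residues) != len(sequence):
        raise PairingError(
            f"sequence length {len(sequence)} does not match "
            f"{len(residues)} bound residues")
    extended = conformers.build_peptide(
        sequence, conformers.TEMPLATES["extended"],
        chain_id=bound_peptide.chains[0].chain_id)
    pa, pb = _paired_backbone(bound_peptide, extended.structure)
    _, _, rmsd = kabsch_superpose(pb, pa)
    return DifficultyClass(difficulty_from_rmsd(rmsd), rmsd)


def receptor_conformational_change(bound: Structure, unbound: Structure,
                                   peptide_chain: str,
                                   receptor_chain: str | None = None,
                                   cutoff: float = 10.0) -> float:
    """Backbone RMSD of the receptor interface between bound and unbound
    forms.

    The interface is defined on the bound complex as receptor residues with
    any heavy atom within ``cutoff`` Å of the peptide; residues that cannot
    be mapped onto the unbound structure by (seq_id, insertion_code) are
    reported and excluded. Values above 2.0 Å mark a large binding-induced
    rearrangement.
    """
    import warnings

    if receptor_chain is None:
        receptor_chain = next(c for c in bound.chain_ids() if c != peptide_chain)
    interface = residues_within(
        bound,
        chain_selection(bound, receptor_chain),
        chain_selection(bound, peptide_chain),
        cutoff)
    unbound_chain = unbound.chains[0].chain_id if receptor_chain not in \
        unbound.chain_ids() else receptor_chain
    pa, pb = [], []
    for cid, seq_id, icode in interface.triples:
        res_b = bound.chain(cid).residue(seq_id, icode)
        res_u = unbound.chain(unbound_chain).residue(seq_id, icode)
        if res_u is None:
            warnings.warn(f"interface residue {cid}:{seq_id}{icode} missing "
                          f"in unbound structure; excluded")
            continue
        for name in BACKBONE_ATOMS:
            ab, au = res_b.atom(name), res_u.atom(name)
            if ab is not None and au is not None:
                pa.append(ab.coords)
                pb.append(au.coords)
    if len(pa) < 3:
        raise PairingError("fewer than 3 mappable interface backbone atoms")
    _, _, rmsd = kabsch_superpose(np.array(pb), np.array(pa))
    return rmsd
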