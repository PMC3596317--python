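"""Canonical peptide conformer construction.

Bound peptides overwhelmingly adopt one of three backbone conformations:
extended (β-like), α-helix, or polyproline II. This module builds those
three ideal conformers for an arbitrary sequence by sequential
internal-coordinate chain extension (NeRF) from standard bond geometry, so
that a docking run can start from a small, representative conformational
ensemble instead of a single guess.

The shipped dihedral templates are::

    extended  φ = −139°, ψ = −135°
    helix     φ =  −57°, ψ =  −47°
    ppii      φ =  −78°, ψ =  149°

all with ω = 180° (trans peptide bonds). An ideal extended chain has a
per-residue Cα extension (end-to-end distance over n−1) of ≈ 3.46 Å.

Only the backbone (N, CA, C, O) and Cβ are built: the rigid-body stage
operates on this reduced representation, and side chains beyond Cβ would
require rotamer modelling that the rigid protocol cannot exploit anyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structmodel import (
    Atom,
    Chain,
    PepdockError,
    Residue,
    Structure,
    measure_dihedral,
    place_atom_nerf,
)

__all__ = [
    "DihedralTemplate",
    "PeptideConformer",
    "DihedralRestraint",
    "TEMPLATES",
    "ONE_TO_THREE",
    "build_peptide",
    "per_residue_extension",
    "canonical_ensemble",
    "helical_dihedral_restraints",
    "measure_backbone_dihedrals",
    "restraint_energy",
    "write_restraints_table",
    "write_restraints_cns",
]

# Engh-Huber-style standard backbone geometry (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
# Cβ placement frozen from ideal L-alanine: torsion(C, N, CA, CB) = +120°
ANGLE_N_CA_CB = 109.5
TORSION_C_N_CA_CB = 120.0

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class DihedralTemplate:
    """Ideal backbone dihedrals defining one canonical conformation."""

    name: str
    phi: float
    psi: float
    omega: float = 180.0

    def __post_init__(self) -> None:
        for v in (self.phi, self.psi, self.omega):
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"template angle {v} outside (-180, 180]")


#: The canonical three-member ensemble (fixed model order: extended, helix, ppii).
TEMPLATES: dict[str, DihedralTemplate] = {
    "extended": DihedralTemplate("extended", -139.0, -135.0),
    "helix": DihedralTemplate("helix", -57.0, -47.0),
    "ppii": DihedralTemplate("ppii", -78.0, 149.0),
}


@dataclass
class PeptideConformer:
    structure: Structure
    template: DihedralTemplate
    sequence: str
    charged_nter: bool = False
    charged_cter: bool = False

    @property
    def conformer_id(self) -> str:
        return self.template.name


@dataclass(frozen=True)
class DihedralRestraint:
    """Flat-bottom restraint on one backbone dihedral.

    ``atoms`` holds four (chain_id, seq_id, atom_name) references; the
    restraint energy is ``k * max(0, |Δ(target)| − half_width)²`` with Δ the
    wrapped angular deviation in degrees.
    """

    atoms: tuple[tuple[str, int, str], ...]
    target: float
    half_width: float = 10.0
    force_constant: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")


def _validate_sequence(sequence: str) -> str:
    sequence = sequence.strip().upper()
    if len(sequence) < 3:
        raise PepdockError("peptide sequence must have at least 3 residues")
    bad = [ch for ch in sequence if ch not in ONE_TO_THREE]
    if bad:
        raise PepdockError(f"nonstandard amino-acid letters: {sorted(set(bad))}")
    return sequence


def build_peptide(sequence: str, template: DihedralTemplate,
                  charged_nter: bool = False, charged_cter: bool = False,
                  chain_id: str = "B") -> PeptideConformer:
    """Build an ideal peptide conformer from sequence and a dihedral template.

    The backbone is grown N→C by NeRF placement with standard bond lengths
    and angles; every interior (φ, ψ) equals the template exactly and every
    ω is 180°. Cβ is added for all residues except glycine with L
    chirality; carbonyl O is placed anti to the next amide nitrogen.

    Charged-termini flags carry through to the electrostatics term of the
    docking score; no extra atoms are built for them.
    """
    sequence = _validate_sequence(sequence)
    n = len(sequence)
    phi, psi, omega = template.phi, template.psi, template.omega

    # grow the N/CA/C trace
    ncac: list[np.ndarray] = []
    ncac.append(np.zeros(3))                                    # N1
    ncac.append(np.array([BOND_N_CA, 0.0, 0.0]))                # CA1
    ang = np.radians(ANGLE_N_CA_C)
    ncac.append(ncac[1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0]))  # C1
    for i in range(1, n):
        n_i = place_atom_nerf(ncac[-3], ncac[-2], ncac[-1],
                              BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = place_atom_nerf(ncac[-2], ncac[-1], n_i,
                               BOND_N_CA, ANGLE_C_N_CA, omega)
        c_i = place_atom_nerf(ncac[-1], n_i, ca_i,
                              BOND_CA_C, ANGLE_N_CA_C, phi)
        ncac.extend([n_i, ca_i, c_i])

    residues: list[Residue] = []
    for i in range(n):
        nn, ca, cc = ncac[3 * i], ncac[3 * i + 1], ncac[3 * i + 2]
        atoms = [
            Atom("N", "N", nn),
            Atom("CA", "C", ca),
            Atom("C", "C", cc),
        ]
        # carbonyl O anti to the following amide N (same plane); for the
        # C-terminal residue the template psi fixes the virtual direction
        atoms.append(Atom("O", "O", place_atom_nerf(nn, ca, cc, BOND_C_O,
                                                    ANGLE_CA_C_O, psi - 180.0)))
        if sequence[i] != "G":
            atoms.append(Atom("CB", "C", place_atom_nerf(cc, nn, ca, BOND_CA_CB,
                                                         ANGLE_N_CA_CB,
                                                         TORSION_C_N_CA_CB)))
        residues.append(Residue(ONE_TO_THREE[sequence[i]], i + 1, "", atoms))

    structure = Structure([Chain(chain_id, residues)],
                          source=f"{template.name}:{sequence}")
    return PeptideConformer(structure, template, sequence,
                            charged_nter, charged_cter)


def measure_backbone_dihedrals(peptide: Structure
                               ) -> list[tuple[float | None, float | None]]:
    """Measured (φ, ψ) per residue of a single-chain peptide; terminal
    angles that lack a flanking atom are None."""
    residues = peptide.chains[0].residues
    out: list[tuple[float | None, float | None]] = []
    for i, res in enumerate(residues):
        phi = psi = None
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        if i > 0:
            prev_c = residues[i - 1].atom("C")
            if all(a is not None for a in (prev_c, n, ca, c)):
                phi = measure_dihedral(prev_c.coords, n.coords, ca.coords, c.coords)
        if i < len(residues) - 1:
            next_n = residues[i + 1].atom("N")
            if all(a is not None for a in (n, ca, c, next_n)):
                psi = measure_dihedral(n.coords, ca.coords, c.coords, next_n.coords)
        out.append((phi, psi))
    return out


def per_residue_extension(peptide: Structure) -> float:
    """End-to-end Cα distance divided by (n − 1), in Å per residue.

    An ideal extended chain measures ≈ 3.46 Å/residue; compact
    conformations score lower, which is the basis of the extended /
    disordered classification.
    """
    cas = []
    for res in peptide.chains[0].residues:
        ca = res.atom("CA")
        if ca is None:
            raise PepdockError(f"residue {res.name}{res.seq_id} lacks a CA atom")
        cas.append(ca.coords)
    if len(cas) < 2:
        raise PepdockError("need at least 2 CA atoms for extension")
    return float(np.linalg.norm(cas[0] - cas[-1])) / (len(cas) - 1)


def canonical_ensemble(sequence: str, charged_nter: bool = False,
                       charged_cter: bool = False, chain_id: str = "B"
                       ) -> list[PeptideConformer]:
    """The three canonical conformers in fixed order: extended, helix, ppii."""
    return [build_peptide(sequence, TEMPLATES[name], charged_nter,
                          charged_cter, chain_id)
            for name in ("extended", "helix", "ppii")]


def helical_dihedral_restraints(conformer: PeptideConformer,
                                helix_assignment: list[bool] | None = None,
                                half_width: float = 10.0,
                                force_constant: float = 1.0
                                ) -> list[DihedralRestraint]:
    """Backbone φ/ψ restraints (± ``half_width`` around the measured value)
    for residues flagged helical.

    These keep helical regions from unwinding under flexible refinement;
    one φ and one ψ restraint is emitted per flagged residue where the four
    defining atoms exist.
    """
    structure = conformer.structure
    chain = structure.chains[0]
    residues = chain.residues
    if helix_assignment is None:
        helix_assignment = [True] * len(residues)
    if len(helix_assignment) != len(residues):
        raise PepdockError("helix assignment length mismatch")
    dihedrals = measure_backbone_dihedrals(structure)
    cid = chain.chain_id
    out: list[DihedralRestraint] = []
    for i, (res, flagged) in enumerate(zip(residues, helix_assignment)):
        if not flagged:
            continue
        phi, psi = dihedrals[i]
        if phi is not None:
            out.append(DihedralRestraint(
                atoms=((cid, residues[i - 1].seq_id, "C"),
                       (cid, res.seq_id, "N"),
                       (cid, res.seq_id, "CA"),
                       (cid, res.seq_id, "C")),
                target=phi, half_width=half_width,
                force_constant=force_constant, label=f"phi:{res.seq_id}"))
        if psi is not None:
            out.append(DihedralRestraint(
                atoms=((cid, res.seq_id, "N"),
                       (cid, res.seq_id, "CA"),
                       (cid, res.seq_id, "C"),
                       (cid, residues[i + 1].seq_id, "N")),
                target=psi, half_width=half_width,
                force_constant=force_constant, label=f"psi:{res.seq_id}"))
    return out


def _wrapped_deviation(value: float, target: float) -> float:
    d = (value - target + 180.0) % 360.0 - 180.0
    return abs(d)


def restraint_energy(structure: Structure,
                     restraints: list[DihedralRestraint]) -> float:
    """Flat-bottom harmonic energy of a set of dihedral restraints on a
    structure (zero inside target ± half_width)."""
    total = 0.0
    for r in restraints:
        pts = []
        for cid, seq_id, name in r.atoms:
            res = structure.chain(cid).residue(seq_id)
            atom = res.atom(name) if res is not None else None
            if atom is None:
                raise PepdockError(f"restraint atom ({cid},{seq_id},{name}) missing")
            pts.append(atom.coords)
        value = measure_dihedral(*pts)
        excess = max(0.0, _wrapped_deviation(value, r.target) - r.half_width)
        total += r.force_constant * excess * excess
    return total


def write_restraints_table(restraints: list[DihedralRestraint],
                           path: str | Path) -> None:
    """Plain-text table: one restraint per line (atom quadruple, target,
    half-width, force constant)."""
    lines = ["label\tatoms\ttarget_deg\thalf_width_deg\tforce_constant"]
    for r in restraints:
        quad = ",".join(f"{c}:{s}:{n}" for c, s, n in r.atoms)
        lines.append(f"{r.label}\t{quad}\t{r.target:.4f}\t{r.half_width:.2f}"
                     f"\t{r.force_constant:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_restraints_cns(restraints: list[DihedralRestraint],
                         path: str | Path) -> None:
    """CNS-style ``assign`` dihedral statements."""
    lines = []
    for r in restraints:
        sel = " ".join(
            f"(segid {c} and resid {s} and name {n})" for c, s, n in r.atoms)
        lines.append(f"assign {sel} {r.force_constant:.1f} {r.target:.2f} "
                     f"{r.half_width:.1f} 2")
    Path(path).write_text("\n".join(lines) + "\n")
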