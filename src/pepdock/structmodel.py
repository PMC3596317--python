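"""Coordinate data model, PDB I/O and geometric primitives.

This module is the foundation of the toolkit: a light hierarchical
``Atom``/``Residue``/``Chain``/``Structure`` model read from standard PDB
files (via Biopython), plus the geometry kernels every downstream stage
relies on — Kabsch superposition, RMSD, dihedral angles, internal-coordinate
atom placement (NeRF), Shrake–Rupley solvent-accessible surface areas,
relative accessibility, and residue-residue contact selections.

Conventions used throughout the package:

* author residue numbering from the PDB file is preserved (1-based, with
  insertion codes), never renumbered;
* hydrogens (and deuteriums) are ignored in all distance, contact and SASA
  computations;
* the backbone atom set is ``{N, CA, C, O}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "Selection",
    "BACKBONE_ATOMS",
    "VDW_RADII",
    "PepdockError",
    "EmptyStructureError",
    "DegenerateGeometryError",
    "PairingError",
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "kabsch_superpose",
    "apply_transform",
    "rmsd_no_fit",
    "superposed_rmsd",
    "measure_dihedral",
    "measure_angle",
    "place_atom_nerf",
    "shrake_rupley_sasa",
    "sasa_of_atoms",
    "residue_sasa",
    "relative_accessibility",
    "residues_within",
    "chain_selection",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Element-based van der Waals radii (Å) used for SASA and contact work.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PepdockError(Exception):
    """Base class for toolkit errors."""


class EmptyStructureError(PepdockError):
    """Raised when a parsed file contains no protein atoms."""


class DegenerateGeometryError(PepdockError):
    """Raised for geometric operations on degenerate input (collinear
    superposition sets, coincident dihedral points, ...)."""


class PairingError(PepdockError):
    """Raised when two coordinate sets cannot be put in 1:1 correspondence."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(), self.occupancy, self.altloc)


@dataclass
class Residue:
    name: str
    seq_id: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def backbone(self) -> list[Atom]:
        out = []
        for name in BACKBONE_ATOMS:
            a = self.atom(name)
            if a is not None:
                out.append(a)
        return out

    def copy(self) -> "Residue":
        return Residue(self.name, self.seq_id, self.insertion_code,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seq_id: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.seq_id == seq_id and r.insertion_code == insertion_code:
                return r
        return None

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    source: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.source!r}")

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def iter_residues(self) -> Iterator[tuple[str, Residue]]:
        for c in self.chains:
            for r in c.residues:
                yield c.chain_id, r

    def heavy_atoms(self) -> list[tuple[str, Residue, Atom]]:
        return [(cid, r, a) for cid, r in self.iter_residues() for a in r.heavy_atoms()]

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms()
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for _, _, a in atoms])

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())

    def copy(self) -> "Structure":
        return Structure([c.copy() for c in self.chains], self.source)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chain_ids: Sequence[str] | None = None) -> "Structure":
        """Return a copy with ``x -> R x + t`` applied to the given chains
        (all chains when ``chain_ids`` is None)."""
        out = self.copy()
        targets = set(chain_ids) if chain_ids is not None else set(out.chain_ids())
        for c in out.chains:
            if c.chain_id in targets:
                for r in c.residues:
                    for a in r.atoms:
                        a.coords = rotation @ a.coords + np.asarray(translation, float)
        return out

    def merged_with(self, other: "Structure") -> "Structure":
        """Concatenate the chains of two structures into one complex."""
        merged = self.copy()
        ids = set(merged.chain_ids())
        for c in other.chains:
            if c.chain_id in ids:
                raise ValueError(f"duplicate chain id {c.chain_id!r} in merge")
            merged.chains.append(c.copy())
        return merged


@dataclass(frozen=True)
class Selection:
    """A set of residues (as ``(chain_id, seq_id, insertion_code)`` triples)
    with an optional atom-name filter."""

    triples: tuple[tuple[str, int, str], ...]
    atom_names: frozenset[str] | None = None

    @classmethod
    def of(cls, triples: Iterable[tuple[str, int, str]],
           atom_names: Iterable[str] | None = None) -> "Selection":
        names = frozenset(atom_names) if atom_names is not None else None
        return cls(tuple(triples), names)

    def with_atoms(self, atom_names: Iterable[str] | None) -> "Selection":
        return Selection.of(self.triples, atom_names)

    def __len__(self) -> int:
        return len(self.triples)

    def resolve(self, structure: Structure) -> list[tuple[str, Residue]]:
        out = []
        for cid, seq_id, icode in self.triples:
            res = structure.chain(cid).residue(seq_id, icode)
            if res is None:
                raise PairingError(
                    f"selection triple ({cid}, {seq_id}, {icode!r}) "
                    f"does not resolve in structure {structure.source!r}")
            out.append((cid, res))
        return out

    def atoms(self, structure: Structure) -> list[tuple[str, Residue, Atom]]:
        """Heavy atoms of the selected residues, honouring the name filter."""
        out = []
        for cid, res in self.resolve(structure):
            for a in res.heavy_atoms():
                if self.atom_names is None or a.name in self.atom_names:
                    out.append((cid, res, a))
        return out

    def coords(self, structure: Structure) -> np.ndarray:
        atoms = self.atoms(structure)
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for _, _, a in atoms])


def chain_selection(structure: Structure, chain_id: str,
                    atom_names: Iterable[str] | None = None) -> Selection:
    """Selection of every residue of one chain."""
    chain = structure.chain(chain_id)
    return Selection.of([(chain_id, r.seq_id, r.insertion_code) for r in chain.residues],
                        atom_names)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def _element_of(bio_atom) -> str:
    el = (bio_atom.element or "").strip().upper()
    if not el:
        # infer from the atom name: first alphabetic character
        for ch in bio_atom.get_name():
            if ch.isalpha():
                el = ch.upper()
                break
    return el


def _convert_bio_model(model, source: str) -> Structure:
    chains: list[Chain] = []
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, seq_id, icode = bio_res.get_id()
            if hetflag == "W" or bio_res.get_resname().strip() in _WATER_NAMES:
                continue
            # altloc resolution: keep the highest-occupancy variant of each
            # atom name; ties keep the first encountered.
            best: dict[str, Atom] = {}
            order: list[str] = []
            for bio_atom in bio_res.get_unpacked_list():
                name = bio_atom.get_name()
                occ = bio_atom.get_occupancy()
                occ = 1.0 if occ is None else float(occ)
                atom = Atom(
                    name=name,
                    element=_element_of(bio_atom),
                    coords=np.array(bio_atom.get_coord(), dtype=float),
                    occupancy=occ,
                    altloc=(bio_atom.get_altloc() or "").strip(),
                )
                if name not in best:
                    best[name] = atom
                    order.append(name)
                elif occ > best[name].occupancy:
                    best[name] = atom
            if best:
                residues.append(Residue(bio_res.get_resname().strip(), seq_id,
                                        icode.strip(), [best[n] for n in order]))
        if residues:
            chains.append(Chain(bio_chain.get_id().strip() or "A", residues))
    return Structure(chains, source)


def read_pdb_models(path: str | Path) -> list[Structure]:
    """Read every MODEL of a PDB file as a separate :class:`Structure`.

    Waters are dropped and alternate locations resolved to the
    highest-occupancy conformer (ties: first in file).
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure(path.stem, str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise IOError(f"cannot parse PDB file {path}: {exc}") from exc
    models = [_convert_bio_model(m, path.stem) for m in bio]
    models = [m for m in models if m.chains]
    if not models:
        raise EmptyStructureError(f"{path} contains no protein atoms")
    return models


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file as a single :class:`Structure` (MODEL 1 only)."""
    return read_pdb_models(path)[0]


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element right-justified in 13-14 for 1-2 letter
    # elements with short names.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structures: Structure | Sequence[Structure], path: str | Path) -> None:
    """Write one structure (or a sequence, as a multi-MODEL ensemble) in
    standard PDB format."""
    if isinstance(structures, Structure):
        models = [structures]
        multi = False
    else:
        models = list(structures)
        multi = len(models) > 1
    lines: list[str] = []
    for i, structure in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        serial = 1
        for chain in structure.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    lines.append(
                        "ATOM  {serial:5d} {name}{alt:1s}{res:>3s} {chain:1s}"
                        "{seq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                        "{occ:6.2f}{b:6.2f}          {el:>2s}".format(
                            serial=serial,
                            name=_format_atom_name(atom.name, atom.element),
                            alt=atom.altloc or " ",
                            res=res.name,
                            chain=chain.chain_id,
                            seq=res.seq_id,
                            icode=res.insertion_code or " ",
                            x=atom.coords[0], y=atom.coords[1], z=atom.coords[2],
                            occ=atom.occupancy, b=0.0,
                            el=atom.element[:2]))
                    serial += 1
            lines.append(f"TER   {serial:5d}      {chain.residues[-1].name:>3s} "
                         f"{chain.chain_id:1s}{chain.residues[-1].seq_id:4d}")
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------


def _check_paired(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or b.ndim != 2 or b.shape[1] != 3:
        raise PairingError("coordinate sets must be (N, 3) arrays")
    if a.shape[0] != b.shape[0]:
        raise PairingError(f"coordinate sets differ in length: {a.shape[0]} vs {b.shape[0]}")
    return a, b


def rmsd_no_fit(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between paired coordinate sets without superposition."""
    a, b = _check_paired(a, b)
    if a.shape[0] == 0:
        raise PairingError("empty coordinate sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile points onto the reference in
    the least-squares sense; the rotation is always proper (det = +1).
    """
    mobile, reference = _check_paired(mobile, reference)
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 paired points to superpose")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    m = mobile - mc
    r = reference - rc
    # collinear sets leave a free rotation about the common axis
    for pts in (m, r):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] < 1e-8 * max(sv[0], 1.0):
            raise DegenerateGeometryError("superposition points are (nearly) collinear")
    h = m.T @ r
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = rc - rotation @ mc
    fitted = m @ rotation.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    """Apply ``x -> R x + t`` to an (N, 3) array."""
    return np.asarray(coords, float) @ np.asarray(rotation, float).T + \
        np.asarray(translation, float)


def superposed_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Post-fit RMSD after Kabsch superposition."""
    return kabsch_superpose(mobile, reference)[2]


# ---------------------------------------------------------------------------
# dihedrals and internal-coordinate placement
# ---------------------------------------------------------------------------


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) in (−180, 180], IUPAC convention
    (cis = 0, trans = 180)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-10:
            raise DegenerateGeometryError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear points: dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = math.degrees(math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2))))
    if angle <= -180.0:
        angle += 360.0
    return angle


def measure_angle(p1, p2, p3) -> float:
    """Bond angle at p2 in degrees."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(float(np.clip(cosang, -1.0, 1.0))))


def place_atom_nerf(p1, p2, p3, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a fourth point from three reference points and internal
    coordinates (natural extension reference frame).

    The returned point ``d`` satisfies ``|d − p3| = bond``,
    ``angle(p2, p3, d) = angle`` and ``dihedral(p1, p2, p3, d) = torsion``
    (degrees).
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p1
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise DegenerateGeometryError("collinear reference points in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        -bond * math.sin(ang) * math.sin(tor),
    ])
    return p3 + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake-Rupley)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _unit_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci
    lattice)."""
    i = np.arange(n_points, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    return pts


def _radii_for(atoms: Sequence[Atom], fallback_radius: float | None) -> np.ndarray:
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        r = VDW_RADII.get(a.element)
        if r is None:
            if fallback_radius is None:
                raise PepdockError(
                    f"no van der Waals radius for element {a.element!r} "
                    f"(atom {a.name}); pass fallback_radius to proceed")
            r = fallback_radius
        radii[i] = r
    return radii


def sasa_of_atoms(coords: np.ndarray, radii: np.ndarray,
                  indices: np.ndarray | None = None,
                  probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake–Rupley SASA (Å²) for selected atoms in the context of all
    atoms given by ``coords``/``radii``.

    ``indices`` selects the atoms whose areas are computed (default: all).
    This array-level kernel is shared by the structure-level API and by the
    docking score's incremental buried-surface computation.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    if indices is None:
        indices = np.arange(n)
    sphere = _unit_sphere(n_points)
    tree = cKDTree(coords)
    max_r = radii.max() if n else 0.0
    areas = np.zeros(len(indices))
    for k, i in enumerate(indices):
        ri = radii[i] + probe
        pts = coords[i] + ri * sphere
        neigh = tree.query_ball_point(coords[i], ri + max_r + probe)
        neigh = [j for j in neigh if j != i]
        if neigh:
            nc = coords[neigh]
            nr = radii[np.asarray(neigh)] + probe
            d2 = np.sum((pts[:, None, :] - nc[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (nr ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[k] = 4.0 * math.pi * ri * ri * frac
    return areas


def shrake_rupley_sasa(structure: Structure, probe: float = 1.4,
                       n_points: int = 960,
                       fallback_radius: float | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²) for every heavy atom of
    ``structure`` (order matches :meth:`Structure.heavy_atoms`)."""
    atoms = [a for _, _, a in structure.heavy_atoms()]
    if not atoms:
        raise EmptyStructureError("no heavy atoms for SASA computation")
    coords = np.array([a.coords for a in atoms])
    radii = _radii_for(atoms, fallback_radius)
    return sasa_of_atoms(coords, radii, probe=probe, n_points=n_points)


def residue_sasa(structure: Structure, probe: float = 1.4, n_points: int = 960,
                 fallback_radius: float | None = None
                 ) -> dict[tuple[str, int, str], float]:
    """Total heavy-atom SASA per residue, keyed by (chain, seq_id, icode)."""
    areas = shrake_rupley_sasa(structure, probe, n_points, fallback_radius)
    out: dict[tuple[str, int, str], float] = {}
    for (cid, res, _), area in zip(structure.heavy_atoms(), areas):
        key = (cid, res.seq_id, res.insertion_code)
        out[key] = out.get(key, 0.0) + float(area)
    return out


_SIDECHAIN_EXCLUDE = set(BACKBONE_ATOMS) | {"OXT"}


@lru_cache(maxsize=64)
def _reference_areas(res_name: str) -> tuple[float, float]:
    """Maximal (side-chain, backbone) SASA of residue type X in an extended
    Gly-X-Gly tripeptide built by the conformers module.

    Self-consistent with this module's SASA implementation. Glycine has no
    side chain beyond the backbone; its side-chain reference is 0.
    """
    from . import conformers

    three_to_one = {v: k for k, v in conformers.ONE_TO_THREE.items()}
    if res_name not in three_to_one:
        raise PepdockError(f"no reference accessibility for residue {res_name!r}")
    seq = "G" + three_to_one[res_name] + "G"
    pep = conformers.build_peptide(seq, conformers.TEMPLATES["extended"])
    struct = pep.structure
    center = struct.chains[0].residues[1]
    sc = bb = 0.0
    areas = shrake_rupley_sasa(struct)
    for (cid, res, atom), area in zip(struct.heavy_atoms(), areas):
        if res is center:
            if atom.name in BACKBONE_ATOMS:
                bb += float(area)
            elif atom.name not in _SIDECHAIN_EXCLUDE:
                sc += float(area)
    return sc, bb


def relative_accessibility(residue_key: tuple[str, int, str], context: Structure,
                           probe: float = 1.4, n_points: int = 960
                           ) -> tuple[float, float, bool]:
    """Relative side-chain and backbone accessibility of one residue in its
    structural context, plus the surface flag.

    A residue counts as solvent accessible when either its side chain or its
    backbone exceeds 40% relative accessibility (strictly greater).
    """
    cid, seq_id, icode = residue_key
    res = context.chain(cid).residue(seq_id, icode)
    if res is None:
        raise PairingError(f"residue {residue_key} not in structure")
    ref_sc, ref_bb = _reference_areas(res.name)
    areas = shrake_rupley_sasa(context, probe, n_points)
    sc = bb = 0.0
    for (acid, ares, atom), area in zip(context.heavy_atoms(), areas):
        if acid == cid and ares is res:
            if atom.name in BACKBONE_ATOMS:
                bb += float(area)
            elif atom.name not in _SIDECHAIN_EXCLUDE:
                sc += float(area)
    sc_rel = sc / ref_sc if ref_sc > 0 else 0.0
    bb_rel = bb / ref_bb if ref_bb > 0 else 0.0
    return sc_rel, bb_rel, (sc_rel > 0.40 or bb_rel > 0.40)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def residues_within(structure: Structure, selection_a: Selection,
                    selection_b: Selection, cutoff: float) -> Selection:
    """Residues of ``selection_a`` having any heavy atom within ``cutoff`` Å
    of any heavy atom of ``selection_b``. Hydrogens are ignored."""
    atoms_a = selection_a.atoms(structure)
    atoms_b = selection_b.atoms(structure)
    if not atoms_a or not atoms_b:
        raise PepdockError("residues_within requires non-empty selections")
    coords_a = np.array([a.coords for _, _, a in atoms_a])
    coords_b = np.array([a.coords for _, _, a in atoms_b])
    tree_b = cKDTree(coords_b)
    close = tree_b.query_ball_point(coords_a, cutoff)
    hit: list[tuple[str, int, str]] = []
    seen = set()
    for (cid, res, _), neighbours in zip(atoms_a, close):
        if neighbours:
            key = (cid, res.seq_id, res.insertion_code)
            if key not in seen:
                seen.add(key)
                hit.append(key)
    return Selection.of(hit, selection_a.atom_names)
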