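"""Deterministic toy receptor-peptide complexes for testing and demos.

Real benchmark complexes require downloads and licensing; every capability
of this toolkit is instead exercisable on synthetic complexes built here:
a poly-alanine lattice "receptor" shaped either as a slab with a snug
binding groove (the buried-peptide regime) or as a flat convex patch (the
solvent-exposed regime), with an ideal peptide conformer placed in the
binding site. The groove is closed at both ends and sized to the chosen
conformer, so the reference placement is the unique low-clash registration.

The decoy generator produces rigid perturbations of the reference peptide
whose magnitudes are calibrated (by bisection against the assessment
metrics) to land in prescribed i-RMSD strata, giving labelled ground truth
for assessment and clustering tests.

Everything is deterministic per seed, down to the PDB text written.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import conformers
from .assess import i_rmsd, interface_selection, quality_from_irmsd
from .structmodel import Atom, Chain, PepdockError, Residue, Structure

__all__ = ["FixtureSpec", "make_complex", "make_decoy_set"]

LATTICE_SPACING = 5.0  # Å between receptor residue sites
RECEPTOR_CHAIN = "A"
PEPTIDE_CHAIN = "B"


@dataclass(frozen=True)
class FixtureSpec:
    shape: str = "slab_with_groove"  # or "convex_patch"
    sequence: str = "AAAAAAAA"
    template: str = "extended"
    groove_width: float = 5.0  # Å clear width of the slot
    groove_depth: float = 5.0  # Å (one wall layer per 5 Å)
    margin: float = 8.0       # Å of slab beyond the peptide footprint
    jitter: float = 0.05       # Å random displacement of receptor atoms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("slab_with_groove", "convex_patch"):
            raise PepdockError(f"unknown fixture shape {self.shape!r}")


def _ala_unit() -> np.ndarray:
    """Coordinates of one rigid ALA residue (N, CA, C, O, CB), centred on
    its CA. Taken from the middle residue of an ideal extended build."""
    pep = conformers.build_peptide("AAA", conformers.TEMPLATES["extended"])
    res = pep.structure.chains[0].residues[1]
    ca = res.atom("CA").coords
    return np.array([res.atom(n).coords - ca for n in ("N", "CA", "C", "O", "CB")])


_ALA_NAMES = ("N", "CA", "C", "O", "CB")
_ALA_ELEMENTS = ("N", "C", "C", "O", "C")


def _oriented_peptide(spec: FixtureSpec) -> Structure:
    """Build the peptide and align its Cα axis with x, centred at the
    origin."""
    pep = conformers.build_peptide(spec.sequence,
                                   conformers.TEMPLATES[spec.template],
                                   chain_id=PEPTIDE_CHAIN)
    struct = pep.structure
    cas = np.array([r.atom("CA").coords for r in struct.chains[0].residues])
    axis = cas[-1] - cas[0]
    axis /= np.linalg.norm(axis)
    # rotation taking the long axis onto +x
    v = np.cross(axis, [1.0, 0.0, 0.0])
    s = np.linalg.norm(v)
    c = float(np.dot(axis, [1.0, 0.0, 0.0]))
    if s < 1e-9:
        rot = np.eye(3) if c > 0 else Rotation.from_rotvec(
            [0.0, np.pi, 0.0]).as_matrix()
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))
    centroid = struct.heavy_coords().mean(axis=0)
    return struct.transformed(rot, -rot @ centroid)


def make_complex(spec: FixtureSpec) -> tuple[Structure, Structure, str]:
    """Build (reference complex, receptor-only structure, peptide sequence).

    The receptor is a poly-ALA lattice slab; for ``slab_with_groove`` a
    wall layer with a closed rectangular hole wraps the peptide, for
    ``convex_patch`` the peptide simply rests on the flat face.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2718]))
    peptide = _oriented_peptide(spec)
    pep_coords = peptide.heavy_coords()
    a = LATTICE_SPACING
    x_lo, y_lo, z_lo = pep_coords.min(axis=0)
    x_hi, y_hi, z_hi = pep_coords.max(axis=0)

    # slab footprint in lattice cells
    nx = int(np.ceil((x_hi - x_lo + 2 * spec.margin) / a))
    ny = int(np.ceil((y_hi - y_lo + 2 * spec.margin) / a))
    xs = (np.arange(nx) - (nx - 1) / 2) * a
    ys = (np.arange(ny) - (ny - 1) / 2) * a

    # peptide sits just above the base layer; sites carry an optional fixed
    # orientation (groove-lining residues point their CB away from the slot
    # so the slot width is controlled, everything else is randomly oriented)
    base_z = z_lo - 4.5
    sites: list[tuple[np.ndarray, float | None]] = []
    for x in xs:
        for y in ys:
            sites.append((np.array([x, y, base_z]), None))
            sites.append((np.array([x, y, base_z - a]), None))  # second base layer
    if spec.shape == "slab_with_groove":
        n_layers = max(1, int(round(spec.groove_depth / a)))
        half_w = spec.groove_width / 2.0 + a / 2.0
        hole_x = (x_lo - a * 0.8, x_hi + a * 0.8)
        for layer in range(1, n_layers + 1):
            z = base_z + layer * a
            for x in xs:
                for y in ys:
                    inside_hole = (hole_x[0] - a / 2 < x < hole_x[1] + a / 2
                                   and abs(y) < half_w)
                    if inside_hole:
                        continue
                    lining = abs(y) < half_w + a  # first wall row
                    orient = (np.pi / 2 if y > 0 else -np.pi / 2) \
                        if lining else None
                    sites.append((np.array([x, y, z]), orient))

    unit = _ala_unit()
    residues = []
    for i, (site, orient) in enumerate(sites):
        # deterministic per-site orientation: fixed for groove lining,
        # random (via the seeded rng) elsewhere
        angle = rng.uniform(0, 2 * np.pi)
        if orient is not None:
            angle = orient
        rot = Rotation.from_euler("z", angle).as_matrix()
        coords = unit @ rot.T + site + rng.normal(scale=spec.jitter, size=3)
        atoms = [Atom(n, el, coords[k].copy())
                 for k, (n, el) in enumerate(zip(_ALA_NAMES, _ALA_ELEMENTS))]
        residues.append(Residue("ALA", i + 1, "", atoms))
    receptor = Structure([Chain(RECEPTOR_CHAIN, residues)],
                         source=f"fixture:{spec.shape}")

    # steric sanity: groove must be wide enough for the chosen conformer
    from scipy.spatial import cKDTree

    rec_coords = receptor.heavy_coords()
    dmin = cKDTree(rec_coords).query(pep_coords)[0].min()
    if dmin < 1.8:
        raise PepdockError(
            f"groove too narrow for the {spec.template} conformer "
            f"(closest receptor-peptide approach {dmin:.2f} Å)")
    complex_ref = receptor.merged_with(peptide)
    # invariant: the peptide must actually touch the receptor
    d5 = (cKDTree(rec_coords).query(pep_coords)[0] < 5.0).any()
    if not d5:
        raise PepdockError("fixture peptide does not contact the receptor")
    return complex_ref, receptor, spec.sequence


def _perturbed_model(reference: Structure, rotation: np.ndarray,
                     translation: np.ndarray) -> Structure:
    """Reference complex with the rigid perturbation applied to the peptide
    chain about its centroid."""
    chain = reference.chain(PEPTIDE_CHAIN)
    coords = np.array([a.coords for r in chain.residues for a in r.atoms])
    centroid = coords.mean(axis=0)
    t = centroid - rotation @ centroid + translation
    return reference.transformed(rotation, t, chain_ids=[PEPTIDE_CHAIN])


def make_decoy_set(reference: Structure, counts: dict[str, int], seed: int,
                   receptor_chain: str = RECEPTOR_CHAIN,
                   peptide_chain: str = PEPTIDE_CHAIN
                   ) -> list[tuple[Structure, str, float]]:
    """Labelled decoys in prescribed quality strata.

    ``counts`` maps stratum labels (``high``, ``near_native``,
    ``not_acceptable``) to the number of decoys wanted. Each decoy is a
    random rigid perturbation of the reference peptide whose magnitude is
    bisected until the i-RMSD lands at a stratum-interior target. Returns
    ``(model, label, i_rmsd)`` triples.
    """
    targets = {"high": 0.5, "near_native": 1.5, "not_acceptable": 4.0}
    bad = set(counts) - set(targets)
    if bad:
        raise PepdockError(f"unknown strata {sorted(bad)}")
    interfaces = interface_selection(reference, receptor_chain, peptide_chain)
    out: list[tuple[Structure, str, float]] = []
    k = 0
    for label, n in counts.items():
        target = targets[label]
        for _ in range(n):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 31, k]))
            k += 1
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)

            def irmsd_at(s: float) -> float:
                rot = Rotation.from_rotvec(axis * np.radians(8.0 * s)).as_matrix()
                model = _perturbed_model(reference, rot, direction * s)
                return i_rmsd(model, reference, interfaces)

            s_hi = 0.5
            while irmsd_at(s_hi) < target and s_hi < 64:
                s_hi *= 2.0
            s_lo = 0.0
            for _ in range(40):
                mid = 0.5 * (s_lo + s_hi)
                if irmsd_at(mid) < target:
                    s_lo = mid
                else:
                    s_hi = mid
            s = 0.5 * (s_lo + s_hi)
            rot = Rotation.from_rotvec(axis * np.radians(8.0 * s)).as_matrix()
            model = _perturbed_model(reference, rot, direction * s)
            achieved = i_rmsd(model, reference, interfaces)
            if quality_from_irmsd(achieved) != label:
                raise PepdockError(
                    f"decoy calibration failed: wanted {label}, "
                    f"i-RMSD {achieved:.3f}")
            out.append((model, label, achieved))
    return out
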