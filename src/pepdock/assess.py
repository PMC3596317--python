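"""CAPRI-style quality assessment adapted to protein-peptide complexes.

Models are compared with a reference complex through four metrics:

* i-RMSD — backbone RMSD over the interface residues of *both* molecules
  (reference-defined, 10 Å), after fitting on those same atoms;
* l-RMSD — peptide backbone RMSD after fitting on the full receptor
  backbone;
* l-i-RMSD — peptide-interface backbone RMSD after fitting on the
  receptor-interface backbone (insensitive to receptor flexibility);
* Fnat — fraction of reference residue-residue contacts (any heavy-atom
  pair within 5 Å) reproduced by the model.

Because peptide interfaces are small, the quality classes are stricter than
in protein-protein assessment: high quality (sub-angstrom) at
i-RMSD ≤ 1 Å, near-native at 1 < i-RMSD ≤ 2 Å, not acceptable above 2 Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structmodel import (
    BACKBONE_ATOMS,
    PairingError,
    PepdockError,
    Selection,
    Structure,
    apply_transform,
    chain_selection,
    kabsch_superpose,
    residues_within,
    rmsd_no_fit,
)

__all__ = [
    "QualityReport",
    "interface_selection",
    "i_rmsd",
    "l_rmsd",
    "l_i_rmsd",
    "fnat",
    "quality_from_irmsd",
    "assess_model",
    "success_curve",
    "ACCEPTABLE_QUALITIES",
]

ACCEPTABLE_QUALITIES = ("high", "near_native")


@dataclass(frozen=True)
class QualityReport:
    i_rmsd: float
    l_rmsd: float
    l_i_rmsd: float
    fnat: float
    quality: str  # high | near_native | not_acceptable
    model_id: int = -1

    @property
    def acceptable(self) -> bool:
        return self.quality in ACCEPTABLE_QUALITIES


def quality_from_irmsd(value: float) -> str:
    """CAPRI-style class from i-RMSD with inclusive 1 and 2 Å boundaries."""
    if value <= 1.0:
        return "high"
    if value <= 2.0:
        return "near_native"
    return "not_acceptable"


def interface_selection(reference: Structure, receptor_chain: str,
                        peptide_chain: str, cutoff: float = 10.0
                        ) -> tuple[Selection, Selection]:
    """Both-sided interface residue selections, always defined from the
    reference complex (never from a model) and reused for every model of a
    case."""
    rec_sel = chain_selection(reference, receptor_chain)
    pep_sel = chain_selection(reference, peptide_chain)
    rec_iface = residues_within(reference, rec_sel, pep_sel, cutoff)
    pep_iface = residues_within(reference, pep_sel, rec_sel, cutoff)
    if len(rec_iface) == 0 or len(pep_iface) == 0:
        raise PepdockError("empty interface in reference complex")
    return rec_iface, pep_iface


def _paired_coords(model: Structure, reference: Structure,
                   selection: Selection,
                   atom_names: tuple[str, ...] = BACKBONE_ATOMS
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Backbone coordinates of the selected residues paired model ↔
    reference by (chain, seq_id, insertion_code, atom name)."""
    pm, pr, missing = [], [], []
    for cid, seq_id, icode in selection.triples:
        res_r = reference.chain(cid).residue(seq_id, icode)
        try:
            res_m = model.chain(cid).residue(seq_id, icode)
        except KeyError:
            res_m = None
        if res_m is None:
            missing.append((cid, seq_id, icode))
            continue
        for name in atom_names:
            ar = res_r.atom(name) if res_r else None
            am = res_m.atom(name)
            if ar is not None and am is not None:
                pm.append(am.coords)
                pr.append(ar.coords)
    if missing:
        raise PairingError(f"model lacks reference residues: {missing}")
    if not pm:
        raise PairingError("no paired backbone atoms for selection")
    return np.array(pm), np.array(pr)


def i_rmsd(model: Structure, reference: Structure,
           interfaces: tuple[Selection, Selection]) -> float:
    """Interface backbone RMSD: Kabsch fit on the pooled two-sided
    interface backbone, RMSD over the same atoms."""
    rec_iface, pep_iface = interfaces
    pm_r, pr_r = _paired_coords(model, reference, rec_iface)
    pm_p, pr_p = _paired_coords(model, reference, pep_iface)
    pm = np.vstack([pm_r, pm_p])
    pr = np.vstack([pr_r, pr_p])
    return kabsch_superpose(pm, pr)[2]


def l_rmsd(model: Structure, reference: Structure, receptor_chain: str,
           peptide_chain: str) -> float:
    """Ligand RMSD: fit on all receptor backbone atoms, then peptide
    backbone RMSD without a second fit."""
    rec_sel = chain_selection(reference, receptor_chain)
    pep_sel = chain_selection(reference, peptide_chain)
    rm, rr = _paired_coords(model, reference, rec_sel)
    rot, trans, _ = kabsch_superpose(rm, rr)
    pm, pr = _paired_coords(model, reference, pep_sel)
    return rmsd_no_fit(apply_transform(pm, rot, trans), pr)


def l_i_rmsd(model: Structure, reference: Structure,
             interfaces: tuple[Selection, Selection]) -> float:
    """Ligand-interface RMSD: fit on the receptor-interface backbone, RMSD
    over the peptide-interface backbone."""
    rec_iface, pep_iface = interfaces
    rm, rr = _paired_coords(model, reference, rec_iface)
    rot, trans, _ = kabsch_superpose(rm, rr)
    pm, pr = _paired_coords(model, reference, pep_iface)
    return rmsd_no_fit(apply_transform(pm, rot, trans), pr)


def _contacts(structure: Structure, receptor_chain: str, peptide_chain: str,
              cutoff: float) -> set[tuple]:
    rec_atoms = chain_selection(structure, receptor_chain).atoms(structure)
    pep_atoms = chain_selection(structure, peptide_chain).atoms(structure)
    rc = np.array([a.coords for _, _, a in rec_atoms])
    pc = np.array([a.coords for _, _, a in pep_atoms])
    tree = cKDTree(pc)
    pairs = set()
    for i, neigh in enumerate(tree.query_ball_point(rc, cutoff)):
        _, res_r, _ = rec_atoms[i]
        for j in neigh:
            _, res_p, _ = pep_atoms[j]
            pairs.add(((receptor_chain, res_r.seq_id, res_r.insertion_code),
                       (peptide_chain, res_p.seq_id, res_p.insertion_code)))
    return pairs


def fnat(model: Structure, reference: Structure, receptor_chain: str,
         peptide_chain: str, contact_cutoff: float = 5.0) -> float:
    """Fraction of native receptor-peptide residue contacts (heavy atoms
    within ``contact_cutoff``) present in the model."""
    native = _contacts(reference, receptor_chain, peptide_chain, contact_cutoff)
    if not native:
        raise PepdockError("reference complex has no native contacts")
    modeled = _contacts(model, receptor_chain, peptide_chain, contact_cutoff)
    return len(native & modeled) / len(native)


def assess_model(model: Structure, reference: Structure, receptor_chain: str,
                 peptide_chain: str,
                 interfaces: tuple[Selection, Selection] | None = None,
                 model_id: int = -1) -> QualityReport:
    """All four metrics plus the quality class for one model."""
    if interfaces is None:
        interfaces = interface_selection(reference, receptor_chain,
                                         peptide_chain)
    irmsd = i_rmsd(model, reference, interfaces)
    return QualityReport(
        i_rmsd=irmsd,
        l_rmsd=l_rmsd(model, reference, receptor_chain, peptide_chain),
        l_i_rmsd=l_i_rmsd(model, reference, interfaces),
        fnat=fnat(model, reference, receptor_chain, peptide_chain),
        quality=quality_from_irmsd(irmsd),
        model_id=model_id,
    )


def success_curve(cases: list[list[QualityReport]],
                  n_values: list[int]) -> dict[int, float]:
    """Fraction of cases with at least one acceptable model in the top N,
    for each N. Each case is a score-ranked report list; the curve is
    monotone non-decreasing in N."""
    out = {}
    for n in n_values:
        hits = 0
        for reports in cases:
            if any(r.acceptable for r in reports[:n]):
                hits += 1
        out[n] = hits / len(cases) if cases else 0.0
    return out
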