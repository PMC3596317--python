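"""Shared fixtures: synthetic complexes, restraints and ensembles.

Everything is generated programmatically (no data files); session scope is
used for the expensive objects so the suite builds each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from pepdock import (
    FixtureSpec,
    canonical_ensemble,
    define_airs,
    interface_selection,
    make_complex,
)

RECEPTOR_CHAIN = "A"
PEPTIDE_CHAIN = "B"


@pytest.fixture(scope="session")
def groove_case():
    """Easy docking case: extended 8-mer in a snug closed groove."""
    spec = FixtureSpec(shape="slab_with_groove", sequence="AAAAAAAA",
                       template="extended", seed=1)
    complex_ref, receptor, sequence = make_complex(spec)
    return {
        "spec": spec,
        "complex": complex_ref,
        "receptor": receptor,
        "sequence": sequence,
        "airs": define_airs(complex_ref, RECEPTOR_CHAIN, PEPTIDE_CHAIN),
        "interfaces": interface_selection(complex_ref, RECEPTOR_CHAIN,
                                          PEPTIDE_CHAIN),
        "ensemble": canonical_ensemble(sequence, chain_id=PEPTIDE_CHAIN),
    }


@pytest.fixture(scope="session")
def patch_case():
    """Exposed-peptide case: peptide resting on a flat convex patch."""
    spec = FixtureSpec(shape="convex_patch", sequence="AAAAAAAA",
                       template="extended", seed=2)
    complex_ref, receptor, sequence = make_complex(spec)
    return {"spec": spec, "complex": complex_ref, "receptor": receptor,
            "sequence": sequence}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


MINIMAL_ALA_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.152  -4.950  1.00  0.00           C
ATOM      4  O   ALA A   1      13.560   7.342  -5.806  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.247   4.676  -4.898  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BSER A   1       1.458   1.000   0.000  0.40  0.00           C
ATOM      4  C   SER A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      5  O   SER A   1       1.251   2.390   0.000  1.00  0.00           O
HETATM    6  O   HOH A 101       8.000   8.000   8.000  1.00  0.00           O
END
"""
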