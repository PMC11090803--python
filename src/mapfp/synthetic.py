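"""Synthetic molecule generators for property tests and calibration plots.

``random_chiral_molecules`` emulates a drug-like chemical-space sample for
the chiral-shingle-fraction analysis: random branched C/N/O skeletons of
10-50 heavy atoms with an occasional ring, all potential tetrahedral
centers assigned to random configurations.  It spans a wide range of
chiral-atom fractions, which is what the correlation analysis needs; it
does not emulate aromatic ring systems, charge states or the functional
group distribution of real screening libraries.

``CONSTITUTIONAL_ISOMERS_DIAMINOCYCLOHEXANE`` is a small hand-written set
of C6H14N2 constitutional isomers standing in for database-derived isomer
lists in the stereoisomer-vs-structural-isomer distance analyses.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

from .chem_io import stereo_centers

# C6H14N2 constitutional isomers around the 1,4-diaminocyclohexane scaffold
CONSTITUTIONAL_ISOMERS_DIAMINOCYCLOHEXANE = (
    "NC1CCC(N)CC1",        # 1,4-diaminocyclohexane
    "NC1CCCC(N)C1",        # 1,3-diaminocyclohexane
    "NC1CCCCC1N",          # 1,2-diaminocyclohexane
    "NCC1CCCC1N",          # 2-(aminomethyl)cyclopentan-1-amine
    "NCC1CCC(N)C1",        # 3-(aminomethyl)cyclopentan-1-amine
    "NCC1CCCC1CN",         # cyclopentane-1,2-diyldimethanamine precursor isomer
    "CC1CCC(CN)C1N",       # methyl/aminomethyl cyclopentane diamine
    "NCCC1CCC1CN",         # cyclobutane-based diamine
    "CC1(N)CCC(N)CC1",     # 1-methyl-1,4-diaminocyclohexane ring-contracted homolog
    "NC1(CN)CCCC1",        # 1-(aminomethyl)cyclopentan-1-amine
)

_ELEMENTS = ("C", "C", "C", "C", "C", "N", "O")  # ~70 % carbon
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2}


def _random_skeleton(rng: np.random.Generator, n_atoms: int) -> Chem.Mol | None:
    mol = Chem.RWMol()
    symbols = []
    for index in range(n_atoms):
        symbol = _ELEMENTS[rng.integers(len(_ELEMENTS))] if index else "C"
        symbols.append(symbol)
        mol.AddAtom(Chem.Atom(symbol))
        if index == 0:
            continue
        # attach to a random earlier atom with spare valence
        candidates = [
            j for j in range(index)
            if mol.GetAtomWithIdx(j).GetDegree() < _MAX_VALENCE[symbols[j]]
        ]
        if not candidates:
            return None
        parent = candidates[rng.integers(len(candidates))]
        mol.AddBond(parent, index, Chem.BondType.SINGLE)
    # occasional ring closure between degree-compatible atoms
    if n_atoms > 6 and rng.random() < 0.6:
        open_atoms = [
            j for j in range(n_atoms)
            if mol.GetAtomWithIdx(j).GetDegree() < _MAX_VALENCE[symbols[j]] - 1
        ]
        if len(open_atoms) >= 2:
            rng.shuffle(open_atoms)
            first = open_atoms[0]
            partners = [
                b for b in open_atoms[1:]
                if not mol.GetBondBetweenAtoms(first, b)
            ]
            if partners:
                mol.AddBond(first, partners[0], Chem.BondType.SINGLE)
    candidate = mol.GetMol()
    try:
        Chem.SanitizeMol(candidate)
    except Exception:
        return None
    return candidate


def random_chiral_molecules(
    n: int, seed: int = 0, min_heavy: int = 10, max_heavy: int = 50,
) -> list[str]:
    """n random chiral molecules with every potential center defined.

    Each molecule has 10-50 heavy atoms and at least one defined
    tetrahedral stereocenter; configurations are drawn uniformly.
    Returns canonical isomeric SMILES.
    """
    rng = np.random.default_rng(seed)
    tags = (Chem.ChiralType.CHI_TETRAHEDRAL_CW, Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
    out: list[str] = []
    while len(out) < n:
        n_atoms = int(rng.integers(min_heavy, max_heavy + 1))
        skeleton = _random_skeleton(rng, n_atoms)
        if skeleton is None:
            continue
        centers = stereo_centers(skeleton)
        if not centers:
            continue
        editable = Chem.RWMol(skeleton)
        for center in centers:
            editable.GetAtomWithIdx(center.atom_index).SetChiralTag(
                tags[rng.integers(2)]
            )
        candidate = editable.GetMol()
        Chem.AssignStereochemistry(candidate, cleanIt=True, force=True)
        if not any(c.defined for c in stereo_centers(candidate)):
            continue
        out.append(Chem.MolToSmiles(candidate))
    return out
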