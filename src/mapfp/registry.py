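"""Registry of the stereochemically complex benchmark molecules.

Fourteen carbohydrates, peptides and macrocyclic natural products with 5-16
tetrahedral stereocenters and internal rotational symmetries up to C7, used
throughout the stereoisomer-distinction analyses.  Carbohydrates and
peptides are built from standard literature structures (peptides through
:mod:`mapfp.peptides`); every entry is validated in the test suite against
its published stereocenter count and, via full enumeration, its published
stereoisomer total.

Two entries are synthetic surrogates, not transcriptions: the exact
structures of the C2-symmetric depsipeptides quinaldopeptin and onchidin
were not available to this package, so the registry stores synthetic
C2-symmetric cyclic peptides with the same stereocenter count (8 and 12)
and the same rotational symmetry class, which is what the symmetry-counting
analyses exercise.  ln65 is a representative 7xLys/4xLeu undecapeptide
(the published sequence composition gives the same 330 sequence scrambles).
"""

from __future__ import annotations

from .peptides import D, L, PeptideSpec, peptide_smiles

# 6-methylheptanoyl: the achiral acyl group of polymyxin B2
_PMB2_CAP = "CC(C)CCCCC(=O)"


def polymyxin_b2_spec() -> PeptideSpec:
    """Polymyxin B2: acyl-Dab-Thr-Dab-cyclo[Dab-Dab-DPhe-Leu-Dab-Dab-Thr].

    The side-chain amine of the fourth residue (branching Dab) closes the
    heptapeptide lactam ring onto the C-terminal threonine.  12 stereocenters:
    10 alpha carbons plus the two threonine side chains.
    """
    residues = [
        ("Dab", L), ("T", L), ("Dab", L),
        ("Dab", L),  # branch point
        ("Dab", L), ("F", D), ("L", L), ("Dab", L), ("Dab", L), ("T", L),
    ]
    return PeptideSpec(
        sequence=tuple(residues),
        fixed_positions=frozenset({3}),  # the branching Dab stays in place
        topology="branched:3",
        n_term_cap=_PMB2_CAP,
    )


def ln65_spec() -> PeptideSpec:
    """Representative Lys/Leu undecapeptide (synthetic stand-in for ln65)."""
    return PeptideSpec.from_string("KLLKKLKKLKK", L)


_SUGARS = {
    # alpha-D-glucopyranose, 5 stereocenters
    "alpha-d-glucopyranose": "OC[C@H]1O[C@H](O)[C@H](O)[C@@H](O)[C@@H]1O",
    # beta-lactose: Gal-beta(1->4)-Glc, 10 stereocenters
    "lactose": ("OC[C@H]1O[C@@H](O[C@H]2[C@H](O)[C@@H](O)[C@@H](O)O[C@@H]2CO)"
                "[C@H](O)[C@@H](O)[C@H]1O"),
    # alpha,alpha-trehalose: C2-symmetric non-reducing diglucoside, 10 centers
    "trehalose": ("OC[C@H]1O[C@H](O[C@H]2O[C@H](CO)[C@@H](O)[C@H](O)[C@H]2O)"
                  "[C@H](O)[C@@H](O)[C@@H]1O"),
    # validamycin A: beta-D-glucosyl validoxylamine, 14 centers
    "validamycin-a": ("OC[C@H]1O[C@@H](O[C@H]2[C@@H](O)[C@H](O)[C@@H](CO)C"
                      "[C@H]2N[C@H]2C=C(CO)[C@@H](O)[C@H](O)[C@H]2O)"
                      "[C@H](O)[C@@H](O)[C@@H]1O"),
    # myo-inositol, 6 potential centers, 9 stereoisomers of the parent scaffold
    "inositol": "O[C@@H]1[C@H](O)[C@@H](O)[C@@H](O)[C@H](O)[C@H]1O",
}


def _cyclic(sequence, flags) -> str:
    return peptide_smiles(PeptideSpec.from_string(sequence, flags, topology="cyclic"))


def _valinomycin() -> str:
    # cyclo[-(D-Val - L-Lac - L-Val - D-Hiv)3-], C3 symmetric, 12 centers
    d_val = "N[C@H](C(C)C)C(=O)"
    l_lac = "O[C@@H](C)C(=O)"
    l_val = "N[C@@H](C(C)C)C(=O)"
    d_hiv = "O[C@H](C(C)C)C(=O)"
    unit = d_val + l_lac + l_val + d_hiv
    body = unit * 3
    return "N%99" + body[1:-5] + "C%99=O"


def _nonactin() -> str:
    # macrotetrolide of nonactic acid, (+)(-)(+)(-) alternation, C4 skeleton,
    # 16 stereocenters (4 per monomer unit)
    plus = "O[C@@H](C)C[C@H]%91CC[C@@H](O%91)[C@@H](C)C(=O)"
    minus = "O[C@H](C)C[C@@H]%92CC[C@H](O%92)[C@H](C)C(=O)"
    body = (plus + minus + plus.replace("%91", "%93") + minus.replace("%92", "%94"))
    return "O%99" + body[1:-5] + "C%99=O"


def _quinaldopeptin_surrogate() -> str:
    # synthetic C2-symmetric cyclic decapeptide surrogate: 8 stereocenters
    return _cyclic("GVSAP" * 2, [L, L, D, L, L] * 2)


def _onchidin_surrogate() -> str:
    # synthetic C2-symmetric cyclic depsipeptide surrogate: 12 stereocenters
    l_lac = "O[C@@H](C)C(=O)"
    half = (peptide_smiles(PeptideSpec.from_string("V", L))[:-1]  # strip acid O
            + l_lac
            + peptide_smiles(PeptideSpec.from_string("ATPG", L))[:-1])
    body = half * 2
    return "N%99" + body[1:-5] + "C%99=O"


def _gramicidin_s() -> str:
    # cyclo(-Val-Orn-Leu-DPhe-Pro-)2, C2 symmetric, 10 alpha stereocenters
    seq = [("V", L), ("Orn", L), ("L", L), ("F", D), ("P", L)] * 2
    return peptide_smiles(PeptideSpec(sequence=tuple(seq), topology="cyclic"))


_REGISTRY: dict[str, str] | None = None

#: Entries that are synthetic surrogates rather than literature structures.
SURROGATES = frozenset({"quinaldopeptin", "onchidin", "ln65"})


def fixture_registry() -> dict[str, str]:
    """Mapping of compound name to SMILES for the 14 benchmark molecules."""
    global _REGISTRY
    if _REGISTRY is None:
        reg = dict(_SUGARS)
        reg["polymyxin-b2"] = peptide_smiles(polymyxin_b2_spec())
        reg["ln65"] = peptide_smiles(ln65_spec())
        reg["nona-arginine"] = peptide_smiles(PeptideSpec.from_string("R" * 9, L))
        reg["np213"] = _cyclic("R" * 7, L)
        reg["gramicidin-s"] = _gramicidin_s()
        reg["valinomycin"] = _valinomycin()
        reg["nonactin"] = _nonactin()
        reg["quinaldopeptin"] = _quinaldopeptin_surrogate()
        reg["onchidin"] = _onchidin_surrogate()
        _REGISTRY = reg
    return dict(_REGISTRY)


def get_fixture(name: str) -> str:
    """SMILES of a registry compound; name matching is case/space tolerant."""
    key = name.strip().lower().replace(" ", "-").replace("_", "-")
    registry = fixture_registry()
    if key not in registry:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(registry)}")
    return registry[key]
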