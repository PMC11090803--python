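"""Chiral atom-pair shingle generation — the core of the MAPC fingerprints.

A *shingle* encodes one pair of circular substructures together with the
shortest topological distance (in bonds) between their central atoms::

    substructure 1 | distance | substructure 2

Substructures are the bond environments of radius 1..max_radius around each
heavy atom, serialized as rooted canonical SMILES (the first atom token of
the string is the central atom).  Tetrahedral marks are removed from the
substructure strings; cis/trans marks are kept only when the entire double
bond, including both stereo-defining neighbours, lies inside the
substructure.  Chirality enters through the root token: at the largest
radius considered, when the central atom is a stereocenter, its atom token
is replaced by the whole-molecule CIP descriptor bracketed by dollar signs
(``$R$``, ``$S$``, ``$r$``, ``$s$``) or by ``$?$`` when the configuration is
not specified.  Because only root tokens are labelled, a configuration
change at one atom perturbs a small, local fraction of the shingle set, so
stereoisomers stay much closer to each other than constitutional isomers
while remaining distinguishable.

Variant naming follows the largest *diameter* in bonds: MAP2C/MAP4C/MAP6C
use max_radius 1/2/3.  With ``chiral=False`` the construction reduces to the
achiral MAP fingerprint of the corresponding diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolops

from .chem_io import MoleculeRecord, StereoCenter, as_mol, stereo_centers
from .errors import DisconnectedError, FormatError, TooSmallError

#: Marker object distinguishing "no environment of exactly this radius".
ABSENT = None

_VARIANTS = {
    "map2c": (1, True),
    "map4c": (2, True),
    "map6c": (3, True),
    "map2": (1, False),
    "map4": (2, False),
    "map6": (3, False),
}


@dataclass(frozen=True)
class FPConfig:
    """Fingerprint configuration.

    Parameters
    ----------
    max_radius : int
        Largest substructure radius in bonds (diameter = 2 * max_radius).
        1, 2 and 3 correspond to the named variants MAP2(C), MAP4(C) and
        MAP6(C).
    n_permutations : int
        Number of MinHash components k (fingerprint length).
    seed : int
        Seed of the hash family; part of the fingerprint identity.
    chiral : bool
        Whether stereocenter root tokens are CIP-labelled.
    """

    max_radius: int = 2
    n_permutations: int = 2048
    seed: int = 42
    chiral: bool = True

    def __post_init__(self) -> None:
        if self.max_radius < 1:
            raise ValueError("max_radius must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be > 0")

    @classmethod
    def from_variant(cls, variant: str, n_permutations: int = 2048,
                     seed: int = 42) -> "FPConfig":
        try:
            radius, chiral = _VARIANTS[variant.lower()]
        except KeyError:
            raise ValueError(
                f"unknown variant {variant!r}; expected one of {sorted(_VARIANTS)}"
            ) from None
        return cls(max_radius=radius, n_permutations=n_permutations,
                   seed=seed, chiral=chiral)

    @property
    def variant(self) -> str:
        names = {1: "map2", 2: "map4", 3: "map6"}
        base = names.get(self.max_radius, f"map{2 * self.max_radius}")
        return base + ("c" if self.chiral else "")


@dataclass(frozen=True)
class ShingleSet:
    """The set of shingle strings of one molecule under one configuration."""

    shingles: frozenset[str]
    config: FPConfig
    n_chiral: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "n_chiral", sum(1 for s in self.shingles if "$" in s)
        )

    def __len__(self) -> int:
        return len(self.shingles)


def topological_distance_matrix(mol_like) -> np.ndarray:
    """All-pairs shortest path lengths in bonds between heavy atoms.

    Raises :class:`DisconnectedError` for multi-fragment inputs.
    """
    mol = as_mol(mol_like)
    dm = Chem.GetDistanceMatrix(mol)
    n = mol.GetNumAtoms()
    if np.any(dm > n):  # RDKit marks unreachable pairs with 1e8
        raise DisconnectedError("disconnected input: some atom pairs are unreachable")
    return dm.astype(np.int64)


def circular_substructure(mol_like, center: int, radius: int):
    """Rooted substructure SMILES of the exact-radius environment, or ABSENT.

    The returned string is the canonical SMILES of all bonds within
    ``radius`` bonds of ``center``, written rooted at the center (first atom
    token).  Tetrahedral marks are stripped before canonicalization;
    directional bond marks survive only if the double bond they qualify lies
    entirely inside the substructure.  Returns :data:`ABSENT` when the
    molecule has no environment of exactly that radius around the center
    (e.g. ethane at radius 2).
    """
    mol = as_mol(mol_like)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if not 0 <= center < mol.GetNumAtoms():
        raise IndexError(f"atom index {center} out of range")
    return _substructure(mol, center, radius, strip_dirs=_has_bond_dirs(mol))


def _has_bond_dirs(mol: Chem.Mol) -> bool:
    return any(b.GetBondDir() != Chem.BondDir.NONE for b in mol.GetBonds())


def _substructure(mol, center: int, radius: int, strip_dirs: bool):
    env = rdmolops.FindAtomEnvironmentOfRadiusN(mol, radius, center)
    if not env:
        return ABSENT
    atom_map: dict[int, int] = {}
    sub = Chem.PathToSubmol(mol, env, atomMap=atom_map)
    for atom in sub.GetAtoms():
        if atom.GetChiralTag() == Chem.ChiralType.CHI_UNSPECIFIED:
            continue
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
        # stereo bracket atoms carry their H explicitly ([C@@H]); fold it
        # back to implicit so the string matches an achiral parse
        if atom.GetNumExplicitHs():
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
    sub.UpdatePropertyCache(strict=False)
    if strip_dirs:
        _strip_dangling_bond_dirs(sub)
    return Chem.MolToSmiles(sub, rootedAtAtom=atom_map[center])


def _strip_dangling_bond_dirs(sub: Chem.Mol) -> None:
    """Remove /\\ marks not attached to a fully included stereo double bond."""
    keep: set[int] = set()
    for bond in sub.GetBonds():
        if bond.GetStereo() != Chem.BondStereo.STEREONONE:
            for atom in (bond.GetBeginAtom(), bond.GetEndAtom()):
                for neighbour_bond in atom.GetBonds():
                    keep.add(neighbour_bond.GetIdx())
    for bond in sub.GetBonds():
        if bond.GetBondDir() != Chem.BondDir.NONE and bond.GetIdx() not in keep:
            bond.SetBondDir(Chem.BondDir.NONE)


_TWO_LETTER = ("Cl", "Br")
_ORGANIC_SINGLE = frozenset("BCNOPSFIbcnops")


def apply_chiral_label(sub: str, label: str) -> str:
    """Replace the root atom token of a rooted substructure SMILES by $CIP$.

    ``label`` is one of R, S, r, s or ``?`` (undefined).  Ring-closure
    digits and everything after the root token are preserved.
    """
    if not sub:
        raise FormatError("empty substructure string")
    if sub[0] == "[":
        end = sub.find("]")
        if end < 0:
            raise FormatError(f"unterminated bracket atom in {sub!r}")
        return f"${label}$" + sub[end + 1:]
    if sub[:2] in _TWO_LETTER:
        return f"${label}$" + sub[2:]
    if sub[0] in _ORGANIC_SINGLE:
        return f"${label}$" + sub[1:]
    raise FormatError(f"no leading atom token in {sub!r}")


def compute_shingles(mol_like, config: FPConfig | None = None) -> ShingleSet:
    """The shingle set of a molecule.

    For every radius r = 1..max_radius, every unordered pair of distinct
    atoms whose exact-radius-r environments both exist contributes one
    shingle "subA|d|subB" with the two substructure strings sorted
    lexicographically and d the topological distance of the two centers.
    When ``config.chiral`` is set, root tokens of stereocenters are
    CIP-labelled at the largest radius only.  Duplicates collapse (set
    semantics).
    """
    config = config or FPConfig()
    mol = as_mol(mol_like)
    n = mol.GetNumAtoms()
    if mol.GetNumHeavyAtoms() < 2:
        raise TooSmallError("need at least 2 heavy atoms to form an atom pair")
    dm = topological_distance_matrix(mol)
    labels: dict[int, str] = {}
    if config.chiral:
        labels = {c.atom_index: c.label for c in stereo_centers(mol)}

    strip_dirs = _has_bond_dirs(mol)
    shingles: set[str] = set()
    for radius in range(1, config.max_radius + 1):
        subs: list[str | None] = []
        for i in range(n):
            s = _substructure(mol, i, radius, strip_dirs)
            if s is not ABSENT and radius == config.max_radius and i in labels:
                s = apply_chiral_label(s, labels[i])
            subs.append(s)
        for i in range(n):
            si = subs[i]
            if si is ABSENT:
                continue
            row = dm[i]
            for j in range(i + 1, n):
                sj = subs[j]
                if sj is ABSENT:
                    continue
                a, b = (si, sj) if si <= sj else (sj, si)
                shingles.add(f"{a}|{row[j]}|{b}")
    return ShingleSet(shingles=frozenset(shingles), config=config)


def chiral_shingle_fraction(shingle_set: ShingleSet) -> float:
    """Fraction of shingles carrying at least one $CIP$ (or $?$) root token."""
    if len(shingle_set) == 0:
        raise TooSmallError("empty shingle set")
    return shingle_set.n_chiral / len(shingle_set)
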