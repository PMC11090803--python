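"""Combinatorial stereo and sequence enumeration.

Stereoisomers are generated by assigning every potential tetrahedral
stereocenter of the parent scaffold to each of its configurations,
canonicalizing the resulting isomeric SMILES, and removing duplicates.
Canonical-SMILES deduplication performs the symmetry quotient: for a
scaffold with a rotational symmetry group the number of unique strings
equals the Burnside orbit count (e.g. 2^10 -> 528 for a C2-symmetric
disaccharide), which the test suite cross-checks by direct Burnside
arithmetic.

Three-state enumeration additionally allows each center to be left
undefined (no tetrahedral mark), modelling stereorandomized synthesis with
racemic building blocks at chosen positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from sympy.utilities.iterables import multiset_permutations

from .chem_io import as_mol
from .errors import TooManyCentersError
from .peptides import AMINO_ACIDS_20, L, PeptideSpec, peptide_smiles
from .registry import fixture_registry, get_fixture  # re-exported (spec module surface)

__all__ = [
    "EnumerationResult", "enumerate_stereoisomers", "enumerate_three_state",
    "scramble_sequence", "generate_peptide_benchmark", "PeptideScreenSet",
    "fixture_registry", "get_fixture",
]

_CW = Chem.ChiralType.CHI_TETRAHEDRAL_CW
_CCW = Chem.ChiralType.CHI_TETRAHEDRAL_CCW
_NONE = Chem.ChiralType.CHI_UNSPECIFIED


@dataclass(frozen=True)
class EnumerationResult:
    """Unique canonical isomeric SMILES from a combinatorial enumeration."""

    items: tuple[str, ...]
    n_raw: int

    @property
    def n_unique(self) -> int:
        return len(self.items)


def _potential_center_indices(mol: Chem.Mol) -> list[int]:
    return [
        int(element.centeredOn)
        for element in Chem.FindPotentialStereo(mol, cleanIt=False, flagPossible=True)
        if str(element.type) == "Atom_Tetrahedral"
    ]


def _enumerate_tags(smiles: str, states: tuple, guard: int) -> EnumerationResult:
    parent = as_mol(smiles)
    centers = _potential_center_indices(parent)
    if len(centers) > guard:
        raise TooManyCentersError(
            f"{len(centers)} stereocenters exceeds the enumeration guard ({guard})"
        )
    unique: set[str] = set()
    n_raw = 0
    for assignment in itertools.product(states, repeat=len(centers)):
        n_raw += 1
        mol = Chem.RWMol(parent)
        for idx, tag in zip(centers, assignment):
            mol.GetAtomWithIdx(idx).SetChiralTag(tag)
        candidate = mol.GetMol()
        Chem.AssignStereochemistry(candidate, cleanIt=True, force=True)
        unique.add(Chem.MolToSmiles(candidate))
    return EnumerationResult(items=tuple(sorted(unique)), n_raw=n_raw)


def enumerate_stereoisomers(smiles: str, max_centers: int = 20) -> EnumerationResult:
    """All symmetry-distinct stereoisomers of a scaffold (2^N raw assignments).

    Every potential tetrahedral center is set to both configurations; the
    parent's own configuration is irrelevant.  ``n_raw`` is 2^N and
    ``n_unique`` the number of distinct canonical isomeric SMILES.
    """
    return _enumerate_tags(smiles, (_CW, _CCW), max_centers)


def enumerate_three_state(smiles: str, max_centers: int = 13) -> EnumerationResult:
    """All R/S/undefined assignments of the potential centers (3^N raw)."""
    return _enumerate_tags(smiles, (_CW, _CCW, _NONE), max_centers)


def scramble_sequence(spec: PeptideSpec) -> EnumerationResult:
    """All distinct residue permutations of the non-fixed positions.

    The multiset of (residue, chirality) pairs at non-fixed positions is
    permuted (residues carry their chirality with them); fixed positions,
    the topology and any N-terminal cap are maintained.  Results are
    rendered to molecules and deduplicated by canonical isomeric SMILES.
    """
    positions = [p for p in range(len(spec)) if p not in spec.fixed_positions]
    movable = [spec.sequence[p] for p in positions]
    unique: set[str] = set()
    n_raw = 0
    for perm in multiset_permutations(movable):
        n_raw += 1
        residues = list(spec.sequence)
        for pos, residue in zip(positions, perm):
            residues[pos] = tuple(residue)
        smiles = peptide_smiles(spec.with_sequence(residues))
        unique.add(Chem.MolToSmiles(as_mol(smiles)))
    return EnumerationResult(items=tuple(sorted(unique)), n_raw=n_raw)


# ---------------------------------------------------------------------------
# Peptide screening benchmark generation


@dataclass(frozen=True)
class PeptideScreenSet:
    """One labelled screening set derived from a random parent sequence."""

    name: str
    kind: str  # "mutants" | "scrambles"
    parent: str
    entries: tuple[tuple[str, bool], ...]  # (sequence, is_active)

    @property
    def n_actives(self) -> int:
        return sum(1 for _, active in self.entries if active)

    def smiles_entries(self) -> list[tuple[str, str, bool]]:
        """(id, SMILES, active) triples; sequences rendered as all-L linear."""
        return [
            (f"{self.name}_{i}", peptide_smiles(PeptideSpec.from_string(seq, L)), act)
            for i, (seq, act) in enumerate(self.entries)
        ]


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / max(len(a), len(b))


def generate_peptide_benchmark(
    n_parents: int = 30,
    lengths: tuple[int, ...] = (10, 15, 20),
    n_mutants: int = 10_000,
    n_scrambles: int = 10_000,
    seed: int = 0,
    identity_threshold: float = 0.8,
) -> list[PeptideScreenSet]:
    """Mutant and scrambled peptide screening sets from random parents.

    For each of ``n_parents`` random sequences (lengths cycling through
    ``lengths``) two sets are generated: ``n_mutants`` random single-point
    mutants and ``n_scrambles`` random sequence scrambles, both
    deduplicated.  Actives are labelled by sequence identity to the parent
    at ``identity_threshold`` — the positional-identity stand-in for a
    homology search.  One seeded RNG stream per set makes every set
    independently reproducible.

    Note that single-point mutants of length-L parents all have identity
    (L-1)/L, so at the default threshold mutant sets are entirely active and
    are intended to be screened against scrambled decoys.
    """
    alphabet = list(AMINO_ACIDS_20)
    sets: list[PeptideScreenSet] = []
    for index in range(n_parents):
        length = lengths[index % len(lengths)]
        rng = np.random.default_rng([seed, index])
        parent = "".join(rng.choice(alphabet, size=length))

        mutants: dict[str, bool] = {}
        for _ in range(n_mutants):
            pos = int(rng.integers(length))
            old = parent[pos]
            new = alphabet[int(rng.integers(len(alphabet)))]
            while new == old:
                new = alphabet[int(rng.integers(len(alphabet)))]
            seq = parent[:pos] + new + parent[pos + 1:]
            mutants.setdefault(seq, _identity(seq, parent) >= identity_threshold)
        sets.append(PeptideScreenSet(
            name=f"set{index}_mut", kind="mutants", parent=parent,
            entries=tuple(sorted(mutants.items())),
        ))

        scrambles: dict[str, bool] = {}
        for _ in range(n_scrambles):
            seq = "".join(rng.permutation(list(parent)))
            if seq == parent:
                continue
            scrambles.setdefault(seq, _identity(seq, parent) >= identity_threshold)
        sets.append(PeptideScreenSet(
            name=f"set{index}_scr", kind="scrambles", parent=parent,
            entries=tuple(sorted(scrambles.items())),
        ))
    return sets
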