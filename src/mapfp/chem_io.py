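"""Molecule parsing, canonicalization and stereocenter perception.

This module is the single gateway between text formats (SMILES, ``.smi``
files, CSV) and the RDKit molecular graph used by the rest of the package.
One canonicalization engine (RDKit's canonical isomeric SMILES) is fixed for
the whole package; every distinctness statement elsewhere is defined relative
to it.

Stereocenter labels follow the Cahn-Ingold-Prelog rules as implemented by
RDKit's modern CIP labeler, which covers pseudoasymmetric (r/s) centers.
Tetrahedral centers that are stereogenic but carry no configuration in the
input are reported with the :data:`UNDEFINED` label (the fingerprint renders
them as ``?``).  Allene and conformational (biaryl/helicene) chirality are
never reported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem
from rdkit.Chem import rdCIPLabeler

from .errors import EmptyMoleculeError, ParseError

#: Label used for stereogenic tetrahedral atoms whose configuration is not
#: specified in the input.
UNDEFINED = "?"

#: CIP labels for fully specified tetrahedral centers.
CIP_LABELS = frozenset({"R", "S", "r", "s"})


@dataclass(frozen=True)
class StereoCenter:
    """A (potential) tetrahedral stereocenter.

    ``label`` is one of ``R``, ``S``, ``r``, ``s`` for centers whose
    configuration is specified in the input, or :data:`UNDEFINED` for
    stereogenic atoms without configuration.
    """

    atom_index: int
    label: str

    @property
    def defined(self) -> bool:
        return self.label in CIP_LABELS


@dataclass
class MoleculeRecord:
    """An identifier, a parsed molecular graph and its canonical SMILES."""

    id: str
    mol: Chem.Mol
    canonical_smiles: str = field(default="")

    def __post_init__(self) -> None:
        if not self.canonical_smiles:
            self.canonical_smiles = Chem.MolToSmiles(self.mol)

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()


def parse_molecule(smiles: str, id: str = "") -> MoleculeRecord:
    """Parse and sanitize a SMILES string into a :class:`MoleculeRecord`.

    Tetrahedral marks (``@``/``@@``) and directional double-bond marks
    (``/``/``\\``) present in the input are preserved on the graph.  No E/Z
    perception from geometry is attempted: only marks written in the input
    survive.

    Raises
    ------
    ParseError
        If the SMILES cannot be parsed or sanitized.
    EmptyMoleculeError
        If the molecule has no heavy atoms.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    if mol.GetNumHeavyAtoms() == 0:
        raise EmptyMoleculeError(f"no heavy atoms in {smiles!r}")
    return MoleculeRecord(id=id, mol=mol)


def as_mol(mol_like: "str | Chem.Mol | MoleculeRecord") -> Chem.Mol:
    """Coerce a SMILES string, RDKit Mol or MoleculeRecord to an RDKit Mol."""
    if isinstance(mol_like, MoleculeRecord):
        return mol_like.mol
    if isinstance(mol_like, Chem.Mol):
        return mol_like
    return parse_molecule(mol_like).mol


def stereo_centers(mol_like: "str | Chem.Mol | MoleculeRecord") -> list[StereoCenter]:
    """All potential tetrahedral stereocenters of a molecule.

    Centers whose configuration is specified carry the whole-molecule CIP
    descriptor (R/S, or r/s for pseudoasymmetric centers); stereogenic atoms
    without specified configuration carry :data:`UNDEFINED`.  Detection uses
    exhaustive stereo perception (``FindPotentialStereo``), so undefined
    centers are found even when the input carries no marks at all.

    An achiral molecule yields an empty list.
    """
    mol = Chem.Mol(as_mol(mol_like))
    potential = [
        (int(element.centeredOn), str(element.specified))
        for element in Chem.FindPotentialStereo(mol, cleanIt=False, flagPossible=True)
        if str(element.type) == "Atom_Tetrahedral"
    ]
    if any(spec == "Specified" for _, spec in potential):
        rdCIPLabeler.AssignCIPLabels(mol)
    centers = []
    for idx, spec in potential:
        if spec == "Specified":
            atom = mol.GetAtomWithIdx(idx)
            label = atom.GetPropsAsDict().get("_CIPCode", UNDEFINED)
        else:
            label = UNDEFINED
        centers.append(StereoCenter(atom_index=idx, label=label))
    return centers


def canonical_isomeric_smiles(mol_like: "str | Chem.Mol | MoleculeRecord") -> str:
    """Deterministic canonical isomeric SMILES.

    The output is a function of the abstract stereo-molecule: any atom
    renumbering of the same stereoisomer yields the same string, and distinct
    stereoisomers yield distinct strings.
    """
    return Chem.MolToSmiles(as_mol(mol_like))


# ---------------------------------------------------------------------------
# Readers / writers


def read_smi(path: "str | Path") -> list[MoleculeRecord]:
    """Read a ``.smi`` file: one ``SMILES [whitespace id]`` per line."""
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            records.append(parse_molecule(smiles, id=mol_id))
    return records


def write_smi(records: Iterable[MoleculeRecord], path: "str | Path") -> None:
    with open(path, "w") as handle:
        for record in records:
            handle.write(f"{record.canonical_smiles} {record.id}\n")


def read_csv(path: "str | Path") -> list[MoleculeRecord]:
    """Read a CSV file with (at least) ``id`` and ``smiles`` columns."""
    records = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
            raise ParseError(f"{path}: CSV must have 'id' and 'smiles' columns")
        for row in reader:
            records.append(parse_molecule(row["smiles"], id=row["id"]))
    return records


def write_csv(records: Iterable[MoleculeRecord], path: "str | Path") -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["id", "smiles"])
        for record in records:
            writer.writerow([record.id, record.canonical_smiles])


def iter_molecules(path: "str | Path") -> Iterator[MoleculeRecord]:
    """Dispatch on file suffix (.smi/.csv) and yield records."""
    path = Path(path)
    reader = read_csv if path.suffix.lower() == ".csv" else read_smi
    yield from reader(path)
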