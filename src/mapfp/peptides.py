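"""Peptide sequence specifications and SMILES rendering.

Residues are (code, chirality) pairs.  Codes are the 20 one-letter
proteinogenic codes plus a few residues needed for the natural-product
fixtures (``Dab`` = 2,4-diaminobutyric acid, ``Orn`` = ornithine).
Chirality ``L``/``D`` maps to ``@@``/``@`` on the alpha carbon of the
standard backbone fragment ``N[C@@H](side)C(=O)``; ``UNSPECIFIED`` leaves
the alpha carbon unmarked.  Threonine and isoleucine carry their natural
side-chain configuration; the D flag inverts only the alpha carbon.

Topologies: ``linear`` (free N-terminus unless capped, C-terminal acid),
``cyclic`` (head-to-tail lactam) and ``branched:k`` (residues up to k form
an exocyclic tail, residue k's side-chain amine closes a lactam ring with
the C-terminus — the polymyxin architecture).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

L = "L"
D = "D"
UNSPECIFIED = "UNSPECIFIED"

# side-chain SMILES attached to the alpha carbon; None = special-cased
SIDE_CHAINS = {
    "A": "C",
    "R": "CCCNC(=N)N",
    "N": "CC(N)=O",
    "D": "CC(=O)O",
    "C": "CS",
    "E": "CCC(=O)O",
    "Q": "CCC(N)=O",
    "G": None,
    "H": "Cc1c[nH]cn1",
    "I": "[C@@H](C)CC",
    "L": "CC(C)C",
    "K": "CCCCN",
    "M": "CCSC",
    "F": "Cc1ccccc1",
    "P": None,
    "S": "CO",
    "T": "[C@@H](C)O",
    "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
    "V": "C(C)C",
    "Dab": "CCN",
    "Orn": "CCCN",
}

AMINO_ACIDS_20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide as residues with per-residue chirality flags.

    ``fixed_positions`` are excluded from scrambling.  ``n_term_cap`` is an
    acyl fragment SMILES ending in ``C(=O)`` (e.g. 6-methylheptanoyl for
    polymyxin B2).
    """

    sequence: tuple[tuple[str, str], ...]
    fixed_positions: frozenset[int] = frozenset()
    topology: str = "linear"
    n_term_cap: str | None = None

    def __post_init__(self) -> None:
        for code, chir in self.sequence:
            if code not in SIDE_CHAINS:
                raise ValueError(f"unknown residue code {code!r}")
            if chir not in (L, D, UNSPECIFIED):
                raise ValueError(f"unknown chirality flag {chir!r}")
        if not all(0 <= p < len(self.sequence) for p in self.fixed_positions):
            raise ValueError("fixed_positions out of range")
        kind = self.topology.split(":")[0]
        if kind not in ("linear", "cyclic", "branched"):
            raise ValueError(f"unknown topology {self.topology!r}")

    @classmethod
    def from_string(cls, sequence: str, chirality: str | Sequence[str] = L,
                    **kwargs) -> "PeptideSpec":
        """Build from a one-letter string; chirality is one flag or one per residue."""
        if isinstance(chirality, str) and chirality in (L, D):
            flags = [chirality] * len(sequence)
        else:
            flags = list(chirality)
            if len(flags) != len(sequence):
                raise ValueError("one chirality flag per residue required")
        return cls(sequence=tuple(zip(sequence, flags)), **kwargs)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def branch_index(self) -> int | None:
        if self.topology.startswith("branched"):
            return int(self.topology.split(":")[1])
        return None

    def with_sequence(self, sequence: Iterable[tuple[str, str]]) -> "PeptideSpec":
        return replace(self, sequence=tuple(sequence))

    def symbols(self) -> list[str]:
        """Residue+chirality symbols for edit-distance computations."""
        return [f"{code}:{chir}" for code, chir in self.sequence]


def _alpha(chir: str) -> str:
    return {L: "[C@@H]", D: "[C@H]", UNSPECIFIED: "C"}[chir]


def _residue_fragment(code: str, chir: str, side_suffix: str = "") -> str:
    if code == "G":
        return "NCC(=O)"
    if code == "P":
        ring_ca = {L: "[C@H]", D: "[C@@H]", UNSPECIFIED: "C"}[chir]
        return f"N8CCC{ring_ca}8C(=O)"
    side = SIDE_CHAINS[code] + side_suffix
    return f"N{_alpha(chir)}({side})C(=O)"


def peptide_smiles(spec: PeptideSpec) -> str:
    """Render a :class:`PeptideSpec` to SMILES.

    The rendering is deterministic; canonicalization is left to the caller.
    """
    branch = spec.branch_index
    fragments = []
    for pos, (code, chir) in enumerate(spec.sequence):
        suffix = ""
        if branch is not None and pos == branch:
            side = SIDE_CHAINS[code]
            if side is None or not side.endswith("N"):
                raise ValueError(
                    f"branch residue {code!r} needs a side chain ending in an amine"
                )
            suffix = "%99"
        fragments.append(_residue_fragment(code, chir, side_suffix=suffix))
    body = "".join(fragments)

    kind = spec.topology.split(":")[0]
    if kind == "linear":
        smiles = body + "O"
    elif kind == "cyclic":
        if spec.n_term_cap:
            raise ValueError("cyclic peptides cannot carry an N-terminal cap")
        # head-to-tail lactam: first backbone N bonds to last carbonyl carbon
        assert body.startswith("N") and body.endswith("C(=O)")
        smiles = "N%99" + body[1:-5] + "C%99=O"
    else:  # branched: side-chain amine of residue `branch` closes onto C-terminus
        assert body.endswith("C(=O)")
        smiles = body[:-5] + "C%99=O"
    if spec.n_term_cap:
        if not spec.n_term_cap.endswith("C(=O)"):
            raise ValueError("n_term_cap must end with an acyl group C(=O)")
        smiles = spec.n_term_cap + smiles
    return smiles
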