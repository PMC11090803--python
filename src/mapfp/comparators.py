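"""Adapters for established comparator fingerprints (ECFP, Atom-Pair).

These are benchmark comparators, not part of the MinHashed atom-pair
construction: Morgan (ECFP4/6) and Atom-Pair bit vectors, in achiral and
chirality-aware variants, with Dice similarity for ranking.  All come from
RDKit behind this narrow surface.
"""

from __future__ import annotations

import numpy as np
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import as_mol

_VARIANTS = {
    "ecfp4": (2, False), "ecfp4c": (2, True),
    "ecfp6": (3, False), "ecfp6c": (3, True),
}


def comparator_fingerprint(mol_like, variant: str, n_bits: int = 2048):
    """Folded bit-vector fingerprint for a comparator variant.

    Variants: ecfp4/ecfp6 (+'c' for chirality-aware) and ap/apc.
    """
    mol = as_mol(mol_like)
    key = variant.lower()
    if key in _VARIANTS:
        radius, chiral = _VARIANTS[key]
        generator = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits, includeChirality=chiral
        )
    elif key in ("ap", "apc"):
        generator = rdFingerprintGenerator.GetAtomPairGenerator(
            fpSize=n_bits, includeChirality=(key == "apc")
        )
    else:
        raise ValueError(f"unknown comparator variant {variant!r}")
    return generator.GetFingerprint(mol)


def dice_similarity(fp_a, fp_b) -> float:
    return float(DataStructs.DiceSimilarity(fp_a, fp_b))


def count_distinct_comparator(molecules, variant: str, n_bits: int = 2048) -> int:
    """Number of distinct comparator bit vectors over a family of molecules."""
    seen = set()
    for smiles in molecules:
        fp = comparator_fingerprint(smiles, variant, n_bits)
        seen.add(DataStructs.BitVectToBinaryText(fp))
    return len(seen)
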