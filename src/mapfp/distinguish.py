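"""Stereoisomer-distinction counting and isomer-distance analytics.

The central question: does a fingerprint assign a different value to every
stereoisomer of a molecule?  ``count_distinct_fingerprints`` answers it by
exact MinHash-vector equality (the reported quantity), with the number of
distinct raw shingle sets alongside for diagnosis — a gap between the two
indicates hash collisions, a gap between shingle sets and structures
indicates a genuine resolution limit of the shingling at that diameter.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import as_mol, stereo_centers
from .errors import ParseError
from .fingerprint import MinHashedAtomPairFingerprint
from .minhash import HashScheme, base_hash_array, jaccard_matrix, minhash_values
from .peptides import PeptideSpec
from .shingling import FPConfig, compute_shingles


@dataclass(frozen=True)
class DistinctionReport:
    """Result of a distinct-fingerprint count over a family of molecules."""

    n_inputs: int
    n_unique_structures: int
    n_distinct_fps: int
    n_distinct_shingle_sets: int
    k: int
    variant: str
    collisions: tuple[tuple[str, str], ...] = ()

    def as_dict(self) -> dict:
        return {
            "n_inputs": self.n_inputs,
            "n_unique_structures": self.n_unique_structures,
            "n_distinct_fps": self.n_distinct_fps,
            "n_distinct_shingle_sets": self.n_distinct_shingle_sets,
            "k": self.k,
            "variant": self.variant,
            "collisions": [list(pair) for pair in self.collisions],
        }


def count_distinct_fingerprints(
    molecules, config: FPConfig | None = None, ids=None,
    max_collisions: int = 50,
) -> DistinctionReport:
    """Count exact-vector-distinct fingerprints over a family of SMILES.

    ``collisions`` lists (up to ``max_collisions``) pairs of inputs whose
    fingerprints are bit-equal although their canonical SMILES differ.
    Parse errors are re-raised with the offending molecule index.
    """
    config = config or FPConfig()
    molecules = list(molecules)
    ids = list(ids) if ids is not None else [str(i) for i in range(len(molecules))]
    scheme = HashScheme.from_config(config)

    structures: set[str] = set()
    shingle_digests: set[bytes] = set()
    by_fp: dict[bytes, list[int]] = {}
    canonical: list[str] = []
    for index, smiles in enumerate(molecules):
        try:
            mol = as_mol(smiles)
        except ParseError as exc:
            raise ParseError(f"molecule {index} ({ids[index]}): {exc}") from exc
        canonical.append(Chem.MolToSmiles(mol))
        structures.add(canonical[-1])
        shingle_set = compute_shingles(mol, config)
        ordered = sorted(shingle_set.shingles)
        shingle_digests.add(hashlib.sha1("\n".join(ordered).encode()).digest())
        fp = minhash_values(base_hash_array(ordered), scheme).tobytes()
        by_fp.setdefault(fp, []).append(index)

    collisions: list[tuple[str, str]] = []
    for indices in by_fp.values():
        if len(indices) < 2:
            continue
        first = indices[0]
        for other in indices[1:]:
            if canonical[other] != canonical[first] and len(collisions) < max_collisions:
                collisions.append((ids[first], ids[other]))
    return DistinctionReport(
        n_inputs=len(molecules),
        n_unique_structures=len(structures),
        n_distinct_fps=len(by_fp),
        n_distinct_shingle_sets=len(shingle_digests),
        k=config.n_permutations,
        variant=config.variant,
        collisions=tuple(collisions),
    )


def stereo_levenshtein(a: "PeptideSpec | list[str]", b: "PeptideSpec | list[str]") -> int:
    """Edit distance over (residue, chirality) symbols.

    Any symbol mismatch — residue change, chirality inversion, or both —
    costs 1, as do insertions and deletions.  Cyclic peptides are compared
    on their written linear register.
    """
    sa = a.symbols() if isinstance(a, PeptideSpec) else list(a)
    sb = b.symbols() if isinstance(b, PeptideSpec) else list(b)
    previous = list(range(len(sb) + 1))
    for i, x in enumerate(sa, start=1):
        current = [i]
        for j, y in enumerate(sb, start=1):
            current.append(min(
                previous[j] + 1,
                current[j - 1] + 1,
                previous[j - 1] + (x != y),
            ))
        previous = current
    return previous[-1]


@dataclass(frozen=True)
class DistancePairSummary:
    """Jaccard-distance distribution of one isomer group."""

    group_label: str
    distances: np.ndarray
    per_molecule_mean: np.ndarray
    levenshtein: np.ndarray | None = None

    def summary(self) -> dict:
        q1, median, q3 = np.percentile(self.distances, [25, 50, 75])
        return {
            "group": self.group_label, "n_pairs": int(self.distances.size),
            "q1": float(q1), "median": float(median), "q3": float(q3),
            "mean": float(self.distances.mean()),
        }


def _pairwise_distances(fps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sim = jaccard_matrix(fps)
    dist = 1.0 - sim
    iu = np.triu_indices(len(dist), k=1)
    per_mol = (dist.sum(axis=1)) / max(len(dist) - 1, 1)
    return dist[iu], per_mol


def isomer_distance_summary(
    stereoisomers, other_isomers, config: FPConfig | None = None,
    stereo_specs=None, other_specs=None,
) -> tuple[DistancePairSummary, DistancePairSummary]:
    """Pairwise Jaccard-distance distributions for two isomer groups.

    Returns summaries for the stereoisomer group and the structural /
    sequence-isomer group; when peptide specs are supplied the pairwise
    stereo-aware Levenshtein distances are attached for stratification.
    Both per-pair distances and per-molecule mean distances are emitted.
    """
    config = config or FPConfig()
    transformer = MinHashedAtomPairFingerprint(
        config.variant, n_permutations=config.n_permutations, seed=config.seed
    ).fit()

    def build(smiles_list, specs, label):
        fps = transformer.transform(smiles_list)
        distances, per_mol = _pairwise_distances(fps)
        lev = None
        if specs is not None:
            n = len(specs)
            iu = np.triu_indices(n, k=1)
            lev = np.array([
                stereo_levenshtein(specs[i], specs[j])
                for i, j in zip(*iu)
            ])
        return DistancePairSummary(
            group_label=label, distances=distances,
            per_molecule_mean=per_mol, levenshtein=lev,
        )

    return (
        build(list(stereoisomers), stereo_specs, "stereoisomer-pair"),
        build(list(other_isomers), other_specs, "isomer-pair"),
    )


def chirality_stats(molecules, bin_width: int = 1) -> pd.DataFrame:
    """Fraction of molecules with >= 1 (potential) stereocenter per HAC bin.

    Returns a DataFrame with columns ``hac_bin`` (left edge), ``n`` and
    ``fraction_chiral``.  Defined and undefined potential centers both
    count as chiral.
    """
    rows = []
    for smiles in molecules:
        mol = as_mol(smiles)
        rows.append((
            (mol.GetNumHeavyAtoms() // bin_width) * bin_width,
            bool(stereo_centers(mol)),
        ))
    frame = pd.DataFrame(rows, columns=["hac_bin", "chiral"])
    grouped = frame.groupby("hac_bin", as_index=False).agg(
        n=("chiral", "size"), fraction_chiral=("chiral", "mean")
    )
    return grouped
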