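"""scikit-learn style transformer for the MAP(C) fingerprint family.

:class:`MinHashedAtomPairFingerprint` turns an iterable of molecules
(SMILES strings, RDKit Mols or :class:`~mapfp.chem_io.MoleculeRecord`) into
a dense ``(n_samples, n_permutations)`` uint64 matrix of MinHash values.
It follows the sklearn estimator contract (``fit``/``transform``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so it
composes with pipelines; similarity between rows is the fraction of equal
components (:func:`mapfp.minhash.jaccard_matrix`).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .chem_io import as_mol
from .minhash import HashScheme, MinHashFP, base_hash_array, minhash_values
from .shingling import FPConfig, compute_shingles


class MinHashedAtomPairFingerprint(TransformerMixin, BaseEstimator):
    """MinHashed chiral atom-pair fingerprint (MAP2C/MAP4C/MAP6C family).

    Parameters
    ----------
    variant : str, default "map4c"
        One of map2c/map4c/map6c (chiral) or map2/map4/map6 (achiral).
        The number is the largest substructure diameter in bonds.
    n_permutations : int, default 2048
        Fingerprint length k.
    seed : int, default 42
        Seed of the MinHash hash family; part of the fingerprint identity.

    Attributes
    ----------
    config_ : FPConfig
        Resolved configuration after :meth:`fit`.
    scheme_ : HashScheme
        The seeded hash family.

    Examples
    --------
    >>> fp = MinHashedAtomPairFingerprint("map4c").fit()
    >>> X = fp.transform(["CCO", "CCN"])
    >>> X.shape
    (2, 2048)
    """

    def __init__(self, variant: str = "map4c", n_permutations: int = 2048,
                 seed: int = 42):
        self.variant = variant
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, X=None, y=None) -> "MinHashedAtomPairFingerprint":
        """Resolve the configuration and build the hash family (stateless in X)."""
        self.config_ = FPConfig.from_variant(
            self.variant, n_permutations=self.n_permutations, seed=self.seed
        )
        self.scheme_ = HashScheme.from_config(self.config_)
        return self

    def _ensure_fitted(self) -> None:
        if not hasattr(self, "config_"):
            self.fit()

    def transform(self, X: Iterable) -> np.ndarray:
        """Fingerprint each molecule; returns (n_samples, k) uint64."""
        self._ensure_fitted()
        rows = [self.encode(item) for item in X]
        if not rows:
            return np.empty((0, self.config_.n_permutations), dtype=np.uint64)
        return np.vstack(rows)

    def encode(self, mol_like) -> np.ndarray:
        """Fingerprint of a single molecule as a length-k uint64 vector."""
        self._ensure_fitted()
        shingle_set = compute_shingles(as_mol(mol_like), self.config_)
        hashes = base_hash_array(sorted(shingle_set.shingles))
        return minhash_values(hashes, self.scheme_)

    def fingerprint(self, mol_like) -> MinHashFP:
        """Like :meth:`encode` but wrapped with its configuration."""
        self._ensure_fitted()
        return MinHashFP(values=self.encode(mol_like), config=self.config_)
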