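"""MinHash compression of shingle sets and Jaccard similarity estimation.

Each shingle string is first mapped to a stable 64-bit base hash
(BLAKE2b-64 of its UTF-8 bytes; process-randomized hashing is never used).
A seeded family of k multiply-shift hash functions

    h_i(x) = ((a_i * x + b_i) mod 2**64) >> 32,   a_i odd

then produces the fingerprint component i as the minimum of h_i over the
base hashes of all shingles in the set.  Equal shingle sets give bit-equal
vectors; the fraction of matching components between two fingerprints is an
(approximately) unbiased estimator of the Jaccard index of the underlying
sets with standard error sqrt(J(1-J)/k).

Multipliers and offsets are drawn from ``numpy.random.default_rng(seed)``,
so a (k, seed) pair fully determines the hash family.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigMismatchError, EmptySetError
from .shingling import FPConfig, ShingleSet

_SHIFT = np.uint64(32)
_BLOCK = 512  # permutations per vectorized block; bounds peak memory


@dataclass(frozen=True)
class HashScheme:
    """A seeded family of k multiply-shift hash functions."""

    k: int
    seed: int
    a: np.ndarray = field(repr=False, compare=False, default=None)
    b: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.a is None:
            rng = np.random.default_rng(self.seed)
            a = rng.integers(1, 1 << 63, size=self.k, dtype=np.uint64) | np.uint64(1)
            b = rng.integers(0, 1 << 63, size=self.k, dtype=np.uint64)
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)

    @classmethod
    def from_config(cls, config: FPConfig) -> "HashScheme":
        return cls(k=config.n_permutations, seed=config.seed)


@dataclass(frozen=True)
class MinHashFP:
    """A fixed-length MinHash vector plus the configuration that made it."""

    values: np.ndarray
    config: FPConfig

    def __len__(self) -> int:
        return len(self.values)

    def tobytes(self) -> bytes:
        return self.values.tobytes()


def base_hash(shingle: str) -> int:
    """Stable 64-bit hash of a shingle string (BLAKE2b, big-endian)."""
    return int.from_bytes(
        hashlib.blake2b(shingle.encode("utf-8"), digest_size=8).digest(), "big"
    )


def base_hash_array(shingles) -> np.ndarray:
    return np.fromiter(
        (base_hash(s) for s in shingles), dtype=np.uint64, count=len(shingles)
    )


def minhash_values(base_hashes: np.ndarray, scheme: HashScheme) -> np.ndarray:
    """Length-k vector of minima of the permuted hashes (uint64, < 2**32)."""
    if base_hashes.size == 0:
        raise EmptySetError("cannot MinHash an empty set")
    out = np.empty(scheme.k, dtype=np.uint64)
    x = base_hashes[None, :]
    for start in range(0, scheme.k, _BLOCK):
        stop = min(start + _BLOCK, scheme.k)
        h = (scheme.a[start:stop, None] * x + scheme.b[start:stop, None]) >> _SHIFT
        out[start:stop] = h.min(axis=1)
    return out


def minhash_fingerprint(shingle_set: ShingleSet, scheme: HashScheme | None = None) -> MinHashFP:
    """MinHash a :class:`ShingleSet` into a fixed-length fingerprint."""
    if len(shingle_set) == 0:
        raise EmptySetError("cannot MinHash an empty shingle set")
    scheme = scheme or HashScheme.from_config(shingle_set.config)
    hashes = base_hash_array(sorted(shingle_set.shingles))
    values = minhash_values(hashes, scheme)
    return MinHashFP(values=values, config=shingle_set.config)


def jaccard_similarity(a: MinHashFP, b: MinHashFP) -> float:
    """Fraction of matching components — estimates the true Jaccard index."""
    if a.config != b.config:
        raise ConfigMismatchError(
            f"incompatible fingerprints: {a.config} vs {b.config}"
        )
    return float(np.mean(a.values == b.values))


def jaccard_matrix(fps_a: np.ndarray, fps_b: np.ndarray | None = None) -> np.ndarray:
    """Pairwise matching-component fractions between fingerprint matrices.

    ``fps_a`` is (n, k); ``fps_b`` defaults to ``fps_a``.  Returns (n, m).
    """
    if fps_b is None:
        fps_b = fps_a
    n, m = fps_a.shape[0], fps_b.shape[0]
    out = np.empty((n, m), dtype=np.float64)
    for i in range(n):
        out[i] = np.mean(fps_b == fps_a[i][None, :], axis=1)
    return out


def exact_jaccard(a, b) -> float:
    """|A n B| / |A u B| of two string sets (test oracle and reference)."""
    a, b = set(a), set(b)
    if not a and not b:
        raise EmptySetError("Jaccard of two empty sets is undefined")
    return len(a & b) / len(a | b)
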