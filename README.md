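# mapfp — chiral MinHashed atom-pair fingerprints

Most molecular fingerprints ignore stereochemistry, which becomes a real
problem for carbohydrates, macrocyclic natural products and peptides: a
molecule with N tetrahedral stereocenters has up to 2^N stereoisomers, all
with identical achiral fingerprints.  `mapfp` implements the chiral
MinHashed atom-pair fingerprint family **MAP2C / MAP4C / MAP6C** for anyone
doing similarity search, virtual screening or chemical-space analysis on
stereochemically rich molecules, together with the machinery to study how
well a fingerprint separates stereoisomers.

## The fingerprint

For every heavy atom and every radius r = 1..R (R = 1, 2, 3 for MAP2C,
MAP4C, MAP6C; the largest substructure *diameter* is 2R bonds), the bond
environment is extracted as a rooted canonical SMILES with tetrahedral
marks removed (cis/trans marks are kept when the whole double bond lies
inside).  Every unordered pair of same-radius substructures forms a
*shingle*

```
substructure 1 | topological distance in bonds | substructure 2
```

At the largest radius, when the central atom is a stereocenter, its root
atom token is replaced by the whole-molecule Cahn–Ingold–Prelog descriptor
bracketed in dollar signs — `$R$`, `$S$`, `$r$`, `$s$`, or `$?$` when the
configuration is not specified.  The shingle set S is then MinHashed into a
fixed-length vector: component i is min over s in S of h_i(hash64(s)) for a
seeded family of k universal hash functions (default k = 2048).  The
fraction of matching components between two fingerprints is an unbiased
estimate of the Jaccard index |A∩B| / |A∪B| of the two shingle sets.

Because only max-radius root tokens carry chirality, a configuration flip
perturbs a small local fraction of the shingles: stereoisomers stay much
closer to each other than constitutional isomers, while (for most scaffolds)
every stereoisomer still receives a distinct fingerprint.

## Worked example

```python
>>> from mapfp import MinHashedAtomPairFingerprint, compute_shingles, FPConfig, parse_molecule
>>> sorted(compute_shingles(parse_molecule("CCC"), FPConfig.from_variant("map2c")).shingles)
['C(C)C|1|CC', 'CC|2|CC']

>>> fp = MinHashedAtomPairFingerprint("map4c").fit()   # sklearn-style transformer
>>> X = fp.transform(["N[C@@H](C)C(=O)O", "N[C@H](C)C(=O)O", "CC(N)C(=O)O"])
>>> X.shape
(3, 2048)
>>> import numpy as np
>>> float(np.mean(X[0] == X[1]))   # L- vs D-alanine: close but distinct
0.708984375
>>> float(np.mean(X[0] == X[0]))
1.0
```

The L/D pair shares all shingles except those rooted at the flipped center
(`$S$...` vs `$R$...`), hence the high — but not perfect — similarity.

Enumerating and separating stereoisomers:

```python
>>> from mapfp import enumerate_stereoisomers, count_distinct_fingerprints, get_fixture
>>> result = enumerate_stereoisomers(get_fixture("trehalose"))
>>> (result.n_raw, result.n_unique)     # C2 symmetry quotients 2^10
(1024, 528)
>>> report = count_distinct_fingerprints(result.items, FPConfig.from_variant("map4c"))
>>> report.n_distinct_fps
528
```

A command-line interface mirrors the library:

```bash
mapfp shingles --smiles 'CC' --variant map4c     # -> CC|1|CC
mapfp enumerate --smiles 'OC1C(O)C(O)C(O)C(O)C1O'   # 9 inositol isomers
mapfp distinguish --in isomers.smi --variant map4c --k 2048
mapfp benchmark --actives a.smi --decoys d.smi --variant map4c --seed 1
```

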