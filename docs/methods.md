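# Methods

## The chiral MinHashed atom-pair construction

A molecule is encoded in four steps.

1. **Circular substructures.** For every heavy atom and every radius
   r = 1..R bonds (radius 0 is skipped), the set of bonds within r bonds of
   the atom is serialized as a canonical SMILES rooted at the central atom
   (the root is always the first atom token).  Tetrahedral marks are
   removed from the substructure before canonicalization; directional
   cis/trans marks survive only when the entire stereo double bond,
   including both stereo-defining neighbours, lies inside the substructure
   (a dangling `/` next to a half-included double bond carries no
   information and would break locality).  If no environment of exactly
   radius r exists around an atom (the molecule is too small there), that
   (atom, radius) pair is absent.  Allene and conformational chirality are
   out of scope: only tetrahedral atom centers are annotated.

2. **Chiral root labels.** At the *largest* radius only, when the central
   atom is a tetrahedral stereocenter, the root atom token is replaced by
   the CIP descriptor of that atom bracketed by dollar signs: `$R$`, `$S$`,
   `$r$`, `$s$`, or `$?$` for a stereogenic atom without specified
   configuration.  The descriptor is computed on the entire molecule (CIP
   priorities depend on remote atoms), using RDKit's modern CIP labeler,
   which handles pseudoasymmetric (r/s) centers.  Undefined centers are
   detected by exhaustive stereo perception, not just by present marks, so
   stereo-randomized inputs produce `$?$` shingles.

3. **Shingles.** For each radius independently, every unordered pair of
   distinct atoms whose radius-r substructures both exist contributes the
   string `subA|d|subB`, where d is the shortest topological distance in
   bonds between the two central atoms and the two substructure strings
   are sorted bytewise (so the shingle is orientation-free).  Duplicates
   collapse: the shingle set has set, not multiset, semantics.  Pairs are
   formed within a radius only — cross-radius pairs would duplicate
   sub-maximal environments.  Self-pairs are excluded; d >= 1.

4. **MinHash.** Each shingle is hashed to 64 bits with BLAKE2b (stable
   across processes and platforms; process-randomized hashing is never
   used).  A seeded family of k hash functions
   `h_i(x) = ((a_i * x + b_i) mod 2^64) >> 32` with odd multipliers a_i
   (the multiply-shift universal family) yields fingerprint component i as
   the minimum of h_i over the shingle hashes.  The fraction of equal
   components between two fingerprints estimates the Jaccard index of the
   two shingle sets with standard error sqrt(J(1-J)/k).  Multiply-shift was
   chosen over modular hashing with a Mersenne prime because 64-bit word
   arithmetic vectorizes directly in numpy; exact mod-(2^61-1) products
   need 128-bit emulation and measured about five times slower, while the
   estimator contract (determinism given (k, seed), unbiasedness,
   1/sqrt(k) error decay) is identical and is verified in the test suite
   against exact set Jaccard.

Variant naming: MAP2C / MAP4C / MAP6C use R = 1 / 2 / 3 (the number is the
largest substructure *diameter* in bonds); `chiral=False` gives the achiral
MAP2/MAP4/MAP6 construction, which on any input coincides with the chiral
construction applied to the stereo-stripped molecule.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `max_radius` | 2 (MAP4C) | largest environment radius in bonds; diameter = 2R |
| `n_permutations` (k) | 2048 | fingerprint length; Jaccard standard error ~ sqrt(J(1-J)/k) ≈ 0.01 at J = 0.5 |
| `seed` | 42 | seed of the hash family; part of the fingerprint identity — vectors with different (k, seed) are never comparable |
| `chiral` | true | whether stereocenter root tokens are CIP-labelled |

Distinctness statements ("N distinct fingerprints") always refer to exact
vector equality at a recorded (k, seed); distinct shingle sets map to
distinct vectors unless a hash collision intervenes, so counts are reported
together with k and the raw shingle-set count for diagnosis.

## Stereoisomer enumeration

`enumerate_stereoisomers` assigns every *potential* tetrahedral stereocenter
of the parent scaffold (found by exhaustive stereo perception) to both
configurations, re-perceives stereochemistry per instance (dropping tags on
atoms that are non-stereogenic in that particular diastereomer, e.g. the
pseudoasymmetric positions of the inositols), canonicalizes, and removes
duplicate strings.  Canonical deduplication performs the symmetry quotient:
for a scaffold whose constitution has a cyclic symmetry group, the unique
count equals the Burnside orbit count, which the tests verify independently
by direct group arithmetic (C2: trehalose 2^10 → 528; C3: valinomycin
2^12 → 1376; C4: nonactin 2^16 → 16456; C7: cyclic hepta-arginine
2^7 → 20).  A guard (default 20 centers) bounds the 2^N cost.
`enumerate_three_state` adds "mark removed" as a third state per center
(3^N raw combinations), modelling stereorandomized synthesis with racemic
building blocks.

Sequence scrambles (`scramble_sequence`) permute the multiset of
(residue, chirality) pairs at non-fixed positions of a peptide spec,
render each permutation to SMILES and deduplicate structurally — for
asymmetric topologies the unique count is the multinomial coefficient
(polymyxin B2: 9 movable residues {Dab×5, Thr×2, Phe, Leu} → 1512).

## The molecule registry

`mapfp.registry` holds the fourteen benchmark scaffolds (5-16
stereocenters, symmetries up to C7).  Peptides are generated from residue
templates; sugars and macrolides are literal literature structures.  Every
entry is validated in the tests against its published stereocenter count
and enumeration total.  Three entries are explicitly synthetic surrogates
rather than transcriptions: ln65 is a representative 7×Lys/4×Leu
undecapeptide with the published composition (330 scrambles), and
quinaldopeptin/onchidin are C2-symmetric cyclic peptides matching the
reported stereocenter counts (8, 12) and symmetry class — sufficient for
the symmetry-counting analyses they participate in, but not the natural
products themselves.  Polymyxin B2 uses the achiral 6-methylheptanoyl acyl
group, giving exactly the published 12 stereocenters (10 alpha carbons
plus two threonine side chains).

Distinct-fingerprint counts are defined relative to this package's fixed
serialization (RDKit canonical rooted SMILES of the stereo-stripped
environment).  For scaffolds where the diameter-four fingerprint cannot
separate all stereoisomers (symmetric macrocycles such as gramicidin S),
the exact number of residual coincidences depends on byte-level
serialization choices and is implementation-defined; the qualitative
pattern — full separation for asymmetric scaffolds, residual symmetric
pairs at diameter four that diameter six resolves — is what the package
reproduces and tests.

## Synthetic data

`random_chiral_molecules` builds random branched C/N/O skeletons (10-50
heavy atoms, occasional single ring, uniform random configurations on all
potential centers) for the chiral-shingle-fraction calibration: across
such a sample the fraction of shingles carrying a `$` token is
approximately equal to the fraction of chiral atoms (about half of all
MAP4C shingles are max-radius pairs, and a fraction ~2c of those touch a
labelled root, giving slope ≈ 1 at small c).  The generator does not
emulate aromatic systems, charges or realistic functional-group
distributions, so passing calibration tests demonstrate the geometric
property of the encoding, not screening performance on real libraries.

The peptide benchmark generator emulates the published protocol: random
10/15/20-mer parents, 10,000 single-point mutants and 10,000 scrambles per
parent, deduplicated, one seeded RNG stream per set.  Homology labelling
is positional sequence identity at a threshold (default 0.8) — a stand-in
for a BLAST search.  Single-point mutants of an L-mer all have identity
(L-1)/L, so mutant sets are entirely active at the default threshold and
are meant to be screened against scrambled decoys via the explicit
(actives, decoys) interface of `run_benchmark_set`.

## Screening metrics

AUC uses the rank-sum formulation with mid-rank ties.  EF at x% counts
actives in the top ceil(x/100·n) of the deterministic ranking (ties broken
by molecule id — the definition leaves tie handling open, so it is fixed
and documented here).  RIE is the sum of exp(-α·r_i/n) over active ranks
divided by its uniform-placement expectation; BEDROC rescales RIE to [0,1]
using its exact best/worst-case values obtained by evaluating the same
formula with all actives at the top/bottom — algebraically identical to
the closed form but immune to transcription error.  All four are verified
against brute-force oracles and an independent toolkit implementation on
small lists, including exhaustive tie configurations.

## Numerical and testing notes

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; fingerprints are bit-reproducible for a given (k, seed).
- The MinHash 3-sigma acceptance check is evaluated as a coverage test
  (at most 2 of 120 pairs outside the bound): a per-pair hard bound at
  3 sigma would be violated by any correct estimator with ~30 %
  probability over 100+ pairs.
- The chirality-locality trend (Jaccard distance vs number of inverted
  centers) is evaluated on per-stratum mean distances, mirroring the
  per-stratum box-plot analysis: which particular centers flip dominates
  the within-stratum variance, so the trend is a property of the strata,
  not of individual pairs.
- Test and acceptance problem sizes: families up to 2^16 enumerated
  structures and 2^14 fingerprinted structures run in the acceptance
  script; the pytest suite keeps to families of ≤ 1024 structures.

## Known limitations

- Distinct counts for symmetric macrocycles at sub-resolving diameters are
  implementation-defined (see above); only full-separation counts are
  exactly comparable across implementations.
- Cyclic-peptide Levenshtein distances are computed on the written linear
  register; rotational alignment is not searched.
- Double-bond stereo is honoured only when written in the input; no E/Z
  perception from coordinates.
- No tautomer normalization, salt stripping or 3D input.
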