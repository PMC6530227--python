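# Methods

## The descriptor

A protein sequence is mapped to its **adjacency vector**: 400 non-negative
integers counting each ordered pair of adjacent residues under the fixed
residue ordering A, R, N, D, C, Q, E, G, H, I, L, K, M, F, P, S, T, W, Y, V
(element 20·i + j = count of residue i immediately followed by residue j).
Counting uses a sliding window of width 2 and step 1, so a length-L sequence
contributes exactly L − 1 pairs; absent pairs are 0. The descriptor is the
overlapping-2-mer (dipeptide) composition of the sequence; order within the
pair matters, so reversing a sequence transposes the 20×20 matrix view of
the counts, and concatenating two sequences adds their vectors plus the one
boundary pair.

Degenerate inputs: a length-1 sequence maps to the zero vector rather than
an error — the descriptor stays total, and the one place where a zero vector
is meaningless (the angle, which needs a direction) rejects it explicitly by
name. Empty sequences are rejected at I/O time.

## Residue policies

The descriptor assumes exactly 20 symbols. Real FASTA files occasionally
contain ambiguity codes (X, B, Z, ...), stops (`*`) or gaps (`-`). Three
policies are provided, chosen at read time:

- `strict` (default): any non-canonical character is an error naming the
  record and position. This is the right default for the benchmark data,
  which is fully canonical.
- `mask`: the character is kept but every width-2 window touching it is
  skipped; the skipped windows are tallied per sequence (`skipped_pairs`),
  so the sum invariant becomes Σcounts = L − 1 − skipped.
- `drop`: the character is deleted before pairing, which joins its two
  neighbours into a (possibly spurious) pair.

`mask` is the conservative choice for lightly ambiguous data; `drop` changes
pair structure and is provided mainly for contrast.

## The group representative

A family (≥ 2 sequences; a singleton is allowed with a warning) is
summarised by the **elementwise median** of its members' adjacency vectors.
The median is preferred to the mean for its robustness: replacing one
member's count by an arbitrarily large value moves each element by at most
one order statistic. With an even number of members the standard convention
(mean of the two central order statistics) is used, so representative values
may be half-integers; they are kept exact — never rounded — because the
similarity statistics consume them directly. With an odd number of members
every element is an integer.

## Similarity statistics

Against a representative GR, each member's adjacency vector A is scored by

- **D = ‖A − GR‖**, the Euclidean norm of the difference, computed on raw
  count vectors; and
- **θ = arccos( A·GR / (‖A‖‖GR‖) )** in radians, the angle between the two
  descriptors.

θ is invariant under positive rescaling of either vector and therefore
insensitive to sequence length; D is not, and for families with
heterogeneous lengths θ is the statistic to prefer. Two exploratory
normalization modes for D are exposed (`unit`: each vector divided by its
Euclidean norm; `length`: divided by its total pair count) but `none` is the
default: the raw Euclidean difference is the statistic as defined, and no
single rescaling of it is canonical. Published benchmark tables print D
values that are inconsistent with raw integer-count geometry (three beta
globin sequences of different lengths share D = 0.5568, below the minimum
distance of distinct integer vectors), so this package treats printed D
columns as non-reproducible and validates D by construction instead: oracle
equivalence and the Euclidean metric axioms (symmetry, triangle inequality,
identity of indiscernibles). θ columns are scale-free and are reproduced
directly.

Numerical contract for θ: the cosine is clamped to [−1, 1] before arccos to
absorb floating-point overshoot, and exactly identical descriptors return
exactly 0 (short-circuited before any rounding can leave a ~1e-9 residue).
There is no randomness anywhere in the core, so reruns are byte-identical.

### Similarity vector vs pairwise matrix

The similarity vector holds one (D, θ) entry per member against the family
representative — n statistic evaluations per metric for a family of n. The
conventional all-pairs matrix (provided as a contrast mode, with PHYLIP
export) needs n(n−1)/2 evaluations; the implementation instruments the
count, and the test suite pins it to 21 at n = 7. Entries are reported in
input order; ranked output is opt-in (`--sort`), never silent.

### Cross-group comparison

Scoring family X's members against family Y's representative uses the
identical computation with the output tagged by both group names. For
well-separated families every member's θ against the foreign representative
exceeds its θ against its own; the package validates this *qualitatively* on
synthetic families (own-GR θ < foreign-GR θ for every member of both
families, in ≥ 95% of 20 seeded trials) rather than against published
cross-group tables, which are internally inconsistent (identical rows appear
under different sample/representative combinations).

## Class-coherence rule

For a family whose members carry class labels (e.g. the spike sample's
classes I, II, III and SARS-CoVs), the report computes each class's θ
interval and flags misfits. No canonical flagging rule exists, so the
package states its own: a two-pass leave-one-out interval test. Pass 1
marks a sequence *suspect* when its θ lies outside the interval spanned by
the rest of its own class. Pass 2 recomputes each class's *core* interval
from non-suspect members only — so a genuine outlier cannot inflate its own
class's interval and cascade flags onto healthy members of other classes —
and flags every suspect whose θ lands inside another class's core interval.
Singleton classes have an empty leave-one-out interval, so their member is
suspect by construction and flagged only if it invades another class.

## Synthetic families

The fixture generator draws a uniform-random ancestor of given length over
the 20 canonical residues, then derives each further member by substituting
every site independently with probability `substitution_rate` to a uniformly
random *different* residue; the ancestor is member 0 and everything is
deterministic given the seed. Defaults: length 200, 8 members, rate 0.1 — a
compact family with clearly separated within- and between-family angles at
the scale of the benchmark proteins (hundreds of residues, ~10⁰–10¹ %
divergence within a family).

What the generator emulates is *group structure only*: a common origin plus
independent point substitutions. It has no substitution matrix, no indels,
no compositional bias, no phylogeny — so tests passing on synthetic families
demonstrate the machinery (descriptor arithmetic, median robustness,
within- vs cross-group separation), not performance on real evolutionary
data. The published beta globin / ND5 / spike families are the realistic
check; their sequences must be fetched from NCBI once
(`scripts/fetch_published.py`) since the library itself never touches the
network.

## Problem sizes used in checks

The automated checks run on the built-in 30-residue worked example, random
sequences up to a few hundred residues, synthetic families of 6–9 members
(lengths 150–400), 20-trial seeded simulations for the cross-group and
rate-monotonicity frequencies, and a 100-sequence brute-force oracle sweep —
sizes at which every oracle is exact and the whole suite completes in well
under a minute.

## Known limitations

- Order-2 composition only: k-mers with k > 2, gap-aware counting and
  weighting schemes are out of scope.
- Printed D benchmark columns cannot be matched (see above); θ is the
  comparable statistic.
- The median representative needs a handful of members to be meaningful; a
  singleton family's representative is just that member (warned).
- Ambiguity handling is policy-based masking/dropping, not probabilistic
  expansion of ambiguity codes.
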