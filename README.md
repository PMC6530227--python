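# grvec

Alignment-free similarity analysis of protein families, built around two
ideas:

1. **Adjacency vector.** Each protein sequence over the 20 canonical amino
   acids is summarised by a 400-element integer vector *A* counting every
   ordered pair of adjacent residues read left to right (a sliding window of
   width 2, so a length-*L* sequence yields *L* − 1 pairs). With the
   residues in the fixed order A, R, N, D, C, Q, E, G, H, I, L, K, M, F, P,
   S, T, W, Y, V, element 20·*i* + *j* counts residue *i* followed by
   residue *j*.
2. **Group representative.** A family of sequences is summarised by the
   elementwise **median** of its members' adjacency vectors, *GR* — a robust
   consensus descriptor that one aberrant member cannot drag around.

Each member is then scored against its family's representative with two
statistics:

- magnitude **D** = ‖*A* − *GR*‖ (Euclidean norm of the difference), and
- angle **θ** = arccos( *A* · *GR* / (‖*A*‖ ‖*GR*‖) ) in radians,
  scale-free and therefore insensitive to sequence length.

This replaces the classical all-pairs similarity matrix — n(n−1)/2 statistic
evaluations — with a *similarity vector* of n evaluations, one per member.
Scoring a family against a *foreign* family's representative (cross-group
comparison) shows a systematic blow-up of θ, which is what makes the
representative a usable family signature. A conventional pairwise-matrix
mode is included for contrast, with PHYLIP export for tree tools.

The intended users are researchers comparing protein families (globins,
mitochondrial ND5, coronavirus spike proteins, ...) who want a cheap,
alignment-free family descriptor and per-sequence membership scores.

## Worked example

```python
from grvec import (worked_example, compute_adjacency,
                   build_representative, similarity_vector)

sample = worked_example()          # two 30-residue yeast protein segments
for v in map(compute_adjacency, sample.records):
    print(v.source_id, v.total_pairs, v.count("N", "D"))

gr = build_representative(sample)  # elementwise median (here: midpoint)
for e in similarity_vector(sample, gr).entries:
    print(f"{e.sequence_id}: D = {e.D:.4f}, theta = {e.theta:.4f} rad")
```

prints

```
ProteinI 29 1
ProteinII 29 2
ProteinI: D = 2.0000, theta = 0.3670 rad
ProteinII: D = 2.0000, theta = 0.3552 rad
```

Each 30-residue sequence yields 29 ordered pairs; the pair ND occurs once in
ProteinI and twice in ProteinII. With only two members the median
representative is the midpoint of the two descriptors, so both members are
equidistant (equal D) while θ still resolves which member's pair
*composition* is closer to the consensus direction.

The `examples/` directory holds one short narrative script per capability
(worked example, synthetic families, cross-group comparison, pairwise
matrix, class-coherence report); each prints the numbers it computes and a
line on what they mean.

## Command line

A thin CLI wraps the library:

```
grvec fixtures -o fx                 # write built-in + synthetic FASTA fixtures
grvec compute fx/family0.fasta       # 400-column adjacency table
grvec represent fx/family0.fasta -o gr.tsv
grvec similarity fx/family0.fasta -o run/
grvec crossgroup fx/family1.fasta gr.tsv
grvec matrix fx/family0.fasta -o m.tsv --metric theta [--phylip]
grvec report fx/family0.fasta fx/group_map.tsv -o run/
```

All verbs accept `--policy {strict,mask,drop}` for residues outside the
20-letter alphabet, `--normalize {none,unit,length}` (exploratory scalings
of D), and `--precision`.

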