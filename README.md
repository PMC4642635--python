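# hapshare

Haplotype-sharing measures of genomic relatedness for diploid genomes, with
the pedigree and marker-based comparators they are usually judged against.

Most molecular relatedness estimators are genome-wide averages of
single-SNP statistics and ignore how long the genomic regions shared by two
individuals are. `hapshare` instead divides the genome into `p` intervals
and the possible variant DNA strings per interval into *segments*, so a
diploid genome is a multiset of `2p` segments (two per interval, one per
haplotype). The segmentation comes from an acyclic probabilistic finite
automaton (APFA) — the haplotype-cluster model underlying Beagle — whose
edges *are* the segments: haplotypes traversing the same edge share the
same DNA in that interval.

With `x_is ∈ {0,1,2}` the multiplicity of segment `s` in genome `i` (the
N×|E| haplomarker design matrix `X`), the package computes:

* **intersect measure** `b_ij = Σ_s min(x_is, x_js) / 2p` — the fraction of
  genome shared; `b_ii = 1`, `0 ≤ b_ij ≤ 1`;
* **product measure** `c_ij = Σ_s x_is x_js / 2p = (XXᵀ/2p)_ij` — twice the
  identity-by-state coancestry off the diagonal and `1 + f_i` on it, where
  `f_i` is IBS inbreeding (homozygosity); linked to B by
  `c_ij = 2 b_ij − κ_ij` with `κ` the shared heterozygosity;
* **pedigree numerator matrix** `A` (recursive tabular method), pedigree
  shortest-path distances, and **vanRaden's G** from unphased genotypes;
* a **hybrid matrix** `R` equal to realized genomic values on a genotyped
  subset `S` and pedigree-propagated expectations elsewhere, plus the
  covariance **conditioning operator** `A|A*₁₁` (replace a subgroup's
  marginal covariance, preserve the rest's conditional covariance) and a
  replicated consistency check built on it;
* a **meiosis simulator** (gene-drop through arbitrary pedigrees on an APFA
  segment pool) that verifies the exact offspring-expectation identities
  `E(c_ik) = (c_ii + c_ij)/2`, `E(c_kk) = 1 + c_ij/2`, `E(f_k) = c_ij/2`,
  `E(c_kh) = (c_ih + c_jh)/2`, `E(b_ik) = 1/2 + c_ij/4` — identities that
  hold for *any* gamete partition, verified by exhaustive enumeration of
  the four equiprobable gamete combinations;
* weighted variants of B and C, and a `−log b` distance with classical
  principal coordinates for visualising population structure.

Intended users: quantitative and population geneticists building
relationship matrices for genomic prediction, parentage or conservation
work from phased SNP data.

## Worked example

A 20-interval trio: both parents heterozygous everywhere (`c_ii = 1`),
sharing 30 of their 40 segment copies (`c_ij = 0.75`); the offspring
carries the same segment on both haplotypes at 9 of 20 intervals.

```python
import numpy as np
from hapshare import (Apfa, Edge, Genome, design_matrix, product_measure,
                      homozygosity, exact_expectation)
from hapshare.simulate import GametePair

p = 20
vertices = {f"V{k}": k for k in range(p + 1)}
edges = tuple(Edge(f"L{k}E{a}", k, f"V{k}", f"V{k+1}", str(a), 0.25)
              for k in range(p) for a in range(4))
apfa = Apfa(p, vertices, edges)
s = lambda k, a: f"L{k}E{a}"

mother = Genome("mother", tuple(s(k, 0) for k in range(p)),
                          tuple(s(k, 1) for k in range(p)))
father = Genome("father", tuple(s(k, 0) for k in range(p)),
                          tuple(s(k, 1) if k < 10 else s(k, 2) for k in range(p)))
child  = Genome("child",  tuple(s(k, 0) for k in range(p)),
                          tuple(s(k, 0) if k < 9 else s(k, 1) for k in range(p)))

X = design_matrix([mother, father, child], apfa)
C = product_measure(X)
print(C.loc("mother", "father"))        # 0.75
print(homozygosity(X)["child"])         # 0.45
print(C.loc("child", "child"))          # 1.45   (= 1 + f)
print((C.loc("mother", "mother") + C.loc("mother", "father")) / 2)  # 0.875
```

Output:

```
0.75
0.45
1.45
0.875
```

The last number is the expected parent–offspring product measure
`(c_ii + c_ij)/2`: for parents this related, a future offspring is
expected to have `c = 0.875` with each parent, and `c_kk = 1 + 0.75/2 =
1.375` with itself — regardless of how meiosis happens to partition the
parental genomes, as `exact_expectation` verifies by enumerating the four
gamete combinations.

## Command line

One binary with subcommands mirroring the library:

```sh
hapshare simulate   --apfa model.tsv --pedigree ped.tsv --seed 7 --out-prefix sim
hapshare build-apfa --haplotypes sim.haplotypes.tsv -o trie.tsv
hapshare cmatrix    --haplotypes sim.haplotypes.tsv --apfa model.tsv -o C.tsv
hapshare amatrix    --pedigree ped.tsv -o A.tsv
hapshare compare    --matrix1 A.tsv --matrix2 C.tsv
hapshare consistency --matrix A.tsv --realized C.tsv --group1-size 10 \
                     --replicates 10 --seed 1 -o consistency.tsv
```

All stochastic subcommands require `--seed` and are byte-deterministic.
Formats are plain TSV (phased haplotype tables, pedigrees, matrices), a
native APFA edge list, a Beagle-3-style DAG dialect, and phased VCF.

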