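# Methods

## Model

The genome is divided into `p` physical intervals; the variant DNA strings
that can occupy an interval are its *segments*, and segments of different
intervals never coincide. A diploid genome is then a multiset of `2p`
segments — two per interval, one from each haplotype — with multiplicities
in {0, 1, 2}. Relatedness is similarity between these multisets:

* intersect measure `b_ij = |G_i ∩ G_j| / 2p` (element-wise minimum of
  multiplicities): the fraction of genome shared;
* product measure `c_ij = |G_i × G_j| / 2p` (element-wise product):
  `c_ij = 2ϑ_ij`, twice the identity-by-state coancestry, and
  `c_ii = 1 + ϑ_i` with `ϑ_i` the IBS inbreeding coefficient. This makes C
  the IBS analogue of the pedigree numerator matrix A (`a_ij = 2θ_ij`,
  `a_ii = 1 + θ_i`, θ the IBD coefficients).

The two are linked through the shared heterozygosity
`κ_ij = #{s : x_is = x_js = 1}/2p` by `c_ij = 2 b_ij − κ_ij`, which follows
from `xy = 2·min(x, y) − I(x = y = 1)` on {0, 1, 2}.

The segmentation is supplied by an acyclic probabilistic finite automaton:
a leveled directed multigraph with one root (level 0) and one sink (level
`p`), edges carrying an allele symbol and a transition probability,
outgoing probabilities summing to one per vertex. Haplotypes are
root-to-sink paths; their probability is the product of edge
probabilities. Identifying segments with edges asserts that haplotypes
traversing the same edge are IBS in that interval — a strong assumption
whose quality depends on the fitted model; an overly coarse automaton
(small training data) overstates sharing.

Fitting the automaton is model selection and is out of scope here. The
package ingests externally fitted models (a native TSV edge list, or a
Beagle-3-style DAG dialect whose per-parent counts are normalized to
probabilities) and offers `build_trie_apfa`, a deliberately minimal
prefix-tree constructor that assigns every training haplotype its
empirical frequency. It produces a maximally specific segmentation — no
sharing beyond exact prefix identity — and is intended for fixtures and
end-to-end pipelines, not as a statistical model of linkage disequilibrium.

## Expected relatedness and the hybrid matrix

Meiosis partitions a parent genome into two complementary gametes of `p`
segments; an offspring takes one gamete from each parent, the four
combinations equiprobable. Averaging any of the offspring measures over
those four combinations gives expectations that depend only on the
parental measures — not on the partition itself:

    E(c_ik) = (c_ii + c_ij)/2      E(c_kk) = 1 + c_ij/2     E(f_k) = c_ij/2
    E(c_kh) = (c_ih + c_jh)/2      E(b_ik) = E(b_jk) = 1/2 + c_ij/4

`exact_expectation` enumerates the four combinations for an arbitrary
user-supplied partition with integer accumulation, so the test of the
invariance claim is exact (bitwise identical across partitions). No closed
form is known for the four-individual intersect expectation `E(b_kh)`; the
package only estimates it by Monte Carlo.

Because the first four identities are precisely the recursions of the
numerator-matrix tabular method, seeding that recursion with realized
genomic values on a genotyped subset `S` yields the hybrid matrix `R`:
`r_ij = c_ij` within `S`, and in topological order `r_kk = 1 + r_ij/2`,
`r_hk = (r_ih + r_jh)/2` (parents i, j of k; unknown parents contribute
`r = 0`, exactly). `S = ∅` reproduces A; `S` = everyone reproduces C. This
adjusts expectations *downstream* of `S`; the complementary route that
adjusts everything outside `S` is covariance conditioning.

## Conditioning `A | A*₁₁`

Treating a relationship matrix as a covariance, the operator replaces the
marginal covariance of group one by `A*₁₁` while preserving the
conditional covariance of group two given group one. The defining contract
is the precision-matrix increment `E = (A*₁₁)⁻¹ − (A₁₁)⁻¹` added to the
group-one block only. The implementation never forms inverses: with
`Z = A₁₁⁻¹A₁₂` from a Cholesky solve,

    Ã₁₁ = A*₁₁,  Ã₁₂ = A*₁₁ Z,  Ã₂₂ = A₂₂ − A₁₂ᵀZ + Zᵀ A*₁₁ Z,

which is algebraically identical to the increment form (a unit test checks
element-wise agreement with explicit inverses on random SPD matrices). The
result is verified positive definite by Cholesky; failures raise rather
than returning an indefinite "covariance".

The consistency check replicates: sample group one uniformly without
replacement, form `A|X₁₁` for a realized measure X, and regress the
group-two off-diagonals of X on those of the conditioned matrix. If X
differs from A only through the founder assumptions behind A (founders
unrelated, non-inbred), the no-intercept slope is close to one.

## vanRaden's G

`g_ij = Σ_k (m_ik − m̄_k)(m_jk − m̄_k) / D` with genotypes in {0, 1, 2} and
`m̄_k` the sample mean genotype. The scaling `D` is ambiguous when written
in terms of `m̄_k ∈ [0, 2]`: `Σ 2m̄_k(1 − m̄_k)` can be negative. The
default therefore uses the allele frequency `p̂_k = m̄_k/2`,
`D = Σ_k 2p̂_k(1 − p̂_k)` — the standard method-1 scaling, always positive
for polymorphic markers — while `denominator="genotype-mean"` exposes the
literal alternative for comparison. Markers with no variation across the
sample are a hard error by default (`drop_monomorphic=True` removes them);
silent NaN propagation is worse than refusing. Sample-mean centering makes
every row of G sum to zero exactly.

Matrix comparison statistics (mean squared deviation and adjusted R² with
and without intercept) are computed over distinct off-diagonal pairs by
closed-form least squares, regressing the reference (first) matrix on the
second; the adjusted-R² conventions match statsmodels and are cross-checked
against it in the tests.

## Simulator: what it emulates and what it does not

The gene-drop simulator samples founder genomes as pairs of
probability-weighted APFA paths (or accepts explicit founder genomes) and
produces descendants by simulated meiosis in topological order. The
crossover model is the simplest process satisfying the gamete axioms: the
gamete starts on a uniformly chosen parental haplotype and switches source
independently with probability `r` at each interval boundary (default
`r = 0.05`, a light map-free rate). Because every verified expectation is
invariant to the partition process, the choice of `r` affects only
variances, never the tested means. An individual with exactly one recorded
parent receives one gamete from that parent and one fresh APFA-sampled
haplotype for the unknown side, consistent with the `r = 0` convention for
unknown parents.

Not emulated: crossover interference, sex-specific or physical genetic
maps, mutation, gene conversion, selection, genotyping or phasing error,
multi-chromosome genomes (use one APFA per chromosome with globally unique
segment ids and pooled intervals), and polyploidy. Passing tests therefore
demonstrate the algebraic and distributional properties of the measures
under idealized segregation on a correct segmentation — not robustness to
phasing error or to misspecified automata, which real data would add.

For vanRaden's G inside `monte_carlo_expectations`, marker dosages are
derived from edge allele symbols with "0" as the reference allele (dosage =
count of non-"0" alleles); monomorphic simulated markers are dropped, and G
is reported as NaN when fewer than two polymorphic markers remain.

## Numerical choices

* Multiplicity sums are accumulated as 64-bit integers and divided once,
  so `C = 2B − κ` and `C = XXᵀ/2p` are exact at the integer level; after
  the single division, agreement is within one ulp (the test tolerance is
  1e-14/1e-15 where the two sides divide by different denominators).
* Weighted measures (`Σ_s w_{l(s)}·… / 2`, weights non-negative summing to
  one within 1e-9) route uniform weight vectors through the integer path
  scaled by `p·w`, so `w_k = 1/p` reproduces the unweighted measures
  bitwise whenever `fl(1/p)·p = 1` in double precision (all `p` used here).
* Outgoing-probability normalization tolerance is 1e-9. Operations that
  need probabilities (path probability, founder sampling) reject invalid
  models; purely combinatorial ones (B, C, κ, f) need only edge identities
  and accept them.
* Haplotype tracing through a multigraph resolves duplicate allele symbols
  on outgoing edges by higher probability, ties by lexicographic edge id,
  with a warning — deterministic by construction.
* Topological sorting uses Kahn's algorithm with ties broken by input
  order, so every matrix is reproducible for a given input file.
* Matrix files default to 17 significant digits and are parsed with
  round-trip float precision, so file round trips are bitwise stable.
* Classical scaling (principal coordinates) clamps negative eigenvalues to
  zero in the returned coordinates and refuses non-finite distances
  (`b = 0` pairs map to infinite `−log b` distance and must be handled
  upstream).

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
worked-example trios at `p = 20`, random-genome oracles at `p ≤ 10` with
up to 15 individuals, a 50-individual pedigree against a 100 000-replicate
gene-drop oracle, 1000-meiosis Monte-Carlo recovery, and a 30-individual
consistency study. All computations are dense `O(N²|E|)`; the algorithms
themselves scale to thousands of individuals.

## Known limitations

* The IBS interpretation of C inherits the assumption that same-edge ⇒
  same DNA; with a poor segmentation the measures overstate relatedness.
* `build_trie_apfa` is not a linkage-disequilibrium model; use externally
  fitted automata for real data.
* The Beagle DAG dialect accepted here is one plausible layout
  (level, parent, child, allele, count with `#` comments); other dialects
  can be added behind the same `Apfa` type.
* No closed form for `E(b_kh)` across four individuals; Monte Carlo only.
* Diploid only; multiplicities above 2 are rejected by construction.
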