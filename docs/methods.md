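# Methods

## Scope and design

The package reimplements, as a tested library, the desk analysis of
sex-biased microRNA expression and chromosomal distribution in a *Drosophila*
species pair: differential expression between sexes, cross-species homology
grouping of hairpin loci, genomic clustering, Muller-element synteny, and
rank-based factorial tests of fold-change by evolutionary age and chromosomal
context. Raw-read processing (trimming, mapping, counting) is out of scope:
the entry point is a count table plus locus annotation, or the synthetic
generator. All coordinates are 1-based inclusive; all randomness flows from a
single seed through per-stage `numpy` generator streams, and reruns are
byte-identical.

## Differential expression

The paired study design is two sequencing batches, each containing one male
and one female library. Counts are normalized by per-sample size factors:

- **Median of ratios**: s_j = median over loci of c_ij / (∏_j c_ij)^{1/n},
  computed on loci positive in every sample and rescaled to geometric mean 1.
  An optional pseudo-reference fallback uses geometric means over positive
  counts when no locus is everywhere-positive (off by default).
- **TMM**: log2 factors are trimmed (30% on M, 5% on A), inverse-variance
  weighted means of M-values against a reference sample. The weights are
  delta-method binomial variances evaluated on count proportions at a common
  nominal depth, which makes the factors exactly equivariant when a single
  sample is rescaled.

Loci enter the fold-change analyses when they have at least one raw read in
at least one sample of each sex and a base mean (mean median-of-ratios
normalized count, regardless of which normalization feeds the model) of at
least 1.

Per locus, ordinary least squares is fitted to y = log2(normalized count +
0.5) with intercept, batch indicators (paired design) and a male indicator;
the sex coefficient is log2(male/female). This single transparent model
stands in for the NB-GLM/voom pair of the conventional pipelines; its
fold-changes correlate > 0.95 with a naive normalized mean-ratio estimator on
simulated data, which is the property the downstream comparative analyses
rely on. The unpaired design drops the batch term. Rank-deficient designs
(sex confounded with batch) are rejected with an explicit error.

Significance uses an empirical-Bayes moderated t: per-locus variances s² with
d residual df are shrunk toward a prior, s²_post = (d₀s₀² + d s²)/(d₀ + d),
t = log2FC / (s_post √v), referred to t(d₀ + d). The prior (d₀, s₀²) is
estimated by method of moments on e = log s² − ψ(d/2) + log(d/2); when ≥ 10
loci are available s₀² follows a lowess trend in average log2 abundance
rather than a constant, because count data put systematically more variance
on weakly expressed loci and a flat prior then miscalibrates the tails by
abundance. The lowess is deliberately **non-robust** (no reweighting
iterations): e is left-skewed (log chi-square), robust iterations track its
median while the ψ offset assumes its mean, which inflates the prior ~9% and
makes the test conservative (measured type-I 0.034 instead of 0.05 at α =
0.05). With the mean-tracking smooth the null type-I error is 0.047–0.055 on
both ideal normal data and NB simulations. Multiplicity is handled by
Benjamini–Hochberg (NaNs propagate and do not count toward m). A locus is
called biased when q < 0.10 and |log2FC| ≥ log2 1.25 (both boundaries as
stated: strict on q, inclusive on the fold-change); a stricter FDR of 0.05 is
reported alongside.

## Homology

Hairpins are compared all-against-all with a word-seeded Smith–Waterman:
pairs sharing no exact 10-mer are skipped, survivors are scored by exact
affine-gap dynamic programming (numba), so seeded scores equal exhaustive
ones whenever any seed exists and never exceed them. Default scoring is
match +1, mismatch −2, gap open −5, gap extend −2 (conservative,
blastn-like; a gap of length L costs open + (L−1)·extend). `N` never
matches.

E-values follow ungapped Karlin–Altschul theory, E = K·m·n·exp(−λS). λ is
the positive root of E[e^{λX}] = 1 for the per-site score under uniform base
composition; K is evaluated by the Karlin–Dembo renewal series via exact
lattice convolution and reproduces the published ungapped blastn constants
(+1/−2 → λ = 1.333, K = 0.621). For the cross-species search, m·n is the
**whole search space** (total query length × total subject length), the
standard database-search interpretation: it is symmetric in the direction of
the comparison, and it prevents a bare chance 10-mer between two ~100-nt
hairpins (pairwise E ≈ 0.01) from entering the graph — with per-pair E-values
such chance edges chain unrelated families into mega-components. Gapped
scores are assessed with these ungapped parameters, an approximation; the
thresholds (pairing E ≤ 0.1; genome-scan E ≤ 0.01 with alignment length
≥ 60) are configurable to compensate.

Hits are edges of an undirected graph over all loci of both species; manual
ortholog overrides can add curated edges. Connected components are the
homology groups, classified one-to-one / one-to-many / many-to-many /
unpaired by per-species member counts. For groups of three or more members a
neighbor-joining tree (Saitou–Nei Q-criterion, branch lengths by the split
formula, negative lengths clamped to 0, ties broken lexicographically) is
built on uncorrected p-distances (mismatches over non-gap columns of a global
alignment under the same scoring family). Newick output is canonical:
children ordered by smallest leaf label, branch lengths at full precision.

## Comparative genomics

Clusters are single-linkage runs of same-chromosome loci with boundary gaps
(next.start − prev.end − 1) of at most 10 000 bp, inclusive at exactly
10 kb — the most permissive reading of "within 10 kb". Each cluster is
represented by its highest-base-mean member; ties break to the
lexicographically smallest id. Translocation detection compares Muller
element letters of ortholog pairs (robust to arm renaming: XL/XR are elements
A/D); pairs with an unknown element are excluded and counted separately. The
cross-species bias comparison pairs log2 fold-changes of one-to-one groups
whose members passed the expression filter in both species, stratified by the
species-2 chromosome class (neo-X / other X / autosome), and fits ordinary
least-squares lines per stratum.

## Rank tests

The Scheirer–Ray–Hare test is a two-factor extension of Kruskal–Wallis:
values are jointly mid-ranked, two-way sums of squares are computed on the
ranks (type II via model comparisons — each main effect adjusted for the
other — the standard choice for unbalanced layouts such as few X-linked novel
loci), and H = SS_effect / MS_total with MS_total = SS_total/(N−1) is
referred to χ² on (a−1), (b−1), (a−1)(b−1) df. Because MS_total is the
realized rank variance, tie correction is implicit; the classical correction
factor is still reported. The interaction is computed by default and dropped
with a warning when cells are empty; a main-effects-only mode exists. With
one factor omitted the statistic reduces exactly to tie-corrected
Kruskal–Wallis, which the package also implements independently via the
textbook rank-sum formula so the two routes can check each other. All-equal
values yield H = 0, p = 1 by convention. Measured null rejection at α = 0.05
is 0.047–0.052 over 10 000 balanced 2×2 replicates.

## Synthetic studies

The generator emulates the study design, not real genomes. Species 2 (the
focal species) carries `n_loci` hairpin loci in `n_clusters` clusters laid
out so that within-cluster neighbour gaps are < 10 kb and clusters are
separated by > `intercluster_gap_bp` (> 10 kb required); species 1 carries
the conserved families on the chromosome of the same Muller element. Defaults:
150 loci, 30 clusters, 25% novel (species-2-specific), 30% of clusters on
X-linked elements (species 2's X = elements A and D, D being the neo-X).
A small fraction (5%) of conserved families is tandem-duplicated in species
2, producing one-to-many groups. Exactly `translocation_count` one-to-one
families are planted on a different element in species 2.

Sequences: each family descends from a random ancestor of 60–150 nt (GC 0.5)
mutated independently in each lineage at `substitution_rate` per site
(default 0.05; ≥ 0.5 is rejected as it destroys the homology signal by
design); novel loci are fresh random sequence.

Counts are negative binomial with var = μ + μ²·φ, global dispersion φ = 0.1
(a single global value keeps recovery tests interpretable; real data have
gene-wise dispersions). log2 mean = per-locus base (Normal(6, 2)) + per-locus
batch coefficient + sex effect for male samples, scaled by per-sample library
factors drawn log-uniformly from [0.5, 2]. `batch_effect_log2` (default 0.5)
is the standard deviation of per-locus batch coefficients — a batch shift
common to all loci would be absorbed by normalization and make the batch term
vacuous. Sex effects: novel X-linked loci get the full planted effect
(default 1.5 log2 units), novel autosomal loci half of it (young microRNAs
are male-biased as a class, most strongly on the X), and conserved families
share a Normal(0, 0.75) effect across both species' copies, which is what
makes cross-species fold-change conservation measurable. Two replicates per
sex in two paired batches mirror the focal study design; a gonad mode labels
the samples testis/ovary. Dispersions below 1e-6 switch to the Poisson limit.

What the generator does **not** emulate: secondary structure, read-level
noise, genome assembly artifacts, gene-wise dispersion, and expression
correlation within clusters beyond the planted family effects. Passing tests
therefore validate the algorithms against their own model assumptions, not
against the vagaries of real libraries.

## Numerical and test-design choices

- Problem sizes: null calibration uses 14 simulated studies of 420 loci at 3
  replicates/sex (~6 000 locus tests); fold-change recovery uses 50 studies
  of 150 loci with dispersion 0.005 and mean counts ≳ 100 — the spec of a
  clean recovery experiment, since at dispersion 0.1 the sampling SE of a
  log2 fold-change at n = 3/sex is ~0.38 and no estimator could put 90% of
  estimates within ±0.3.
- Recovery experiments plant effects against an otherwise-null background
  (10% of loci biased): median-of-ratios normalization is composition-biased
  when a large one-sided fraction of loci is differentially expressed (~−0.2
  log2 units at 25% planted male bias; verified to vanish with the true
  size factors). This sensitivity is inherent to ratio-median normalization,
  not to this implementation.
- The trigamma inverse for d₀ uses Newton iteration from the asymptotic
  start 1/y + 0.5; variances are floored at 1e-8 before moderation.
- NJ ties and newick ordering are broken lexicographically so outputs are
  canonical; negative NJ branch lengths are clamped to zero.
- Alignment oracles in the tests are external (Biopython's PairwiseAligner
  for local scores, scikit-bio for NJ topologies), keeping implementation and
  oracle independent.

## Known limitations

- E-values borrow ungapped (λ, K) for gapped scores; absolute E-values are
  approximate, so threshold choices matter more than their nominal scale.
- The expression model is a log-linear stand-in: it does not model NB
  dispersion per locus and is not intended for small-count inference beyond
  the calibrated moderated test.
- The SRH chi-square reference is asymptotic; very small or very unbalanced
  layouts should use the permutation check shown in the tests.
- `uncorrected_distance` uses one optimal global alignment; among co-optimal
  alignments the mismatch count may differ slightly.
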