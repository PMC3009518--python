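# Methods

## Scope and assumptions

`fhapminer` targets candidate-gene regions of densely linked SNPs analyzed
in nuclear and multi-generation families. Its central assumption is **zero
recombination within a family across the region**: each child inherits one
entire parental haplotype per parent. For regions of a few megabases and
family sizes of realistic studies, within-family recombinants are rare
enough that this is the standard working assumption; data that violate it
(or contain genotyping errors) surface as families with *no* consistent
configuration, which the pipeline excludes with a logged warning rather
than silently repairing.

Other standing assumptions: complete genotypes (no missing alleles inside
the phaser), loop-free pedigrees (marriage loops and inbreeding are
rejected at validation), autosomal biallelic-or-multiallelic markers coded
as positive integers, and binary phenotypes coded 1/0 (the scoring
machinery accepts continuous traits unchanged).

## Zero-recombination phasing

With one inheritance variable *h* per parent–child edge and one phase
variable *p* per undetermined heterozygous founder locus, every genotype
constraint is affine over GF(2): a child's received allele at a locus is a
constant when the parent is homozygous there, and otherwise the parent's
first-haplotype allele XOR *h*. Collecting these constraints over all
children and loci and row-reducing gives a particular solution plus a set
of free binary variables α; the solution space has exactly 2^dof
configurations, all materializable or uniformly sampleable.

Two canonicalization rules make the count well defined by removing exact
symmetries:

* within each founder, the first heterozygous locus places the smaller
  allele on the designated-first haplotype (removes the per-founder
  haplotype swap);
* the *h* of an edge whose parent is homozygous at every locus is pinned
  to 0 (descent through two identical haplotypes is unobservable; without
  this rule an all-homozygous family would count 2^edges label-permuted but
  string-identical solutions).

The engine is plain Gaussian elimination over bitmask integers rather than
a union-find structure: constraints that chain through several generations
involve more than two variables, and elimination handles the general case
in negligible time at pedigree scale (≲ 200 variables). Correctness is
pinned by an exhaustive-enumeration oracle: on 1,000 random gene-dropped
pedigrees the solver's solution set equals brute force over all founder
phases × inheritance choices.

When several configurations exist the pipeline draws one uniformly
(reproducibly, from a named substream). This ignores population haplotype
frequencies, which would prefer some configurations over others; a
likelihood-ranked choice is out of scope.

## Founder haplotype scores

The default score is the mean-deviation form
s_ik = Σ_j c_ij (Y_ij − Ȳ_i) with c_ij the *copy count* (0/1/2) of founder
haplotype h_ik in member j. Copy counting, rather than a carrier indicator,
is what makes Σ_k s_ik = 0 hold exactly within each family — each member
contributes its deviation once per haplotype slot — including
homozygous-by-descent carriers. Members with missing phenotypes drop out of
both the mean and the sums. The score is *not* normalized by carrier count;
a haplotype carried by many affecteds accumulates a larger score, which is
the intended weighting.

An alternative ratio score,
s_ik = (Σ c_ij I(Y_ij ≥ t) + ½) / (Σ c_ij I(Y_ij < t) + ½),
with threshold *t* and half pseudocounts, is available behind
`measure="relative-risk"`. Its exact published form is not recoverable from
the sources we reconstruct it from, so it is a declared reconstruction:
selectable, tested for its stated properties, but not the default and not
claimed to match any published number.

## Similarity, clustering, Q-score

At focal marker *m* with window *W* (clipped at chromosome ends, never
padded; even *W* takes the extra marker on the right), two segments score
S = w_L·L + w_N·N where N counts matching alleles in the window and L is
the longest run of consecutive matches containing the focal position (0 on
a focal mismatch). Defaults w_L = w_N = 1; L is measured in markers, not
cM (map distance is reserved for mapping-precision reporting). W defaults
to 1 for single-locus studies and 10 for haplotype studies.

Clusters are DBSCAN groups under the distance d = S_max − S with
MinPts = max(2, ⌈0.05 n⌉) and a reachability radius expressed as a minimum
similarity fraction of S_max (default 0.8); both are configuration keys
recorded in every experiment log. d is not a metric and DBSCAN does not
need it to be. Clustering depends only on the haplotypes, so the scan
computes clusters once per marker and reuses them across permutations.

Each cluster with at least two members on *both* sides of the split is
tested; the marker reports its max-|Q| cluster (ties: smaller p, larger
cluster, lexicographically smallest member set). The default Q is the
**one-sample t of the cluster mean against the overall sample mean**. A
Welch cluster-vs-complement variant is selectable (`qscore="welch"`), but it
is anti-conservative in exactly the situation the max-|Q| rule loves: at a
low-MAF marker the majority-allele "cluster" contains all but a handful of
records, the tiny complement can have near-zero (sometimes exactly zero)
variance — e.g. the two identical records of a founder homozygous for a
rare haplotype — and the Welch statistic's small-variance limit produces
|Q| in the tens on null data. Measured over 3×100 null replicates the Welch
default gave family-wise rates of 0.04–0.14 at nominal 0.05, while the
one-sample form gave 0.00–0.02, consistent with the conservative behaviour
this class of methods reports; hence the default.

Family-wise control is Bonferroni over markers (one max-Q test per marker;
correcting additionally over clusters within a marker would be more
conservative still) or a permutation test on the genome-wide max |Q| with
scores shuffled against haplotypes. Under Bonferroni the adjusted p is
min(1, L·p_raw); permutation p-values are floored at the raw p so the
adjusted value never drops below it.

## TDT baseline

The single-locus comparison method counts, for every affected child with
genotyped parents at every SNP, one transmission per heterozygous parent:
b for the designated (numerically smaller) allele, c against, ½/½ for the
fully ambiguous all-heterozygous triple, and χ² = (b−c)²/(b+c) on 1 df with
Bonferroni over SNPs. Affected children in all generations count, each
parent–child transmission once — the standard TDT-as-linkage-test usage for
multigeneration pedigrees; no within-sibship correlation correction is
applied. The statistic is invariant to which allele is designated.

## Simulator

The simulator emulates the three-step design of family association studies:

1. **Structures.** CEPH-like skeletons: with probability 52/65 a
   three-generation family (4 grandparents, 2 parents, k grandchildren),
   else a couple with k children; k follows truncated negative binomials
   (r = 8, p = 0.5 on [1, 14] and r = 7, p = 0.5 on [2, 18]) chosen so
   sizes span 4–20 with long-run mean ≈ 13. A real structure file can
   replace the parametric model by building skeletons directly.
2. **Gene dropping.** Founders draw two haplotypes i.i.d. from a population
   frequency table; children inherit one whole haplotype per parent by fair
   coin; no recombination. The true configuration is retained as ground
   truth.
3. **Phenotypes.** Affected ~ Bernoulli(f_g), g ∈ {0,1,2} risk copies —
   either of the risk allele at a designated SNP (single-locus mode; the
   SNP is removed from data and map after phenotype assignment, so power
   reflects flanking LD) or of haplotypes in a designated rare-risk set.
   Families are retained only with ≥ 1 affected member, resampling until
   the target count is reached. The null model draws phenotypes
   Bernoulli(K) independent of genotype, with K the scenario prevalence of
   the configured penetrance set at risk frequency 0.1 (0.0995 for set C),
   and still applies ascertainment.

The bundled `synthetic_frequency_table` is a generated stand-in panel — 29
haplotypes over 19 SNPs, 22 rare rows sharing frequency 0.01786, rare
haplotypes derived as 1–2 SNP mutants of common backbones so the panel has
block-like LD. It reproduces those summary statistics of the
cystic-fibrosis-derived panel used in the literature but none of its actual
allele strings or map; numbers computed on it are therefore comparable in
character, not cell-by-cell, with published power tables. Quantities that
need the original haplotype frequency tables as input are covered instead
by property-level checks (saturated-signal power, method ordering on a
constructed rare-haplotype case, monotonicity in sample size).

What passing tests on simulated data do **not** show about real data:
robustness to missing genotypes, genotyping error, within-region
recombination, phenocopies with family-correlated environment, or
ascertainment schemes more complex than "≥ 1 affected".

Penetrance analytics assume Hardy–Weinberg proportions at the risk locus:
K = (1−p)²f₀ + 2p(1−p)f₁ + p²f₂, the genotype distribution among affecteds
is the Bayes inversion, and (λ₁, λ₂) = (f₁/f₀, f₂/f₀) (flagged infinite
when f₀ = 0). The built-in sets are A (0.05, 0.15, 0.25), B (0.01, 0.10,
0.15), C (0.05, 0.30, 0.50).

## Experiments and reproducibility

Power = fraction of replicates in which a method reports *any* marker
significant after correction at overall α = 0.05; detection and
localization are deliberately separated, with mapping precision (cM between
the lowest-p marker and the true risk locus, ties to the lowest marker
index) reported on the side. MAF groups default to Low < 0.13 ≤ Medium
< 0.30 ≤ High. Rare-haplotype power averages over random risk-set
selections per risk-set size.

All randomness flows from one root seed through named substreams
(structure / genedrop / phenotype / analysis) and per-replicate derived
seeds, so any table cell is exactly reproducible and independent of
replicate-level parallelism.

Default study sizes in the shipped tests and acceptance script — 100
replicates × 50 families for error calibration, 20–30 replicates for the
power properties, 1,000 pedigrees for the phasing oracle, 10,000 families
for score conservation — are the package's chosen desk-scale settings;
they keep the whole suite in the low minutes while leaving the statistical
assertions well-powered for the tolerances they state.

## Numerical and degenerate-input choices

* Q-score with zero variance in the tested group: (0, 1) when the means
  coincide, (±∞, 0) otherwise; clusters without two members on each side
  are not tested; a marker with no testable cluster reports p = 1.
* DBSCAN with an exact-match radius (eps = 0) uses an epsilon far below the
  similarity weight resolution, since the backend requires eps > 0.
* Frequency tables must sum to 1 within 1e-6 (renormalization is an
  explicit opt-in); sub-tolerance drift is rescaled away on read.
* Enumeration refuses to materialize more than 2^20 configurations per
  family; sampling remains available at any dof.
* Monomorphic SNPs are skipped (with a warning) as risk loci in power
  scans; b + c = 0 gives an explicitly flagged uninformative TDT result.

## Known limitations

* No missing-genotype handling, no recombination tolerance, no marriage
  loops in the phaser — such families are excluded, not imputed.
* Founder haplotypes are treated as independent across *and within*
  families in the pooled test; the within-family zero-sum constraint on
  scores is a mild dependence the t reference distribution ignores (the
  conservative one-sample default absorbs it in practice).
* Bonferroni over markers ignores LD between tests and is conservative;
  the permutation alternative is exact but costs B scans.
* The fixed window size is a user choice; nothing adapts it to local LD
  structure.
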