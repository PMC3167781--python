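# Methods

## The simulated cross

Genotypes are haploid mosaics of two parental alleles (BY = 0, RM = 1).
Along each of 16 chromosomes, a segregant's first marker allele is
Bernoulli(0.5) and the allele switches between adjacent markers with a
fixed per-interval probability (Haldane-like Markov recombination, no
interference; chromosomes independent). The default map places 2,955
markers uniformly within chromosomes whose lengths follow the budding
yeast karyotype (~12.1 Mb total), so 20-kb binning and basepair gap rules
operate at a realistic scale.

The default per-interval recombination probability is 0.0115. It is
calibrated to the one observable the study design fixes: among 2,955
markers typed on 95 segregants, 1,969 carried unique segregation
patterns. Under the Markov model two adjacent markers share a pattern
with probability (1−r)⁹⁵, so the expected unique-pattern count is
≈ 16 + 2,939·(1−(1−r)⁹⁵); solving for 1,969 gives r ≈ 0.0115. Simulated
panels land at 1,965–1,990 unique patterns. A marker that comes out
monomorphic is re-drawn iid Bernoulli(0.5) (bounded retries, then a hard
error); this breaks that one marker's local linkage but essentially never
triggers at n ≥ 10.

## The expression model

All expression is on the natural-log scale, so locus effects are additive
and a gene's fold variation is exp(max−min) of its segregant means. For
gene *g*, segregant *s*, biological replicate *b*:

    transcript_true(g,s,b) = a_T(g,s) + ε_T(g,s,b)
    protein_true(g,s,b)    = τ(g)·transcript_true(g,s,b) + a_P(g,s) + ε_P(g,s,b)
    observed               = true + technical noise per measurement

where `a_T` sums hotspot transcript effects (times the RM-allele
indicator at the marker nearest the hotspot) and any transcript-layer cis
effect at the marker nearest the gene; `a_P` collects direct protein
effects the same way; τ ∈ [0,1] is the per-gene **transmission** — the
fraction of transcript variation that propagates into the protein. With
τ = 0 the layers share nothing but (possibly) loci; with τ = 1 every
transcript fluctuation, biological noise included, reaches the protein.
The mediation test exists to distinguish `a_P`-type regulation from
τ-type regulation, so the generator keeps them strictly separate.

**Units.** Effect sizes are in units of the segregant-mean trait SD of a
null gene, `sd_ref = sqrt(bio_sd²/2 + tech_sd²/4)` for the 2×2 replicate
layout (≈ 0.186 log-units at the default bio_sd = 0.24, tech_sd = 0.15).
This keeps "a 1.5 SD effect" meaningful regardless of the noise settings.
In the noiseless limit sd_ref falls back to 1.0 (absolute log-units).

**Noise calibration.** bio_sd and tech_sd are set so that the median
across genes of the max/min fold change of segregant-mean transcripts is
≈ 2.7, the typical transcript variation in a cross of this kind;
simulated runs give 2.7–2.9. The 2:1.25 ratio of biological to technical
SD is a design choice — enough technical noise for the replicate
structure to matter, little enough that biological variation dominates.

**Default architecture.** 354 genes: 36 "ribosomal", 93 "amino_acid",
225 background. Two major hotspots (mid-chromosome 3 and 13) each add
+1.5 SD to every amino_acid *transcript* and −1.5 SD directly to every
ribosomal *protein* on the RM allele — diametrically opposed regulation
of the two communities through different channels. Four minor loci
(chromosomes 2, 5, 7, 15; +0.8 SD) act on ribosomal transcripts only,
giving that layer the many-loci/small-effect regulation that makes the
avoidance test meaningful: ribosomal proteins and ribosomal transcripts
are each strongly regulated, but by disjoint loci. Transmission is
U(0, 0.05) for ribosomal genes, high (U(0.8, 1)) for a configurable 25%
of amino_acid genes and U(0, 0.5) for the rest, U(0, 0.6) for background.
47 background genes carry +1.5 SD transcript-layer cis effects and 9
carry protein-layer cis effects (at the marker nearest the gene), making
transcript cis linkage several-fold more common than protein cis linkage.
Community and cis counts scale proportionally when a smaller panel is
requested.

**What the generator does not emulate.** (1) No strain-level random
effect beyond the modelled loci: all non-genetic biological variation
sits at the (strain × biological replicate) level, so simulated
heritabilities center near 0.45–0.50 rather than the ~0.70 typical of
real panels, where unmodelled polygenic background inflates
strain-to-strain variance. Tests that pass on these data therefore say
nothing about polygenic architectures. (2) Gaussian noise only — no
heavy tails, batch structure, or missingness (readers tolerate missing
replicates; the generator never produces them). (3) No epistasis, no
diploids, no measurement-intensity effects.

## Networks

Pair cutoffs follow the k-th-highest rule: with n_perm permutations at
false-positive rate f, the cutoff is the ⌈n_perm·f⌉-th highest permuted
r, and a pair connects iff observed r is *strictly* greater. Network
edges are upper-tail only; per-gene protein–transcript significance is
two-sided on |r| (genuinely negative correlations occur and should be
called). Permutations are uniform random by default; a cyclic-shift mode
(rotate segregant labels by 1, 2, …) exists for compatibility, with the
caveat that only n−1 distinct non-trivial rotations exist, so shifts
repeat beyond that. In the all-pairs build, each permutation round
shuffles every gene's labels independently and correlates shuffled
copies against originals, giving every pair one null draw per round —
marginally identical to the single-pair null at ~1/350th the cost; only
the top ⌈n_perm·f⌉ null values per pair are retained in memory.
Replicates collapse technical-within-biological, then biological, with
missing values ignored at each step, so biological replicates carry
equal weight under partial missingness. Permutations act on
segregant-mean traits, not replicate-level values.

The abundance-binned correlation (for across-gene protein-vs-transcript
comparisons) sorts genes by transcript abundance and greedily extends
each bin while the max/min ratio stays under 3.5; r is computed on log
abundances within bins; bins with < 3 genes are skipped and logged.

## Communities

Community construction percolates *maximal* cliques: maximal cliques of
size ≥ k whose pairwise overlap is ≥ k−1 are chained, and each chain's
node union is one community. This is equivalent to percolating all
k-cliques directly — adjacent k-cliques lie in maximal cliques
overlapping ≥ k−1, and any two maximal cliques overlapping ≥ k−1
contain adjacent k-cliques — and the test suite verifies the equivalence
exhaustively on random graphs alongside an independent library
implementation. Explicit k-clique enumeration is available for small
graphs and carries a hard cap with a loud error (CPM is exponential
worst-case; a silent stall would be worse). Overlapping communities are
reported as-is; an optional merge rule unions communities at one k whose
pairwise Jaccard overlap is ≥ 0.8 (default), reproducing the common
presentation of several near-identical communities as one. The exact
criterion is a package choice; raw CPM output is always kept. Enrichment
is the fold ratio (annotated fraction in community) / (annotated
fraction in background), with no attached p-value.

## Linkage

Markers with identical or fully complementary segregation patterns are
collapsed before scanning (the t test is sign-symmetric); the left-most
marker by genomic order represents its group, and representatives
provably carry identical test results for every member. t tests are
Welch by default (a pooled-variance flag exists); at ~47/48 per group the
difference is negligible, and Welch is the safer general choice.

The per-trait FDR threshold uses the empirical-null count ratio:
FDR(θ) = (mean permuted count of p ≤ θ over n_perm permutations) /
(observed count of p ≤ θ), maximised over the observed p-value grid
subject to FDR ≤ level. Two properties are worth knowing. First, with
n_perm = 100 the resolution is coarse (a warning fires below 20).
Second, the adaptive threshold is mildly anti-conservative under a
global null: the candidate θ equal to the trait's own minimum p is
declared significant whenever few permuted scans beat it, which happens
for roughly 5–10% of pure-noise traits. This is intrinsic to the
estimator (the same data pick the threshold and are judged by it). A
stricter genome-wide max-statistic threshold (the level-quantile of each
permutation scan's minimum p, family-wise control) is available behind
the `fdr_method` flag but is not the default, to keep the per-trait
character of the count-ratio procedure. Planted-effect
recovery is unaffected: 1.5-SD single-locus effects at n = 95 are
recovered within two markers of truth for ~99% of traits.

Significant markers on one chromosome merge into a locus when separated
by < 100 kb (unstated in the source procedure; 100 kb spans several
markers at ~25-kb spacing of unique patterns and is well under the
inter-hotspot distances that matter); the locus peak is the minimum-p
marker, left-most on ties. Hotspot histograms tile each chromosome with
half-open [start, start+20,000) bins from coordinate 0, ordered
chromosome 1→16; a linkage lands in the bin holding its peak marker.

Heritability is between-strain over total sum of squares,
H = Σᵢ nᵢ(x̄ᵢ−GM)² / Σⱼ (mⱼ−GM)², strains weighted by their available
measurement counts nᵢ, the denominator over all N measurements. It
equals the one-way-ANOVA SS ratio on balanced data (verified to 1e-9),
lies in [0,1], and is invariant to shifting or positively rescaling all
measurements. Variance explained is the two-group analogue and equals
the squared point-biserial correlation. No degrees-of-freedom correction
is applied in either — these are descriptive SS ratios, biased upward
for small replicate counts, matching their usual use in this setting.

**Avoidance test.** The statistic is the number of 20-kb bins holding at
least one protein linkage and at least one transcript linkage for the
gene subset of interest. The null redraws each layer's subset linkages
by sampling (without replacement) from that layer's full genome-wide
linkage-bin multiset, preserving subset sizes — i.e., it asks "if this
subset's linkages fell where this layer's linkages generally fall, how
often would the two layers share this few bins?" p_low counts
permutations with shared count ≤ observed (avoidance), p_high ≥ observed
(coincidence); ties count toward both and the resolution floor is
1/n_perm. The null scheme is a reconstruction — the source procedure
says only "permutation testing" — and its calibration is checked by a
dedicated study: under independent random linkage maps p_low is
approximately uniform (KS test across 200 runs). That calibration study
uses large maps (8,000 bins, 3,200 linkages per layer, subsets of 1,600)
because the shared-bin count is integer-valued and ties are counted in
p_low: with small maps the count distribution is narrow, ties are
common, and p_low is visibly super-uniform even though the test is valid
(conservative); wide count distributions make the discreteness
negligible.

## Mediation

OLS of protein on the gene's own transcript (segregant-mean traits);
residuals are orthogonal to the transcript and sum to zero, so residual
linkage measures regulation beyond anything transmitted through the
transcript. Classification is the binary loss-of-significance rule:
among linkages with original p < 0.05, a linkage is transcript_mediated
iff residual p ≥ 0.05. No Sobel-style product test is attempted —
the procedure is the published one, and partial attenuation remains
visible in the reported (−log₁₀ p_original, −log₁₀ p_residual) pairs
without receiving a label. All-zero residuals (protein an exact affine
function of transcript) return p = 1 with a degeneracy flag instead of
erroring, so noiseless synthetic pipelines complete. The residual
significance threshold is 0.05, the same level that defines the tested
set. On the default architecture, labels at the planted hotspot loci are
correct for ~96% of high-transmission no-direct-effect genes and ~100%
of direct-effect ribosomal genes; measured at FDR-scan peak markers
instead, the mediated fraction drops a few points because min-p peak
selection slightly biases the residual test — recovery is therefore
defined at the planted loci.

## Pipeline

One YAML config drives every stage; each stochastic stage has its own
seed, and a fixed config reproduces every output byte for byte (reports
carry a config hash and no timestamps). Stage outputs are plain TSVs so
any stage can be re-run standalone; report percentages follow the
whole-percent-at-≥10% / one-decimal-below rule, and expected counts are
reported raw and rounded. Problem sizes in the bundled studies (100
traits for QTL recovery, 20 seeds for mediation recovery, 200 runs for
avoidance calibration, 1,000 instances for the estimator identities) are
chosen so each study finishes in seconds-to-minutes on one core while
leaving binomial noise well inside the margins being asserted.
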