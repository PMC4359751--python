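# Methods

## Scope and data model

`metaclone` analyses somatic variation across the multiple metastases of
single patients: per-lesion SNV/indel calls with VAF and depth, integer
copy-number segments, purity/ploidy per lesion, interchromosomal
breakends, and optionally a log2 expression matrix with subtype
centroids. Upstream steps — alignment, variant calling, segmentation,
ploidy estimation, microarray normalisation and centroid derivation —
are out of scope and consumed as inputs.

Coordinates are 1-based inclusive on disk (VCF/SEG convention) and
0-based half-open for intervals internally; the conversion lives
entirely in `io_formats`. Variant identity is the exact
(chrom, pos, ref, alt) tuple; indel representations are not normalised
beyond what the caller emitted, trading recall for determinism. Mixed
`chr`-prefixed and bare chromosome names within one file are rejected
rather than silently harmonised. In VCF input the VAF comes from the AD
ratio, falling back to AF+DP; if both are present and disagree by more
than 0.01 the record is rejected, because silent disagreement between
caller fields is the classic corruption mode.

## Presence partitioning

A variant observed in one lesion is scored in each sister lesion as
*present* (same key called there), *absent* (site depth ≥ `min_depth`,
default 20, and alt fraction < `max_absent_vaf`, default 0.02) or
*unassessable*. The depth gate is this package's explicit rule — a
published absence criterion rarely exists — and both knobs are exposed.
Patterns with any unassessable lesion are categorised unassessable and
excluded from Venn counts (but reported); fully assessable patterns are
truncal, shared-subset or private. Patients with a single lesion are
rejected, matching the ≥2-lesion design the analysis presumes. Lowering
`min_depth` can only move calls out of *unassessable*, never flip
present/absent — a property the tests check.

Driver preservation: for a configurable driver set (default *BRAF*,
*NRAS*) every pattern where the driver is present in an earlier lesion
and affirmatively absent (not unassessable) in a later one is reported;
an empty report means preservation. A driver appearing only in a later
lesion is not a violation.

## Multiplicity and clonality

For a clonal mutation on `m` of `CN` tumour copies at purity ρ (germline
copy number 2, autosomes only — sex chromosomes are excluded):

    E[VAF] = m·ρ / (CN·ρ + 2·(1 − ρ))

`m̂` is the argmin over 1..CN of |VAF − E[VAF]|, ties broken toward
smaller m (conservative). A call is *clonal* when the residual is within
`tol` (default 0.10 on the VAF scale; a binomial-interval rule was
rejected to keep the criterion a single knob), else subclonal. A VAF
exceeding even the all-copies expectation plus `tol` raises a
*super-clonal* flag — usually misspecified purity or copy number — and
is never silent. Purity defaults to 1.0 and is overridable per lesion:
explicit beats hidden estimation.

Gene-level summaries sum `m̂` over inactivating hits (nonsense,
frameshift, splice-site); when the sum reaches the locus copy number the
gene is flagged biallelically inactivated. Hits spanning segments of
different CN use their own segment's CN and flag the summary `mixed-CN`
with the locus CN taken as the maximum (conservative for the biallelic
call). The argmin-plus-tolerance rule reproduces the canonical two-hit
worked example (VAFs 0.30 and 0.55 at CN 3 ⇒ 1 + 2 = 3 alleles) but the
exact decision rule is a design choice, since no standard exists.

## Substitution spectra and the window composition test

Substitutions are classified into the six strand-symmetric pair-notation
classes by normalising the mutated base to the pyrimidine strand. The
5′-pyrimidine fraction is computed over C:G→T:A sites only, reading the
flank on the pyrimidine-normalised strand (for a G reference allele the
flank is the complement of the base 3′ on the reference strand).
Variants whose stated reference base disagrees with the sequence are
dropped with a warning; a mismatch rate above 5 % aborts as a
wrong-genome-build error.

The context test compares mutated A/T sites against `n` (default 500)
coding A/T sites sampled uniformly without replacement. "10-position
window" is read as 2k flanking positions with default k = 5; k is
exposed because the informative positions (+1/+2) are detected either
way. Windows are oriented so the central base reads A
(reverse-complement when T); a `reference-strand` mode is provided since
strand handling is a genuine open choice. Sites lacking full ±k flanks
are dropped with a logged count. Each position yields a 4×2 base ×
group table. Because small mutated-set sizes (tens of sites) sit far
below chi-square comfort, the test is Monte-Carlo exact: with both
margins fixed, the permutation null of the mutated column is
multivariate hypergeometric on the pooled base totals, so the null
chi-square statistic is sampled directly (default 10⁵ draws, seeded; the
p-value uses the (1+b)/(B+1) estimator, so the minimum attainable p is
1/(B+1)). Raw p-values are Benjamini–Hochberg adjusted across the 2k
positions via statsmodels. Calibration: under the null the raw-p < 0.05
rate measures 0.048 over 5 000 position tests (500 replicates, seed 202
run of the test suite).

## Progression model

Fully assessable patterns are grouped by their presence subset. Subsets
are admitted into the tree in decreasing mutation-count order (ties by
lexicographic lesion order) subject to laminarity with the accepted
family — the structure a perfect phylogeny on presence/absence data
requires. Rejected (crossing) subsets' mutations are diverted to an
explicit conflict list; edge counts plus conflicts always equal the
number of assessable patterns. For ≤3 lesions this greedy rule is
provably optimal (only the three 2-subsets can pairwise cross, and they
are mutually exclusive), which the exhaustive laminar-family oracle
confirms on random instances. `min_edge_support` (default 1) optionally
gates internal nodes, since an internal clone asserted from very few
mutations may not deserve a node. Copy-number and rearrangement sharing
are annotated post hoc and never influence topology.

## Rearrangement support

Copy-number change points are the boundaries between adjacent segments
of unequal CN (the 1-based start of the later segment; a gap between
segments still yields one change point there). A breakend is supported
when at least one end (`either_end`, default) or both ends
(`both_ends`) lie within `tolerance_bp` (default 50 000) of a
same-chromosome change point in the same lesion. The defaults are this
package's choices — the integration idea fixes no distances — and both
are flags; filtering deliberately discards copy-number-neutral
rearrangements, which is the stated cost of the approach. Supported
calls are merged across lesions when chromosome pairs match and both
canonically oriented ends fall within `merge_window_bp` (default
10 000, union-find, order-independent), then categorised like point
mutations.

## Expression phenotypes

Nearest-centroid classification uses Pearson correlation on the
profile/centroid gene intersection (≥50 % of centroid genes required),
argmax over the four phenotypes, ties resolved by a fixed subtype order
with a warning. Centroid values are external input: their derivation
belongs to the upstream expression study, and the package ships only a
documented table format plus synthetic centroids in the generator.
Variable-gene selection takes the top ⌈fraction·G⌉ genes by variance
(default 75 %), ties broken by gene id. Neighbour concordance clusters
samples hierarchically (1 − Pearson, average linkage by default; both
are flags since no canonical choice exists) on the variable genes; a
patient is concordant when its lesions form a pure subtree (a weaker
adjacent-leaves mode is available), and concordance is cross-tabulated
against phenotype constancy with a two-sided Fisher exact test. The 2×2
construction (constant × neighbours over patients) is declared here, not
inferred from any external convention. Switch detection scans temporally
ordered subtype sequences for any change, for switches *into* the
proliferative phenotype, and for the never-expected switch *out* of it.
Private-burden comparison reports medians/ranges and a two-sided
Mann–Whitney p (exact for small untied samples, otherwise asymptotic
without continuity correction; the method used is reported).

## Synthetic cohorts

The generator is the package's testbed and defines its study
conditions. Genome: four named ~100 kb contigs with alternating 500 bp
coding blocks — small enough for seconds-scale end-to-end runs.
Mutation sites occupy disjoint 24 bp slots (≥13 bp apart) so planted
contexts never collide. Two substitution processes are written into the
FASTA itself, so sequence analyses exercise real lookups: a UV-type
process (P(C:G→T:A) = 0.9, P(5′ pyrimidine) = 0.9) and an alternative
process (P(A:T→G:C) = 0.8 with the +1/+2 base forced to G with
probability 0.9 on the A-normalised strand). Copy number: a shared
whole-contig hemizygous loss, a shared interval gain at CN 3 hosting a
planted two-hit tumour-suppressor pair (multiplicities 1 and 2), and
one private gain per lesion. VAFs are binomial at the expected VAF
given (m, CN, ρ) with Poisson depth (mean 200, in the range of deep
targeted panels); lesions lacking a mutation get background alt reads
at error rate 10⁻³ (a typical post-filter substitution error rate).
Breakends are placed at CN-event boundaries (supported) or on
event-free contigs (neutral). Expression profiles are centroid +
Gaussian noise at half the marker signal. The default 3-lesion
structure is 60 truncal / 2 subset-shared / 2, 8, 37 private;
`patient1_config()` switches to 63 truncal with the third lesion's
privates under the alternative process — the canonical
heavily-diverged-metastasis scenario.

What the generator does *not* emulate: indel realignment ambiguity,
mapping artefacts, contamination between lesions, subclonal copy
number, clustered mutational processes, batch effects in expression.
Passing recovery tests therefore demonstrates correctness of the
inference logic under the stated noise model, not robustness to every
real-data failure mode.

## Validation studies and problem sizes

`metaclone.validation` re-runs the pipeline on replicated simulations:
100 replicates of the diverged 3-lesion structure for clone-tree
topology recovery and +1/+2 context detection; 500 replicates of the
null (mutated sites drawn from the background) for type-I calibration;
400 binomial draws per (m ≤ CN ≤ 4, ρ ∈ {0.6, 0.8, 1.0}) cell at depth
1000 for multiplicity recovery; 200 random cohorts against the
exhaustive set-algebra partition oracle and 500 random 3-lesion
instances against the exhaustive laminar-family oracle. These sizes are
the package's choices for stable-yet-quick estimates; all studies take
an explicit seed and are reproducible. `scripts/acceptance.py` runs all
of them plus the worked examples and writes the numbers as JSON.

## Known limitations

* The absence rule is depth-gated but not statistically calibrated; at
  shallow depth (≲30×) the default `min_depth` of 20 leaves many sites
  unassessable, and the tests relax it accordingly.
* Clonality is a single-threshold rule, not a cancer-cell-fraction
  posterior; no subclone clustering is attempted.
* The clone tree uses presence/absence only; VAF-informed subclonal
  deconvolution within a lesion is out of scope.
* Only interchromosomal rearrangements are handled.
* With more than 3 lesions the greedy laminar construction is a
  heuristic (optimal only for ≤3); the package targets the 2–3 lesion
  design it was built for.
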