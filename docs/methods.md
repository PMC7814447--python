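# Methods

## Callset normalization

Calls from heterogeneous pipelines are made comparable by reducing every
record to a canonical biallelic key `(contig, pos, ref, alt)`:

1. **PASS filtering.** Only records whose FILTER column is exactly `PASS`
   enter the analysis; a bare `.` is *not* treated as PASS, deliberately —
   each pipeline's own acceptance criteria are respected rather than
   re-harmonized, and excluded records are counted in a skip log.
   Symbolic/breakend alleles are rejected at parse time.
2. **Multiallelic splitting.** One biallelic record per alternate allele;
   the genotype is recoded as the dosage of that allele (0/0, 0/1, 1/1).
   Records whose per-allele dosage is zero are dropped: a callset is the set
   of non-reference calls.  Half-calls (`./1`) carry the allele with dosage
   one.
3. **MNP decomposition.** Equal-length multi-base substitutions become one
   SNP per mismatching offset; matching offsets vanish.
4. **Indel left-alignment.** Shared trailing bases are trimmed, extending
   through the reference to the left when an allele would empty, then shared
   leading bases are trimmed; the loop stops at the contig start.  The
   output is parsimonious and leftmost.  A record whose ref allele
   contradicts the reference sequence is passed through with a warning
   rather than aborting a cohort run — real files occasionally carry
   build mismatches and one bad record should not kill 500 files.
5. **Deduplication.** Equivalent representations collapse to one key; the
   maximum depth is retained (deterministic and depth-conservative).

Variant identity is allele-aware but genotype-agnostic: two setups agree on
a variant when they call the same alt allele at the same normalized
position, irrespective of zygosity.  Normalization is idempotent, and
write/read round-trips through minimal VCF 4.2 preserve key sets exactly.

## Concordance measures

Venn partitions and pairwise Jaccard distances are computed **per
individual** and then averaged arithmetically across the cohort (not on
pooled unions): cohort-level statements are about the typical individual,
and per-individual computation keeps cohort size out of the set sizes.
SNPs and indels are analyzed separately throughout; MNPs cannot survive
normalization.  The Jaccard distance of two empty restricted sets is defined
as 0 (the identical-sets limit) with a warning, so stratified analyses on
tiny tracks never crash.

Region stratification assigns each variant by its **anchor base** (VCF pos,
0-based) against half-open BED intervals; an indel spanning a boundary
belongs to the region of its anchor.  This matches the usual semantics of
interval-intersection tools applied to VCF POS.

## Monte-Carlo enrichment test

Null model: the union of all calls is a base population of `N` exchangeable
variants; each setup independently draws its observed total uniformly
without replacement.  Sampling is implemented on subset-signature cells:
adding a setup splits each of the current `2^j` cells with a multivariate
hypergeometric draw.  This is distributionally identical to drawing explicit
item subsets (verified against full enumeration for small N) but costs
`O(reps · k · 2^k)` independent of `N`.

Because each setup's subset is independent and uniform, the per-item
inclusion probability is `p_i = n_i/N` independently across setups, so the
category means have the exact closed form `N·p_i·Π(1−p_j)` (uniques) and
`N·Π p_i` (intersection); the simulator is tested against this closed form
and against exact enumeration.

Reported per category: observed count, null mean, observed/mean ratio, and
a 95% CI from the 2.5th/97.5th percentiles of the per-rep ratios
`observed/expected_rep` (reps with a zero expected count are excluded with a
warning).  The chi-square goodness-of-fit uses the k unique categories, the
all-setups intersection, and a remainder category `N − Σ(uniques) −
intersection`, so both observed and expected totals sum to `N`; dof =
(number of categories with positive expectation) − 1.  The enrichment runs
on cohort-averaged counts (the scale on which the comparison's inputs are
published), with `reps = 1000` and a mandatory seed (default 20210119).

## MAF and exact HWE

Cohort merging treats the sparse VCF representation literally: an individual
without a record at a site — or with a fully missing genotype at it — is
homozygous reference.  MAF is `min(f, 1−f)` with `f` the alt-allele
frequency from genotype counts.

The Hardy-Weinberg test is the exact conditional test: conditioning on the
sample size and minor-allele count, the probability of a heterozygote count
h is proportional to `n! · 2^h / (h! · n_rare_hom! · n_common_hom!)`; the
two-sided p-value sums all configurations whose probability does not exceed
the observed one (no mid-p correction).  Implementation is log-space
(gammaln/logsumexp); tests compare it against exact integer-rational
enumeration for every table with n ≤ 50.  Note the test is conservative and
discrete: an all-heterozygote table only becomes significant at the 5% level
from n = 7 diploids onward.

The rare-variant set is the **conjunction** MAF < 0.05 AND HWE p < 0.05
(strict inequalities); a disjunction mode exists behind a flag for
sensitivity analysis.  Confidence labels come from anchor membership in the
high-confidence track; everything else is low-confidence.  Depth summaries
are five-number summaries over per-carrier depths, with missing depths
excluded and the count reported.

## GC binning

GC content is the fraction of G+C among unambiguous bases per fixed-size bin
(default 100 kbp; the last bin per contig may be short).  N and other
ambiguity codes are excluded from numerator and denominator — including them
would drag telomere/centromere-like bins toward artificial extremes — and
all-N bins get a missing fraction, excluded from quantiles and correlation.
Default class cutoffs are 37% (low/medium) and 47% (medium/high), medium
inclusive on both ends; a derive-from-quantiles mode recomputes the low
cutoff as the 30th percentile of the bin distribution and the high cutoff at
the 90th percentile (the midpoint between the low cutoff and the maximum
falls at an extreme ~95th percentile, which would starve the high class).
Variant-count/GC association uses Spearman rank correlation with
average-rank ties; constant inputs yield a missing coefficient.

## Synthetic cohort generator

The generator emulates the study design the analysis targets: a diploid
cohort (default 99 individuals) called under five setups with
setup-specific error profiles.  Defaults (2 contigs × 5 Mb; 0.65 SNP and
0.13 indel sites per kb; allele-frequency spectrum with a 35% rare
component uniform on (0.005, 0.05) and a common component uniform on
(0.05, 0.95); 2% of sites drawn with excess heterozygosity, F = −0.6) give
roughly 3,000 SNPs and 600 indels per individual — large enough for stable
Jaccard and enrichment statistics, small enough to generate and analyze in
well under a minute per cohort.

The reference is synthesized with a GC gradient (0.30 → 0.55 per 100-kb
window, so bins span all three GC classes), an exact exon/intron/intergenic
block partition, and implanted repeat families (Alu-like ~300 bp interspersed
copies with 8% per-copy divergence, LINE-like ~2 kb, LTR-like ~500 bp,
homopolymer-rich low-complexity stretches, and 2–6 bp STR expansions).  The
high-confidence track is the complement of the simple-repeat and
low-complexity tracks plus extra random low-confidence blocks (~8%).

Per-setup rendering imposes region effects directly through
per-(variant class, region class) sensitivity and false-positive rates
rather than simulating reads: the artifact tests the analysis, not a
caller, and desk-scale determinism matters.  False positives are Poisson
per Mb (a genome-wide baseline plus track-confined extras); genotypes flip
het↔hom with a small error rate; read depth is negative binomial with
separate (mean, dispersion) per confidence stratum; and representation
jitter re-emits a fraction of records denormalized (anchor-padded or
right-shifted indels, adjacent SNPs merged into MNPs, decoy alternate
alleles packed into multiallelic records) plus decoy non-PASS records — all
of which the normalization layer must undo exactly.

The five default profiles encode the qualitative structure the analysis is
meant to recover: `mol-gatk` and `hsx-gatk` share one profile (harmonized
reprocessing — they should be each other's nearest neighbours), and
`hsx-isaac` carries inflated indel false-positive rates confined to the
simple-repeat and Alu-like tracks (its unique-indel enrichment ratio should
exceed 1 significantly and its indel discordance should peak in the
simple-repeat stratum).

All randomness flows from one root seed through named substreams (per
individual × setup × stage), so toggling one noise component (e.g. jitter)
does not perturb the draws of the others, and any single callset can be
regenerated in isolation.  Bundles are byte-reproducible from their embedded
config.

**What the generator does not emulate:** read-level error processes
(quality scores, alignment artifacts, coverage waves), structural variants,
linkage disequilibrium between sites, population structure, reference-build
mismatches, and inter-setup correlation of errors (setups err independently
given the truth).  Passing tests therefore demonstrate that the analysis
recovers planted set-level biases under a faithful error model — not that
any particular real platform behaves like a profile.

## Numerical choices

- Percentiles/quantiles use numpy's default linear interpolation.
- Chi-square cells with zero expectation are dropped with the dof adjusted.
- Duplicate normalized keys keep the maximum depth; ties are harmless since
  only the depth value is retained.
- GC class boundaries are `< low`, `[low, high]`, `> high`.
- Enrichment draw sizes derived from averages are rounded to integers.
- Jaccard of two empty sets is 0 with a warning (see above).

## Known limitations

- Genotype-agnostic identity cannot detect zygosity discordance between
  setups (a het/hom disagreement counts as concordant).
- The enrichment null treats variants as exchangeable; real callsets have
  region-dependent error rates, which the null deliberately ignores (that
  discrepancy is what the test is designed to expose).
- Anchor-base region assignment undercounts long indels spanning region
  boundaries relative to overlap-based assignment.
- The statistical size of the per-category 3·SE oracle checks is handled
  family-wise in the test suite; individual comparisons can exceed 3·SE by
  chance for a correct sampler.
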