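# Methods

## Conservation counting

A codon alignment is a per-species row of codon-width columns (codon or
`---`), produced either by translating each ORF, aligning the amino-acid
sequences, and back-translating, or by ingesting pre-aligned codon FASTA.
All counting is anchored on one reference species: every non-gap reference
column contributes one codon occurrence, and a codon is *conserved* iff
every species carries the identical codon in that same column (any gap
breaks conservation).  This is strict identity — no substitution matrix,
no phylogenetic weighting — because the statistic of interest is the
fraction of positions under strong positional constraint, not overall
divergence.

Two consecutive reference codons always count toward their ordered pair's
total.  The pair is conserved only if both columns are conserved **and**
the columns are consecutive in the alignment: an insertion column
contributed by any species between them breaks positional identity.  (The
alternative convention — dropping interrupted pairs from the denominator
too — is available via `count_interrupted_pairs=False`; interrupted pairs
are counted and reported either way.)  Pairs containing a stop codon are
excluded in the coding frame, leaving 61 sense codons and 3721 sense
pairs.  Rates with zero totals are reported as missing (NaN), never as 0,
and excluded downstream with a logged count.

Frame-shift controls re-tokenize the reference row's ungapped nucleotide
sequence at offsets +1/+2.  Shifted tri-nucleotide units are not codons,
so all 64 unit types are counted; a unit is conserved when its three
nucleotide positions are each gap-free and identical across species and
its columns are mutually adjacent, with the analogous adjacency rule for
unit pairs.

## The origin-constrained model

Pair conservation rate `y` is regressed through the origin on the product
`x` of the constituent codons' rates; the slope is the closed form
`sum(xy)/sum(x^2)` (optionally occurrence-weighted; unweighted by
default).  Residual scale is the sample standard deviation (ddof = 1) of
residuals over all included pairs; deviations are signed residuals in
units of that scale (positive = more conserved than predicted), and
outliers are pairs beyond `k_sigma` (default 3).  Outliers are defined on
residuals of the fitted line; an alternative route thresholds the
pseudocounted normalized scores' own distribution
(`fit(outlier_route="normalized")`), since the two operationalizations
both appear in the literature this analysis follows.

Normalized conservation scores use a pseudocount added to the pair rate
and to each codon rate; the default pseudocount is the reciprocal of the
total reference sense-codon count — the smallest nonzero rate increment
the data could show — so zero conservation never produces a zero or
undefined score.  Dipeptide-family z-scores standardize the *natural log*
of the normalized score within the family of all sense pairs encoding the
same ordered dipeptide under the active genetic code.  The log base is
immaterial (z is base-invariant; asserted in tests).  Families of size 1
(Met-Met, Met-Trp, ...) or with zero spread get z = 0 with a `degenerate`
flag.  Within-family rankings use competition ("min") ranks, descending,
so ties share the best rank.  Cross-comparison consistency flags a pair at
threshold k only if its deviation exceeds k in every comparison where the
pair has defined rates; pairs missing from any comparison are flagged
incomplete rather than treated as zero.

## Aligner

The bundled aligner is progressive global Needleman–Wunsch/Gotoh: affine
gaps (open −10, extend −1, end gaps penalized), BLOSUM62 scoring, guide
order by decreasing pairwise identity, new sequences aligned against the
running profile with mean-column substitution scores, and a fixed
tie-break (diagonal > up > left) so identical inputs give byte-identical
alignments.  It makes no claim to production multiple-alignment quality —
the downstream statistics are alignment-agnostic, and pre-aligned codon
FASTA from any external tool can be ingested instead
(`read_codon_alignment`).  Identical protein sequences shortcut to the
trivial gap-free alignment.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
deliberately minimal:

* **Star phylogeny.** Each non-reference species is derived independently
  from the ancestral sequence, and the reference keeps the ancestor.  With
  per-codon synonymous substitution probability `p_sub` per branch,
  expected codon conservation is `(1 − p_sub)^(n_species − 1)` and
  expected neutral pair conservation is its square — so the neutral
  pair/codon-product coupling is exactly 1.0, the truth value the fit's
  slope is checked against.
* **Synonymous-only divergence by default** (replacement uniform over the
  codon's synonymous class, excluding itself), which keeps amino-acid
  sequences identical and isolates the statistics from aligner behavior;
  nonsynonymous substitutions and codon-level indels are available to
  exercise the aligner path.
* **Planted pairs.** Each planted pair is written into the ancestor at
  non-overlapping uniform-random positions; a fixed fraction of its
  occurrences is *locked* — copied verbatim into every species — creating
  pair conservation in excess of the codon product at defined positions,
  which is precisely the signal the pipeline detects.  The truth record
  stores every occurrence, lock flags, per-ORF conserved-codon counts and
  realized per-pair totals.

Default study conditions (chosen once): 5 species, 500 genes of 100–600
codons, uniform sense-codon frequencies, `p_sub = 0.3` (per-codon
conservation ≈ 0.24 across 5 species, matching the ~0.25 median ORF
conservation typical of sensu-stricto comparisons), nine planted pairs at
lock fraction 0.4 with 50 occurrences each — about the background
expectation per pair (~175k codons / 3721 pairs ≈ 47), so planted pairs
are not usage outliers.  The nine default pairs are built from the slow
wobble-decoded codons characteristic of inhibitory codon pairs
(CGA, CCG, ATA, CTC, GCG, GTA, CTG) with one pair per ordered dipeptide
family, so each is the unique extreme within its family.

What the generator does **not** emulate: realistic codon-usage bias,
tree-structured phylogeny and shared branches, rate variation across genes
and sites, selection on codons themselves, GC/mutation bias, and real
indel length distributions.  Passing recovery tests therefore show the
statistics behave correctly under the model's own assumptions — they do
not validate the biological conclusions on real genomes, where residual
dispersion is biological rather than purely multinomial.

## Statistical components

* **Fisher enrichment**: one-tailed (upper) hypergeometric tail
  P(X ≥ observed) computed by log-space summation of exact log-binomial
  terms (`math.lgamma`); verified against exact rational enumeration for
  every 2×2 table with total ≤ 60 and against an independent library
  implementation.
* **Kolmogorov–Smirnov**: two-sample two-sided via scipy, exact
  small-sample distribution when `n·m ≤ 10^4`, asymptotic otherwise.
* **Chi-squared**: Pearson statistic on the set-by-category contingency,
  `df = (rows−1)(cols−1)`, zero margins dropped with a warning.  No
  multiple-testing correction is applied to the per-property KS p-values
  (raw p at α = 0.05), matching standard practice for this analysis;
  callers can correct externally.
* **Positions**: an occurrence's position is the 1-based index of the
  pair's *first* codon over the reference ORF length in codons, so
  positions lie in (0, 1].  Random pair sets are drawn uniformly without
  replacement from the sense-pair occurrence universe excluding the focal
  set (both switches exposed); sets with zero pooled occurrences are
  redrawn and logged.  Medians of even-sized sets are midpoints of the
  central order statistics.

## Determinism and numerical choices

All stochastic operations take explicit seeds; the pipeline driver derives
stage seeds by SHA-256 of (root seed, stage name), keeping them below
2^31.  TSV outputs carry `#` provenance headers (config hash, seed, stage)
and fixed float formatting, so a rerun of the same config is
byte-identical.  Degenerate inputs are defined rather than accidental:
zero residual sigma yields no outliers (warning); all-zero contingency
tables give p = 1 (warning); zero-length ORFs are excluded with a warning;
sliding conservation windows truncate at the ORF end and collapse to the
single whole-ORF rate when the window is at least the ORF length.

## Problem sizes

The test suite and the acceptance script run the recovery and calibration
experiments on freshly generated genomes at the default study conditions:
20 genomes in the test suite's recovery and null-calibration checks, 10
each in the acceptance script, with 500 KS replicates there (1000 in the
suite).  A single 500-gene, 5-species genome takes ~2 s to generate and
analyze; the full suite completes in about a minute.

## Known limitations

* Strict-identity conservation ignores near-synonymous conservation; a
  codon conserved in 4 of 5 species contributes nothing to frame-0 rates
  (the ≥ min-species rule is used only for ORF-set membership in the
  gene-property comparisons, default 4 of 5).
* At realistic per-pair occurrence counts the pair-rate noise is
  Poisson-skewed, so >3σ outlier calls retain a small spurious tail that
  no Gaussian-based expectation matches; interpreting outlier counts
  should account for this (see the below-line outliers dominated by
  ATG/TGG-containing pairs, whose codon-rate product is large and whose
  count noise is proportionally larger).
* The in-repo aligner is adequate for the mostly-identical proteins this
  analysis meets; heavily diverged or low-complexity proteins should be
  aligned externally and ingested pre-aligned.
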