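# Methods

This note records the models, rules and numerical choices behind
`altimir`, and what the synthetic-data tests do and do not demonstrate.

## Read model and pre-processing

Input is single-end small-RNA FASTQ. The 3' adapter is located by its
longest prefix occurring in the read with at most one substitution and at
least eight matched columns; among equally long matches the leftmost wins.
A read whose adapter starts at position 0 is an empty ligation product and
is counted separately. The insert's mean Phred score must reach Q20
(configurable; the underlying studies say only "low quality") and its
length must lie in 18–28 nt. Surviving inserts are collapsed to unique
tags with per-library counts; the per-library accounting is conservative
(raw = no-adapter + empty + low-quality + out-of-size + kept), which the
suite asserts.

## Hierarchical classification

Tags are classified sequentially, mirroring the small-RNA workbench
convention: (1) genome, both strands; (2) the contaminant pools in a
fixed, explicit order — cDNA, t/rRNA, sno/snRNA, tasiRNA — sense strand
only, first match wins and the tag is discarded from further analysis;
(3) mature miRNAs; (4) clean unassigned. Matching is ungapped exact
substring by default (`max_mismatch=0`); the tolerant path is a naive
scan intended for small problems. A tag maps to a mature when either
contains the other, which covers 5'/3' trimmed and template-extended
variants; tags matching several distinct collapsed matures are assigned
to all, flagged ambiguous, and counted once in totals.

One consequence of exact matching is deliberate and documented: reads
carrying 3' non-template tails or internal substitutions do not occur in
the genome and are labelled `unmapped_genome`. The isomiR stage therefore
screens every non-contaminant tag (miRNA, clean, and genome-unmapped),
just as the original workflow re-mapped cleaned reads onto matures and
precursors separately. Expression counts, by contrast, use only
mature-matched tags; because the variant mixture is identical across loci
and libraries, this thinning cancels exactly in every ratio (fold changes,
arm ratios) and only scales absolute counts by a constant.

## Quantification

RPM = raw count / cleaned-read total × 10⁶, where cleaned reads are
genome-mapped reads minus the contaminant classes (a `mirna_total`
denominator is available; the source protocol does not state which was
used). Cells with zero raw count are set to RPM = 0.01 *after*
normalisation — the floor is part of the normalised scale, not a
pseudocount — so every log₂ fold change is finite. Detection demands ≥10
raw reads pooled over the scope in question.

## Differential expression and between-library structure

The per-unit test is Pearson's chi-square without continuity correction on
`[[a, Ta−a], [b, Tb−b]]`, computed in closed form
(χ² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))) with p from χ²(df=1); a pair is
*tested* only when the count exceeds 10 in at least one library. The
"significant" gate is tested ∧ p < 0.05 ∧ |log₂FC| ≥ 1; all three
thresholds are configuration keys, and Benjamini–Hochberg adjustment is
available but off by default (raw p-values are the convention this family
of studies reports). With million-read libraries the test detects tiny
relative differences, which is why the fold-change gate matters.
Monotone-with-altitude units must pass the gate with the same sign in both
the low→mid and mid→high comparisons.

Jaccard similarity is presence/absence on detected sets. The CI is a
percentile bootstrap that resamples the union of detected units with
replacement and recomputes the index on the resampled universe; this makes
identical sets collapse the interval to [1,1] and the interval shrink as
lists grow. Per-set independent resampling was rejected because it cannot
reproduce the first property.

Clustering: library profiles are log₂ RPM; distance 1 − Pearson r;
average linkage; libraries are processed in sorted order so ties are
deterministic; output is Newick text. Correlation's shift invariance means
a globally rescaled library sits at distance zero, as it should.

ANOVA: per unit, log₂ RPM ~ population × condition via OLS with type-II
sums of squares. With one library per cell (the default design) the
interaction is not estimable and the additive model is fitted with a
warning; the full model is exercised in tests with simulated replicates.
All-equal responses return p = 1 by convention.

## isomiR taxonomy

Coordinates are 0-based half-open on the hairpin; offsets are tag start/end
minus canonical start/end (a non-template tail counts toward the tag end).
The decision tree, first match wins:

1. tag equals the canonical sequence → `canonical`;
2. the whole tag occurs on the hairpin with |offset5|, |offset3| ≤ window
   (default 5) → by offsets: equal → `shifted`; 5' anchored → `template_3p`;
   3' anchored → `start_site`; otherwise `both_end`. Among several
   placements the smallest |o5|+|o3| wins (then |o5|, then the smaller o5).
3. the longest template prefix anchored at the canonical start, with a 1–5 nt
   remainder that disagrees with the template continuation →
   `nontemplate_3p` (tail recorded);
4. the same with a shifted 5' anchor inside the window → `both_end`;
5. equal length, ends aligned, 1–2 internal mismatches not at the first or
   last position → `substitution`;
6. otherwise unassigned (a residual bin, excluded from isomiR statistics).

Two boundary choices are intentional. Exact-template explanations take
precedence over tails and tails over substitutions, so a length-preserving
read whose final base disagrees with the template is a 3' non-template
addition — the prevalent nucleotidyl-transferase signature — not a
substitution. And the tail length bound is a separate constant
(`max_tail=5`) rather than the window: tying it to the window would let a
larger window re-categorise an already-classified read (substitution →
tail), breaking the invariant that enlarging the window only rescues
unassigned reads. An exhaustive enumeration oracle (all windowed
substrings, 3' extensions, substitution variants of twenty synthetic
hairpins) checks the tree tag-for-tag.

A tag explainable by several matures goes to the one with the smallest
|o5|+|o3|, ties to the 5p arm; identical mature sequences from several
loci are collapsed into one expression unit first, so counts are never
double-assigned.

Diversity per mature and library is summarised by the dominance ratio
(most abundant single tag sequence / total assigned expression, a
scale-invariant number in (0,1]) and the distinct-tag count. 3' tailing
composition is the expression-weighted distribution of the *first*
non-template base over {A,C,G,U}. Arm usage compares raw counts of the 5p
and 3p units of a hairpin; zero counts are guarded by the count equivalent
of the 0.01-RPM floor, and significance is a two-sided exact binomial test
against an equal split.

## Novel hairpin screen

Clean unassigned tags are mapped to the genome (both strands; tags with
>20 loci are discarded as repeat-derived), overlapping placements merge
into loci led by the most abundant tag, and loci with lead abundance ≥10
are folded over a ±100 nt window. Folding is an injected callable
`seq → (dot-bracket, MFE)`; production wiring uses ViennaRNA, tests use
deterministic stubs. The star span is the minimal interval covering the
base-pairing partners of the mature, shifted +2 toward the star's 3'
end — the canonical Dicer duplex geometry in which both strands carry 2-nt
3' overhangs (the shift is +2 in sequence coordinates on either arm).
The three criteria: (a) mature and star on opposite arms — any
mature-mature pairing (a loop-spanning mature) or mature/star overlap
fails; (b) ≤4 mature positions inside the duplex (excluding the mature's
own 2-nt 3' overhang) unpaired or paired outside the star; (c) ≤1
asymmetric bulge, none larger than 2 nt, where a bulge is the difference
between consecutive gaps on the two arms (symmetric internal loops count
as mismatches, not bulges). Failure reasons name the violated clause.
Candidates overlapping annotated hairpins are removed in the pipeline —
template-shifted isomiRs of known miRNAs would otherwise re-seed their own
loci. Origin labels come from gene models: any exon overlap → exonic, else
inside a gene → intronic, else intergenic.

## Climate association

The site × variable table mixes units (°C, mm, radiation), so the PCA is
standardised (correlation-matrix PCA) with sample-variance scaling; it is
computed by SVD, degenerate components are dropped (three sites leave at
most two), explained-variance fractions therefore always sum to 1, and
each loading vector's largest-magnitude entry is made positive so reports
are reproducible. Expression is averaged within site before correlating
with PC scores (p-values at n=3 are reported but flagged low-power) and
with the growing-season factors AT/AP/AR. The season flag requires
|r| > 0.98 and p < 0.05; the literal inequality p > 0.05 that appears in
this literature is almost certainly a typo (a "strong correlation" cannot
require non-significance) but is available via `p_rule="greater"`. Note
that at three sites p < 0.05 needs |r| ≳ 0.997, so only near-exact trackers
are flagged there.

## Synthetic study generator

The generator emulates the design of an altitudinal common-garden study:
populations Deh (700 m), Mun (2000 m), Chit (3400 m) × field/glasshouse,
plus a Col-0-like glasshouse control — seven libraries of 600,000 reads by
default, a desk-scale stand-in for the millions of cleaned reads of a real
study, sized so that every unit above the 100-expected-read scoring floor
is estimated with ≲0.1 log₂ sampling error.

Reference: 32 hairpins built as perfect inverted repeats (30 bp stem, 8 nt
loop, 6 nt 3' pad — foldable by construction and validated against the
duplex criteria as a positive control), with 10 both-arm, 8+8 single-arm
and 6 unlabeled-arm annotations; mature lengths 20/21/22 at 25/50/25%.
Hairpins, contaminant pool sequences and two-exon gene models are embedded
in a random two-chromosome genome; cDNA is the spliced exons, and one
additional unannotated hairpin sits in an intron as the planted novel
locus.

Libraries: read classes per library are miRNA (30% field / 25%
glasshouse), genomic background (43/48%), contaminant fragments (20%), and
small low-quality, adapter-only and out-of-size classes that exercise the
trimming accountancy. Unit abundances are log-normal (σ=0.45) with planted
structure: five monotone-up units (multipliers 1/4/16 across altitude, low
base weight so the composition shift they induce stays small), one
monotone-down unit, six non-monotone DE patterns, condition responses (×4
or ×0.25 in GH, applied to whole hairpins so arm ratios stay planted),
three population-specific units (absent elsewhere — they create the unique
sectors of the detection Venn), and two Col-0-specific shifts. IsomiR
categories are drawn per read from a fixed mixture (canonical 78%, NTA 9%,
template 7%, both-end 3%, shifted 1.5%, substitution 1%, start-site 0.5% —
within the ranges such studies report); non-template tail bases follow
A/C/U weights with guanosine weight exactly 0; offset draws are constrained
to keep reads inside the 18–28 nt size window so the planted mixture
survives filtering. Background fragment lengths are normal around 21 nt
(field) or 24 nt (glasshouse), reproducing the characteristic length-mode
flip between conditions. The climate table has 11 temperature-like
variables falling linearly with altitude, 8 precipitation-like variables
with a monsoonal mid-slope maximum, and radiation rising with altitude.

Everything derives from one integer seed through per-stream
`SeedSequence` spawning; identical seeds give byte-identical FASTQ and
manifests. The truth manifest records weights, multipliers, expected
within-class proportions, realised class counts, planted monotone /
condition / population-specific sets, arm ratios, the mixture and the
novel mature, plus the analytic probabilities that a miRNA read is
countable by exact matching (containment-compatible categories) and
cleaned (genome-true categories) — the quantities needed to score recovery
without re-deriving anything.

What passing recovery tests shows — and does not. The generator's reads
are error-free, uniquely mapping, with flat quality strings, exact
category rules and a contaminant set that never overlaps miRNA space; real
libraries have sequencing errors, multi-mapping tags, cross-mapping
between paralogues and expression-dependent tailing. Recovery therefore
validates the *pipeline's arithmetic and rule logic* (classification
order, normalisation, test statistics, taxonomy, validator geometry), not
robustness to alignment ambiguity or error models, which are out of scope.

## Scoring conventions

Fold-change recovery is scored on the field-condition population pairs
(the fold-change plan is defined per population), for units expected at
≥100 countable reads on both sides, with a ±0.3 log₂ band; the isomiR
mixture within 3 multinomial SE; monotone sets by exact recall with ≤5%
false positives; arm ratios within ±0.3 log₂ pooled per population; and
guanosine tails must be exactly absent. The chi-square test is checked
against the closed form and an independent implementation, and its null
type-I error (totals 10⁶, expected count 100, 5000 replicates) must be
5%±1 point at α=0.05.

## Known limitations

- Mismatch-tolerant matching is a naive scan; the pipeline default is
  exact matching, so the tolerance knob is for small experiments only.
- Multi-locus identical matures are collapsed; no probabilistic
  re-assignment of multi-mapping reads is attempted.
- The novel screen applies structural criteria only — no folding-energy
  randomisation p-value, star-read support, or conservation evidence.
- The ANOVA treats libraries as independent replicates of their
  population×condition cell; with pooled-library designs this is a
  convention, not a claim about biological replication.
- Three climate sites give correlation p-values with almost no power; the
  PC-association stage is a screen, not an inference engine.
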