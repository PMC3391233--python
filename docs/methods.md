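# Methods

This note records the models, conventions and numerical choices behind
each stage of the survey pipeline, what the synthetic generators do and do
not emulate, and the design decisions taken where the field's practice is
genuinely open.

## Motif scanning

The CCCH zinc finger is matched by the degenerate consensus
`C-X(a)-C-X(b)-C-X3-H` with spacer bounds 4 ≤ a ≤ 17 and 4 ≤ b ≤ 6. The
classical plant consensus caps a at 15; the default upper bound here is 17
because a genuine C-X17-C-X6-C-X3-H finger has been recorded in maize.
Bounds are configuration (`SpacerBounds`), not constants, so both
conventions are available. The unknown-residue code X may occupy spacer
positions but never an anchor C/H: the anchors define the motif's
metal-coordination chemistry, while spacers are unconstrained.

A cysteine cluster can admit several (C, C, C, H) parses, and published
family surveys resolved such ambiguity with HMM tools whose tie-breaking
is opaque. The scanner instead enumerates every candidate quadruple within
bounds and greedily accepts by **(leftmost start, smallest total span,
smallest a, smallest b)**, discarding candidates that overlap an accepted
hit. The policy is deterministic, favors compact canonical motifs, and is
verified against exhaustive enumeration on short sequences. Hits never
overlap; re-checking any reported hit against the consensus always
succeeds.

Class tallies report percentages as 100·count/total rounded half-up to
one decimal. Logo profiles are position-frequency matrices over the 20
amino acids with per-column information content R = log2(20) − H(column)
in bits (maximum ≈ 4.32). Combined logos of classes differing only in the
first spacer are right-justified on the second cysteine, so the
variable-length first spacer absorbs the offset and the three C/H anchor
columns coincide; columns not covered by the shorter class average only
over the sequences that reach them.

## Phylogeny

Distances are uncorrected p-distances with **pairwise deletion**: each
pair is compared over the columns where both rows are ungapped, and a pair
with zero comparable sites is an error (the tree would be undefined). A
Poisson correction −ln(1 − p) is available behind a flag; p-distance is
the default because grouping depends on topology and support, not on
precise depths, and the assumption-light choice is easiest to reason
about.

Neighbor joining follows the classical algorithm. Two determinism
measures matter in practice:

- **Tie-breaking.** When two pairs minimize the Q criterion, the pair
  whose (lexicographically smallest member-taxon) representatives sort
  lowest wins. Because Q sums accumulate floating-point error in row
  order, ties are detected within a small tolerance band (10⁻⁹ × matrix
  scale); without the band, support values would depend on taxon input
  order.
- **Branch lengths.** Negative NJ estimates are clamped to zero with the
  deficit moved to the sibling edge, the standard repair; downstream
  consumers require non-negative lengths. On additive matrices the tree's
  path metric reproduces the input exactly.

Bootstrap support on an internal edge is 100 × the fraction of replicate
trees — full pipeline re-run on columns resampled with replacement —
containing the same (unrooted, canonicalized) leaf bipartition.
Per-replicate RNG streams derive from the master seed by counter
(`default_rng([seed, rep])`), so results are reproducible and independent
of execution order. `n_reps=0` returns the tree with supports undefined.

**Group assignment.** Families are conventionally divided into groups by
reading supported clades off the displayed tree; on an unrooted NJ tree
with an arbitrary trifurcating root this needs an explicit rule. The rule
here: preorder from the NJ root, a clade whose subtending edge passes the
threshold (strict > 50 by default; an inclusive ≥ variant is selectable)
becomes a group, with two refinements applied recursively —

1. a supported clade whose immediate children are all themselves
   supported internal clades decomposes into them (an arbitrary rooting
   placing the root inside one subfamily must not let the deep split
   swallow the others), and
2. a supported clade strictly weaker than its strongest supported
   internal child defers to that nested structure (a borderline wrapper
   edge must not absorb a strongly supported subfamily).

Finally, if the taxa left ungrouped are exactly one side of a supported
bipartition (the complement of a supported clade at the root), they form
one further group — both clades flanking a supported deepest split are
then recovered. Remaining taxa stay ungrouped. Sister pairs are the
cherries of the rooted representation: nodes with exactly two leaf
children, reported with their edge support.

## Duplicate evolution

Tandem: same chromosome and at most five **intervening** gene loci
(|Δlocus_index| − 1 ≤ 5). The alternative reading |Δindex| ≤ 5 is exposed
as `convention="index"`; the convention must be explicit because
"separated by five or fewer gene loci" supports either. Segmental: the
two genes fall by coordinate containment inside the two mates of one
duplicated-block pairing, in either orientation; block detection itself is
out of scope (the catalogue is an input). A pair qualifying as both is
reported tandem — physically clustered copies are tandem duplicates
regardless of block context, which also matches how the published maize
table labels its two tandem clusters that sit on duplicated blocks.

Ka/Ks uses Nei–Gojobori (1986) counting: per-codon synonymous site
fractions (each of the nine single-nucleotide changes contributes 1/3 of
a site; changes to stop codons count as nonsynonymous), averaged over both
sequences; substitution counts averaged with equal weight over all
minimal pathways between differing codons, excluding pathways that cross
a stop codon (renormalizing over the valid ones, with a per-position
fallback in the all-blocked corner case); Jukes–Cantor correction
d = −3/4·ln(1 − 4p/3) applied to both proportions, with p ≥ 3/4 flagged
as saturated rather than silently clipped. One practical consequence: a
single synonymous change in a very short alignment (a lone codon has only
1/3 synonymous site) saturates the correction and Ks is undefined — the
implementation raises rather than fabricating a value. The implementation
agrees with exact rational-arithmetic pathway counting to < 10⁻¹² and
with an independent reference implementation to ~10⁻¹⁴.

Selection calls: purifying (< 1), neutral (= 1), positive (> 1), and
undefined when Ks = 0 (an infinite ratio is not reported). Dates follow
T = Ks/(2λ) in Mya with λ = 6.5×10⁻⁹ synonymous substitutions per site
per year, the standard grass rate. Report rounding matches the published
table's precision: ratios to three decimals, dates to two, half-up.

The published 17-pair maize CCCH duplicate table ships with the package
(`data/maize_ccch_duplicate_pairs.tsv`); its Ka and Ks columns are inputs,
and the ratio/selection/date columns are recomputed from them by these
operations, reproducing the published values at printed precision.

## Promoter scanning

Promoters are the `length` (default 2,000) bases immediately 5′ of the
translation start on the coding strand, reverse-complemented for − strand
genes and truncated with a warning at chromosome ends. Coordinates are
1-based, sense-strand, inclusive; the ATG would sit at position
length + 1.

The element lexicon is an editable YAML file mapping names to IUPAC
patterns with per-entry source notes. The shipped defaults are the widely
used cores ABRE `ACGTG` and DRE/CRT `RCCGAC` (R = A/G); published surveys
name the element classes but rarely print the exact patterns they
matched, so the lexicon is configuration, not a claim about any
particular study's entries — and figure-level element counts from such
studies are correspondingly not reproduction targets. Scanning reports
**all** occurrences on both strands, overlaps included, because
occurrences are counted per position; N matches nothing, even against
degenerate codes. Strand symmetry holds exactly: scanning a reverse
complement swaps strands and mirrors positions via
pos′ = L − pos − |pattern| + 2.

## qPCR expression

Per well, ΔCt = Ct_target − Ct_reference with the reference paired by
(condition, replicate); ΔΔCt subtracts the gene's **mean** calibrator ΔCt
(replicate pairing across conditions is not defined by the design);
fold = 2^−ΔΔCt per replicate, reported as mean ± SE. SE is computed on
fold values because expression figures annotate fold-scale bars; a
ΔΔCt-scale SE (`se_log`) is also reported. Replicates are exchangeable by
default, with a `replicate_type` column so technical or biological
replicates can be pooled or selected. Invariances: a plate offset applied
to target and reference alike cancels exactly; the calibrator fold is
exactly 1 when noise is zero (with noise, the mean of per-replicate folds
at the calibrator exceeds 1 slightly — the mean of a log-normal — which
is a property of the estimator, not a bug).

## Synthetic data

Generators plant known structure in uniform-background sequence and
guarantee recoverability by rejection sampling of the **background only**
(planted content is never altered; after 10,000 failed redraws the plan is
reported infeasible):

- proteomes: motifs at planned 1-based positions with planned spacers;
  the assembled protein is re-scanned and backgrounds redrawn until the
  hit set equals the plan, so anchors arising in background cannot create
  spurious or alternative parses;
- CDS pairs: ancestor drawn codon-uniform over the 61 sense codons
  (avoiding composition artifacts in NG86 site counting); exactly the
  planned numbers of single-nucleotide synonymous and nonsynonymous
  changes applied in distinct codons, resampling codons with no synonymous
  option (Met/Trp); both sequences stop-free and in frame;
- gene orders: tandem pairs placed ≤ 5 intervening loci apart outside
  blocks, segmental pairs inside the mates of block pairings, fillers
  avoiding block slots so planted labels are exactly recoverable;
- promoters: IUPAC patterns instantiated concretely, reverse-complemented
  for − strand plantings, background redrawn until the scan equals the
  plan;
- Ct tables: reference gene at a fixed baseline, targets encoding the
  planned fold via Ct = Ct_ref + ΔCt_base − log2(fold), i.i.d. Gaussian
  noise per well; zero noise recovers folds exactly;
- clade alignments (fixture for the tree stage): per-clade consensus
  sequences diverged from a shared root at 45% of positions, members at
  2%, giving strong between-clade and weak within-clade signal.

What the generators deliberately do **not** emulate: realistic genome
structure, codon-usage or composition bias, rate heterogeneity across
sites, indel evolution, or correlated qPCR noise. Passing round-trip
tests therefore demonstrates the correctness of the pipeline's
arithmetic and conventions on clean inputs, not robustness to the noise
structure of real data.

## Problem sizes and determinism

Default study-shaped sizes: the demo bundle carries 68 proteins (one with
seven motifs, one with the 17-spacer finger), a 12-taxon 3-clade
alignment with a 200-replicate bootstrap, 17 duplicate pairs (15
segmental + 2 tandem, 300 codons each), 12 promoters of 2,000 bp, and a
7-gene × 4-condition × 3-replicate Ct table. Property tests use 8-taxon
additive matrices (100 seeds) and sequences ≤ 80 residues for the
exhaustive scanner oracle. All randomness flows through
`numpy.random.default_rng` seeded explicitly; bootstrap replicates use
counter-derived child streams; identical seeds produce byte-identical
generator output.

## Known limitations

- The NG86 estimator is the counting method; codon-model ML estimators
  (YN00/codeml-style) can differ appreciably at high divergence, so
  published Ka/Ks values computed with other software are treated as
  inputs rather than re-derived from sequence.
- Group assignment from bootstrap supports is a convention, not an
  inference procedure; the refinements above make it deterministic and
  robust to rooting artifacts, but borderline supports near the threshold
  can still flip group boundaries between nearby datasets.
- p-distance saturates for deeply diverged proteins; use the Poisson flag
  (or an external alignment-and-distances workflow) when depths matter.
- The promoter scanner is exact-pattern (IUPAC) matching; no PWM scoring
  or conservation analysis.
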