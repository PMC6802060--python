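# Methods

This note documents the models, parameters and numerical choices behind
`retroforge`, and what the synthetic-data studies do and do not establish.

## Coordinates and formats

All internal coordinates are 0-based half-open genomic intervals;
conversion happens only at the GTF boundary (1-based inclusive) and BED
(already 0-based). Only `CDS` features are consumed from annotations; each
gene is reduced to one representative transcript (longest CDS, ties broken
by lexicographic transcript id) because the analysis maps proteins, not
isoform sets. Assemblies are held in memory as uppercase A/C/G/T/N
strings; chromosome roles (sex chromosome, scaffold/MT) are inferred from
names (`chrX`, `scaffold*`, `chrM`/`MT`, `chrUn*`).

## Homology search

Queries are proteins ≥ 50 aa. Seeds are exact 4-aa word matches between
the query and all six translation frames of the genome, indexed as sorted
word-hash arrays. A diagonal needs two word hits within 60 aa before
extension (the BLAST-like two-hit heuristic; configurable) — at the ≤ 10%
amino-acid divergence this pipeline targets, true homologies carry dozens
of exact 4-mers, while the rule suppresses nearly all random extensions.
Seed clusters are extended gaplessly with BLOSUM62 and an X-drop of 12,
then trimmed to the maximum-scoring segment. HSPs pass at identity > 0.50,
length ≥ 50 aa and raw score ≥ 50. A raw-score gate replaces an E-value
gate deliberately: Karlin–Altschul calibration adds machinery without
changing behaviour at these genome sizes, and every threshold is exposed
in `SearchParams`. Same-frame overlapping HSPs keep only the best scorer;
collinear same-strand HSPs within 50 kb are chained into candidate loci
(protein and genomic order must agree, reversed on the minus strand).

## Spliced alignment

Each candidate locus (±1 kb flanks) is parsed against the query protein by
a local dynamic program over (protein position × DNA position) with moves:

* codon match — BLOSUM62 score of the residue against the codon's
  translation; stop codons use the matrix's `*` column and are recorded as
  in-frame stops; codons containing N score 0 against anything;
* frameshift — one residue consumes 1, 2, 4 or 5 bases at −20, modelling
  1–2 bp slips;
* gaps — unaligned protein residues and skipped codons at −10 each
  (linear);
* intron — entered at `GT`, left at `AG`, length ≥ 30 bp, flat −25 with no
  per-base cost.

Penalties were chosen so that a true GT..AG intron (−25) beats a
frameshift parse of the same region, while a genuine 1–2 bp slip (−20)
beats opening a spurious intron. Parses scoring ≤ 35 are rejected. Introns
are modelled at codon boundaries (phase 0); the simulator generates
phase-0 introns, and on real annotations phase-1/2 introns surface as
±1 residue fuzz, absorbed by the ±5 aa tolerance of the intron-retention
check. The DP is verified in the test suite against an independent
memoized-recursion implementation of the same state machine on small
inputs, and against planted introns, frameshifts and stops.

## Catalogue construction

Accepted parses with zero introns that do not overlap the query's own gene
are candidates; loci called by several queries are deduplicated (> 50%
reciprocal overlap keeps the best score). Each candidate's conceptual
translation is aligned (Smith–Waterman, BLOSUM62, 11/1 gaps) against every
protein; the best scorer wins at identity > 0.5, overlap > 0.5, ≥ 50 aa,
ties broken by identity then gene id, and the candidate is discarded if
the winner is single-exon. The locus (±2 kb) is then re-parsed with the
assigned parent; a parse showing an intron within ±5 aa of a parental
intron position marks a DNA-level duplicate and is discarded. A retrocopy
is **intact** iff the parent-guided parse has zero frameshifts and zero
in-frame stops; "premature" means any stop before the column aligned to
the parent's final codon (no grace zone by default; a configurable grace
fraction can forgive stops in the final few percent). **Chimeric** means
intact and strictly inside a different same-strand gene that keeps ≥ 1 CDS
exon outside the retrocopy span — an explicit operationalisation of the
fusion-gene configuration. "Novel" retrocopies overlap no annotation on
either strand.

## Ka/Ks, ω and dating

The estimator is classic Nei–Gojobori (1986) counting: per codon, each
position contributes (synonymous single-base changes)/3 synonymous sites,
averaged over the two sequences (N + S = 3L); changes to stop codons count
as nonsynonymous. Observed differences average over all minimal mutational
pathways between the codons, excluding pathways through stop codons (if
every route is blocked, all routes are used). Proportions are corrected
with Jukes–Cantor, K = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is flagged saturated
and the rate (and ω, and age) is reported as undefined rather than
clamped. Codon columns containing a stop or ambiguity are dropped before
counting. ω classes follow the catalogue convention: constrained ω < 0.5,
intermediate 0.5 ≤ ω ≤ 1.2 (upper edge inclusive so the bins partition),
elevated ω > 1.2, undefined when Ks is 0 or saturated (Ks = 0 records stay
in the catalogue but leave the ω statistics).

Counting-method Ka/Ks was chosen over maximum-likelihood codon models
because it is exactly checkable: the test suite compares N, S, Nd, Sd to a
brute-force neighbour/pathway enumeration and requires equality. The
simulator mutates uniformly across sites (κ = 1) by default, matching the
estimator's no-bias assumption so that neutral simulations recover
ω ≈ 1; a κ parameter can inject transition bias, which NG86 will then
undercorrect — by design, as a study tool. Note that the *mean* of ω̂ over
finite pairs sits above 1 (≈ 1.03–1.11 depending on length) because Ks
enters the denominator with sampling noise; the recovery study uses
500-codon pairs where this ratio bias is a few percent.

Ages use T = Ks/2λ in Mya. λ defaults to the canid calibration
0.4×10⁻⁸ substitutions per generation over 3-year generations — the exact
ratio 1.3̄×10⁻⁹/yr, so Ks = 0.02 → 7.5 Mya and Ks = 0.06 → 22.5 Mya
(the rounded constant 1.33×10⁻⁹ would give 22.6 for the upper edge). The
Ks histogram uses 0.02-wide bins on [0, 1) with pooled bins [1, 2) and
[2, ∞), the standard presentation for burst dating with saturated tails.

## EST support

Cleaning trims terminal poly-A/T runs ≥ 10 bp, drops reads < 100 bp after
trimming, and removes low-complexity reads (most common base > 0.8, or
dinucleotide Shannon entropy < 1 bit — a DUST-like gate). Mapping is
11-mer seed-and-extend on both strands; candidate windows ranked by seed
votes are aligned as full-read infix alignments (edit distance), keeping
identity > 0.95 and read coverage > 0.90. A read is *unique* when exactly
one alignment passes, or the best score (matches) exceeds the runner-up by
≥ 5% — this margin is the operational reading of "maps to a unique
location" and is the guard against parent/retrocopy cross-mapping: a read
wholly inside the shared CDS at ~4% parent divergence is ambiguous and is
discarded, while reads touching the poly-A remnant, target-site
duplication or flanks are unique to the retrocopy. Support requires
> 100 bp overlap with the retrocopy locus and > 97% identity *within the
overlap* (walked from the alignment's extended CIGAR). Spliced EST
alignment is out of scope (retrocopies are single-exon targets), so
parent-side reads spanning introns simply fail coverage.

## Gene traffic and the X test

Movements are interchromosomal, intrachromosomal (same primary
chromosome), or scaffold/MT (either side unplaced/organellar). The
functional set is intact with ω < 0.5; the neutral set is pseudogene with
0.5 < ω < 1.0 (both bounds exclusive, as printed in the catalogue
convention); both are restricted to interchromosomal pairs. Per-chromosome
parent and insertion counts are regressed (OLS) on annotated gene count
and chromosome length, reported with Pearson r both over autosomes+X and
over autosomes alone.

The X-outlier test fits OLS on autosomes only and refers X's externally
studentized residual (out-of-sample prediction standard error) to a
two-sided t with n_autosomes − 3 degrees of freedom. The direction of the
residual distinguishes excess from deficit. A calibration study under the
package's own null (events placed multinomially in proportion to the
covariate over a 38-autosome + X karyotype) shows the test is modestly
anticonservative when X sits near the top of the covariate range: measured
type-I error is ≈ 7.5–8% at nominal 5% (4,000 replicates, 272–2,902
events), versus ≈ 4.7% when the tested chromosome is mid-covariate. The
cause is heteroscedasticity — count variance scales with the covariate,
while the t-test pools a single residual variance. The test is kept as the
default because it mirrors the regression-plus-outlier presentation used
in gene-traffic studies; `x_binomial_test` (one-sided binomial on X's
share of events vs X's share of the covariate) is exactly calibrated and
is the recommended alternative when calibration matters more than
comparability. Power is ample either way: under 3× X-origin enrichment at
200 pairs the median t-test p-value is < 10⁻⁵. No multiple-testing
correction is applied across the four regressions, matching standard
practice for this presentation.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
desk scale. Defaults: six chromosomes (five autosomes + X) of 330 kb
(~2 Mb total), 40 genes with 2–8 exons of 90–300 bp (whole codons,
phase-0 GT..AG introns of 80–400 bp), intergenic GC 0.41, and 50
retrotransposition events. Each event copies the parent's spliced CDS,
applies uniform substitutions at 0.04/site (centred on the Ks 0.02–0.06
range where carnivore retrotransposition activity concentrates), then —
independently at 0.3/0.3 — injects a 1–2 bp frameshift at a uniform CDS
position and/or a single-substitution premature stop before 90% of the
CDS; 10% of events instead insert intact into another gene's intron on the
same strand (chimeric). Inserts carry a 30 bp poly-A tail and a 10 bp
target-site duplication; the caller does not use either (realism without
coupling). For events whose intended class is intact, substitutions that
would create an in-frame stop are redrawn, because an intact retrocopy is
*defined* by its preserved ORF; pseudogene-class events accept chance
stops. ESTs (300 reads of 400 bp, 1% uniform error) are substrings of
expressed retrocopy loci (half of events) including 50 bp flanks. An
optional mode injects DNA-level duplicates (full gene regions with
introns) to exercise the intron-retention discard.

What passing recovery tests shows: the chain detects, assigns and
classifies insertions whose divergence, length and disruption spectrum
match the generator. What it does not show: robustness to repeat-rich
backgrounds (no LINE/SINE model), post-insertion indel evolution, isoform
diversity, sequencing chimeras, or parents with close paralogs — real
catalogues face all of these, and the thresholds here (identity/overlap
0.5, 50 aa, score 35) are the community's, not values fitted to the
simulation.

## Determinism and problem sizes

Every stochastic component takes a single integer seed
(`numpy.random.default_rng`); identical configuration and seed give
byte-identical output files. Stable sorts (chromosome, start, id) and
lexicographic tie-breaks make the catalogue reproducible. The bundled
studies use a ~2 Mb / 40-gene / 50-event genome, 300 neutral pairs of 500
codons, and 1,000 null traffic placements — sizes at which every recovery
statistic is stable to a few percent across seeds while the whole suite
runs in minutes on one CPU.

## Known limitations

* The spliced aligner models GT..AG introns only, without splice-site
  profiles or phase-aware intron states; it is a caller's filter, not a
  gene predictor.
* Local alignment trims disruptions within ~4 residues of either CDS end
  rather than paying the frameshift penalty, so a frameshift in the first
  or last few codons can leave a copy classified intact (~2% of simulated
  pseudogenes).
* NG86 assumes no transition/transversion or codon-usage bias;
  biased-mutation genomes need the κ-aware generator plus an external
  ML engine through the catalogue's codon-pair export.
* The EST mapper is co-linear (gaps ≤ 30 bp); it is not a spliced aligner.
* The studentized-residual X test is anticonservative for count data (see
  above); use the binomial alternative for calibrated error rates.
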