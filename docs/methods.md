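# Methods

## The analysis problem

Some organellar genomes transcribe RNAs that differ from their DNA template
at hundreds of positions.  In the deamination systems this package models,
adenosine is converted to inosine (read as guanosine by reverse
transcriptase, so edits appear as A→G in RNA-seq) and cytidine to uridine
(C→T).  On a gene-dense circular mitochondrial genome of ~20 kb the coding
regions can be fragmented by in-frame premature stop codons at the DNA
level; editing converts those stops back to sense codons (typically
tryptophan, TAG/TGA/TAA→TGG via one or two A-to-I events) and reopens the
reading frames.  `mitoedit` detects and quantifies such editing from
matched DNA-seq and RNA-seq, annotates codon-level consequences, and
quantifies the selective signature with the Nei–Gojobori (NG86) Ka/Ks.

## Detection model

For each genome position the package keeps plus-strand A/C/G/T counts of
aligned read bases (a pileup), built from SAM text with pysam or read from
TSV.  A candidate editing site requires:

* RNA depth ≥ `min_rna_depth` (default 11, i.e. strictly more than 10
  reads; all "more than" thresholds in this package are strict),
* DNA depth ≥ 1 (the depth filter is applied to RNA only),
* a majority non-reference RNA allele with ≥ 1 read, where the reference is
  the DNA consensus (majority DNA base, ties broken toward the FASTA base).

The **editing level** is 100 × (edited-allele reads)/(total reads at the
site).  **DNA heterogeneity** is 100 × (majority non-consensus DNA allele
count)/(DNA depth); sites above `dna_het_max_pct` (default 5) are retained
with an `excluded_heterogeneous` flag and skipped by every summary — the
heterogeneity screen validates that an apparent edit is not a genomic
variant, it is not itself an editing call.  Zero-depth sites report a
missing (never zero) score.  Only the majority non-reference allele is
evaluated: one edit per site.

Substitution type is assigned on the transcript strand of the containing
gene (counts themselves are un-stranded): A→G types as A-to-I, C→T as
C-to-U, anything else as `other`; a site inside genes on opposite strands,
or in no gene, stays `unassigned`.  Downstream analyses use sites above
`call_level_pct` (default 50); strain comparison uses `compare_level_pct`
(default 10); the high-level class threshold is 90.

## Codon effects and stop restoration

Each called site inside a CDS yields one effect record per containing
frame — overlapping CDS classify the same site independently, so a site
can be synonymous in one frame and nonsynonymous in the other.  Codons are
extracted strand-aware with modulo arithmetic, so genes wrapping the origin
of the circular genome are handled transparently.  Translation uses a
per-gene NCBI table (default 1; table 4, which reads TGA as Trp, is
selectable — the choice matters only for TGA handling).  Any edit whose
reference codon is a stop is classified `stop_loss`, including each of the
two A-to-I edits TAA needs to reach TGG; whether a gene's premature stops
are actually removed is decided jointly by `detect_stop_restoration`, which
applies all above-threshold edits of a codon together and reports each
internal stop as restored or not.

Amino-acid property changes use a five-class scheme — hydrophobic
(AVLIMFWY), polar (STNQC), positive (KRH), negative (DE), special (GP) —
with stop involvement always a class change.  This scheme is a documented
stand-in; published classifications differ in where they place C, G and P.

The repertoire summary reports a fixed 10-wide level histogram
((0,10] … (90,100]), transcript-type counts and codon-position composition
among called sites, the high-level fraction among called coding sites, per
gene counts/densities, and the edited fraction of the genome
(100 × called sites / genome length).

## NG86 Ka/Ks between unedited and edited CDS

The "two sequences" compared are the genome-encoded CDS and the same CDS
with every edit above `kaks_apply_level_pct` (default 50) substituted.
Synonymous sites per codon are counted by enumerating the three single-base
changes at each position (changes producing stops count as nonsynonymous);
differences between codon pairs are averaged over all orderings of the
differing positions, excluding pathways through stop codons, falling back
to all pathways when every one is excluded.  Proportions pₛ = Sd/S and
pₙ = Nd/N receive the Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p),
undefined (NA) at p ≥ 3/4.

NA semantics: a gene with zero substitutions reports Ka = Ks = NA; with
substitutions but Sd = 0, Ka is real and Ks = NA (hence Ka/Ks = NA) — the
table signature of an all-nonsynonymous editing repertoire.  A strict-zero
mode (`zero_subs_na=False`) reports 0 instead of NA for both conventions.
Codon pairs where either codon is a stop (the premature stops of the
unedited sequence) or contains an ambiguous base are eliminated pairwise;
their substitutions are deliberately not counted.  The reported gene length
excludes only the terminal stop codon, so S + N equals three times the
number of analyzed codon pairs, which is less than the reported length
exactly when premature stops exist.

## Strain comparison

Homologous CDS pairs are aligned globally (Needleman–Wunsch, match +1,
mismatch −1, linear gap −2; traceback ties broken deterministically:
diagonal, then up, then left).  Editing sites are projected into transcript
coordinates and lined up through match/mismatch columns; a column counts
once either strain exceeds the 10% level, and is shared only when both
exceed it with the same substitution type (a flag relaxes the same-type
requirement).  Sites in gap columns are unique to their strain and flagged
`unaligned`.  Linear gap costs suffice for near-identical orthologs; affine
gaps are out of scope.

## Synthetic data generator

The generator emulates the study conditions rather than generic sequencing:

* **Genome**: 20 kb circle, 10 CDS (75–400 codons, ATG start, TAA terminal
  stop) and 6 tRNA genes placed without overlap, ~30% on the minus strand,
  random intergenic gaps; the first CDS deliberately spans the origin so
  wrap-around code paths are always exercised.  In restorative mode each
  CDS carries 1–3 internal premature stop codons.
* **Truth table**: 358 editing sites by default (≈1.8% of the genome,
  matching a densely edited organellar repertoire), split 338:20 between
  A→G and C→T on the transcript strand.  Every internal premature stop
  receives the A→G edit(s) converting it to TGG; all other coding designs
  are nonsynonymous, sense-preserving single edits with at most one edit
  per codon — so the designed repertoire is all-nonsynonymous, as in the
  system being modeled.  10% of free sites fall in tRNA/intergenic space.
* **Levels**: the default `high` preset draws 85% of sites from (90,100],
  12% from (50,90] and 3% from (5,50], mirroring the observed skew where
  ~84% of coding sites exceed the 90% level.  Stop-restoring edits always
  draw from (90,100] so restoration is complete at the 50% application
  threshold.  A `two_band` preset places a chosen fraction in (92,100] and
  the rest in (55,88], keeping every site callable and the above-90%
  fraction known by construction.  Per-site levels are constants; a
  beta-binomial overdispersion switch exists and defaults off.
* **Pileups**: depth is Poisson per site (default 1000×, the depth used
  throughout the desk-scale checks; study-scale coverages are reachable by
  config), edited-allele RNA reads are Binomial(depth, level/100), DNA is
  reference except configured heterogeneity sites, and sequencing error
  substitutes each read base uniformly among the other three bases at
  `error_rate` (default 0).  Counts always sum to depth.  An optional SAM
  writer emits ungapped perfectly placed reads (origin-spanning reads split
  into soft-clipped two-part alignments) together with the generator's own
  tally of those reads, so the SAM reader can be verified exactly.

Everything is driven by one integer seed through per-stage RNG streams:
identical configs give byte-identical outputs.

What the generator does **not** model — and what passing tests therefore do
not show about real data: mapping ambiguity and alignment artifacts, indel
errors, base-quality structure, fragment-level coverage correlation,
directional-library strand bleed, and true biological overdispersion of
editing levels.  The detector's accuracy on real alignments depends on the
upstream mapper in ways these tests cannot measure.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere; circular arithmetic is
  modulo genome length; gene models with end < start wrap the origin and
  are written to GFF3 with a `wraps_origin=true` attribute.
* Deterministic tie-breaks: DNA consensus ties go to the FASTA base; RNA
  alternative-allele ties go to the alphabetically first base; alignment
  traceback prefers diagonal, then up, then left.
* Problem sizes in the test-suite and acceptance script (20 kb genomes,
  300–500 sites, depth 1000, 1000 oracle codon pairs) were chosen so each
  statistical check has narrow sampling bands while the whole suite runs in
  seconds.
* The histogram binning (fixed 10-wide bins) and the `high` level preset
  shape are free parameters of the emulation; both are documented defaults,
  not fitted values.

## Known limitations

* No base- or mapping-quality filtering: pileup TSVs carry no qualities.
* Ka/Ks is NG86 with Jukes–Cantor correction only; maximum-likelihood codon
  models and codon-usage corrections are out of scope, and the exact
  stop-codon conventions of other Ka/Ks software may differ at the decimal
  level.
* The strain comparison assumes near-identical orthologs (linear gap
  penalty, nucleotide-level alignment).
* Multi-allelic RNA sites are reduced to the majority non-reference allele.
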