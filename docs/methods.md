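# Methods

This note documents the models, conventions and numerical choices behind
`asmannot`, and what the synthetic benchmarks do and do not demonstrate.

## Problem and coordinate model

The package compares two assemblies of the same genome, A and B, together
with their annotations. All coordinates are 1-based and fully inclusive
(`interval_length = end − start + 1`), matching GFF3 and the way genome
coordinates are printed in the literature; half-open external formats
would be converted at the I/O boundary. Exons are stored in ascending
genomic order on a single chromosome and strand; transcript (spliced)
order is derived from the strand; a CDS is a transcript-coordinate pair
so it survives relocation unchanged. Conceptual translation applies the
standard genetic code to the annotated CDS with **no curation**: internal
stops read through as `*`, codons containing N become `X`, one trailing
stop is dropped. This is deliberate — uncorrected translations are where
assembly damage is most visible.

## Spliced aligner

Transcript sequences are mapped with a two-stage seeded method:

1. **Candidate windows.** A forward-strand index of genomic k-mers
   (default k = 20, N-containing k-mers skipped) is queried with the
   transcript and with its reverse complement; seed hits on one sequence
   are clustered (gap ≤ 20 kb) and clusters with ≥ 2 shared k-mers become
   windows, padded by 1 kb.
2. **Exon chaining.** Within a window, maximal exact matches ≥ 12 bp are
   chained by dynamic programming maximizing covered query bases with
   light gap/junction penalties. Genomic gaps of ≥ `min_intron` = 30 bp
   (and exceeding the query gap by at least that much) become introns at
   zero column cost; smaller gaps are closed by banded edit-distance
   alignment (edlib). Query bases that cannot be placed at a junction
   (e.g. an exon whose genomic copy is gone) stay unaligned.
3. **Splice-site snapping.** Each intron junction may slide by up to
   ±10 exactly-matching columns onto the strand-appropriate splice
   dinucleotides (GT…AG; CT…AC on a minus-strand window), smallest shift
   first. The slide never changes any aligned column, so it is
   identity-neutral.
4. **End extension.** Query ends beyond the outermost anchors are
   extended semi-globally. An extension is kept whole when it is short
   (≤ 30 columns) or at least two-thirds matches; otherwise only its
   best-scoring prefix (+1 match / −2 otherwise) is kept. The two-thirds
   bar separates homologous-but-noisy sequence from random DNA, whose
   best edit-distance alignment sits near 50–55 % matches.

**Identity** counts matches over aligned (non-gap) columns; **coverage**
is the fraction of query bases inside aligned blocks. Because identity
excludes indel columns, alignment paths are normalized to prefer
substitutions over gap pairs whenever unit-cost edit distance is
ambiguous (gap cost 1.5 vs mismatch 1 in the normalization pass);
without this, equally-cheap indel paths would inflate identity by up to
~2 % on noisy sequence. On single-exon instances up to 500 bp with up to
10 % substitution noise, the reported identity agrees with a full
edit-distance DP (1 − distance/columns) to within 0.01.

Retention follows the standard filter: aligned query span strictly
greater than 100 bp ("longer than 100 bp" is read as exclusive) and
identity ≥ 0.95. Per query, the maximal (coverage, identity, aligned bp)
alignment is primary; exact ties are all primary, which is what makes
duplicated genes visible downstream. Coverage curves report, for x in
{0, 0.05, …, 1}, how many queries have coverage ≥ x, under either the
union of all retained alignments ("all") or primaries only ("best");
the union is used rather than a sum so coverage cannot exceed 1.

## Structure comparison

The comparator consumes the *alignment-projected* structure of a foreign
transcript — its exon blocks on the target genome — and the target's own
annotation, all in target coordinates.

* **Comparable**: total exonic overlap ≥ 50 bp, and, if both structures
  are multi-exon, at least one shared intron. "Shared" means both intron
  boundaries agree within the margin V (default 20 bp); requiring both
  boundaries is this package's reading, configurable to exact.
* **Compatible**: over the genomic interval covered by both structures,
  the same introns with every boundary within V. Introns straddling the
  edge of the common interval (beyond V) are exempt.
* **Priority classes**: P1 compatible + identical extent + same gene
  name and evidence accession; P2 compatible + identical extent; P3/P4
  the mapped structure extends beyond the candidate at one/both ends by
  more than V; P5 the mapped structure ends short of the candidate at
  one end; P6 short at both ends, or short at one and long at the other;
  P7 not compatible. P1 requires identical extent on top of matching
  names — otherwise a named, visibly truncated gene would be absorbed
  into the "identical" class and truncations could never be reported for
  named genes.
* **Orientation.** Extension/truncation describe the *mapped* transcript
  relative to the local annotation: a gene whose terminal exon is lost in
  the target assembly maps as a **truncation**. The opposite reading
  (classifying the candidate relative to the mapped structure) is
  equally defensible linguistically; this package fixes the orientation
  so that the event vocabulary of the generator (below) maps one-to-one
  onto the classes.
* **Best match**: lowest priority level; ties by most common exons
  (exon pairs with both boundaries within V); remaining ties by genomic
  start and id, so runs are reproducible.
* **Rollup**: P1–P2 identical, P3–P4 extensions, P5 truncations, P6
  both, P7 complex. Percentages are rounded half-up to one decimal.
* **One-to-one correspondence** (the paper-style notion is left
  undefined in the field): a pair is one-to-one when each member is the
  other's best match and neither is the best match of any third
  transcript. Duplications therefore break one-to-one status, as they
  should.
* **Agreement curves** use exonic base pairs: the fraction of a mapped
  gene's exonic bases covered by any annotated transcript, against the
  gene's spliced length.
* Transcripts with no comparable candidate can be validated at the
  sequence level against the other annotation's spliced mRNAs (edlib
  infix search, ≥ 95 % identity), flagged complete when the whole query
  aligns.

## Protein comparison

Conceptual translations are aligned to model proteins globally with free
end gaps, BLOSUM62 and affine gaps (open −11, extend −1, a length-k gap
costing open + (k−1)·extend). `*` counts as a mismatch against every
residue including `*`: an in-frame stop is annotation damage, not
agreement. Overhangs are *effective*: the residues outside the
best-scoring aligned core (+1 per identical column, −1 otherwise). This
matters because two same-length proteins sharing only a prefix produce no
end gaps — the DP aligns the scrambled tails residue-to-residue — yet
both tails are unalignable in any meaningful sense; the core construction
exposes them.

Decision order (fixed): identical (exact equality) → near-identical
(identity ≥ 0.90 over internal columns, < 10 gap openings, overhangs
≤ 10 aa) → extension / truncation (one-sided overhang > 10 aa on the
predicted / model side, aligned region of near-identical quality) →
divergent ends (overhangs > 10 aa on both sequences) → gapped (modified
identity ≥ 0.90 — identical / non-gap columns — with ≥ 10 gap openings or
a single gap ≥ 30 aa) → different (modified identity < 0.50) → other.
Quantifications that the verbal taxonomy leaves open are set here: "few
gaps" = fewer than 10 gap *openings*; "low identity" = below 0.50; and
divergent-ends takes precedence over different when both apply. All are
configurable through `ProteinThresholds`.

## SNP remapping

A SNP context is flank5 + variant base + flank3 (generator default
250 bp per side). Stage 1 searches with 20-mer seeds (≥ 2 shared);
stage 2 — only when stage 1 finds nothing — drops to 11-mer seeds. Both
stages chain anchors without introns and close gaps with edit-distance
DP, then extend ends under the same accept/trim rule as the spliced
aligner. The variant column scores as a free match (the sampled
individual may carry either allele); reference-allele scoring is a flag.
Tiers: *found* = any hit with identity ≥ 0.90 and coverage ≥ 0.90;
*mapped* = exactly one hit with identity strictly > 0.95 at coverage
≥ 0.90, after merging hits whose intervals overlap by at least half of
the shorter (guarding against split reportings of one locus). Coverage
is measured against the full context length, including the variant base.
The search target is the placed chromosomes; with rescue enabled,
unmapped SNPs are re-searched against the unplaced contig pool and
reported as found there.

## Synthetic dual assembly

The generator is the package's study design, not a test fixture. A
random i.i.d. genome (default GC 0.42, a typical mammalian value) is
overwritten with constructed genes: exon counts 2–8 (4–8 in the event
benchmark, so internal-exon events leave an intact flanking intron),
exon lengths 100–300 bp, intron lengths 60–2000 bp, GT–AG introns,
ATG…TAA CDS with internal stops rewritten away, genes on both strands
with equal probability, non-overlapping with a 300 bp margin. Model
mRNA and protein equal the spliced sequence and its translation by
construction (asserted at generation time).

Assembly B is derived by applying labeled events. Deletion defaults to
an equal-length N run (a scaffold gap — the common real-world mode; true
excision is a flag). Translocation N-fills the source slot and
re-inserts the segment at the destination, modeling a contig moved out
of its scaffold position. Duplication inserts a copy; unplace removes a
segment into the unplaced contig pool; substitution noise and ±1–2 bp
frameshift indels act within a target interval.

**B's annotation is the naive coordinate projection** of the source
annotation through the edits: exon slots now containing Ns or inverted
sequence are kept in the model. This emulates an evidence-guided
annotator that preserves a gene's known extent across assembly
artifacts — the documented failure mode in which a mis-oriented contig
leaves the annotation holding weakly-supported, frameshifted exons. It
is also the only construction under which assembly damage separates the
mapped structure from the local annotation at all: re-annotating B by
realignment would make the two tautologically identical, and no
truncation or complex class could ever arise. The expected-outcome
decision table follows from this choice:

| event on a gene                    | structure class | protein class |
|------------------------------------|-----------------|---------------|
| none                               | identical       | identical     |
| substitution noise ≤ 1 %           | identical       | near-identical (or identical) |
| terminal-exon deletion             | truncations     | — (X-runs, not asserted) |
| internal-exon deletion             | complex         | —             |
| intra-genic inversion breakpoint   | complex         | —             |
| whole-gene inversion/translocation | identical       | identical     |
| frameshift indel                   | identical       | anything but identical/near-identical |
| whole-gene duplication             | identical (both copies; one-to-one broken) | identical |

SNPs planted inside a segment that is later duplicated are expected
*found, not mapped*; SNPs inside a segment moved to the unplaced pool are
*unmapped*, becoming *found* when rescue against the unplaced contigs is
enabled.

What the synthetic data does **not** emulate: repeat families and
segmental homology (so candidate windows are cleaner than in a real
mammalian genome), alternative splicing, UTR/CDS annotation ambiguity,
evolving evidence sets between annotation runs, and base-call error
profiles. Passing the benchmarks therefore demonstrates the correctness
of the comparison machinery under controlled damage, not the field
accuracy of the aligner on repeat-rich genomes.

## Benchmark sizes and determinism

The shipped study conditions are: null run 2 × 500 kb with 100 genes and
500 SNPs; event recovery 20 genes per category plus 20 controls on
3 × 500 kb; SNP tiers 1,000 SNPs (100 duplicated, 100 unplaced) on
2 × 500 kb; oracle checks on 200 random ≤ 500 bp DNA instances and 50
≤ 50 aa protein toys; monotonicity fuzzing over 20 seeds. These sizes
exercise every code path — multiple windows, both strands, all event
kinds — while keeping a full run to around a minute. Every stochastic
component is a pure function of an explicit seed; `scripts/acceptance.py`
derives all of its seeds from `--seed` and its reports are byte-stable
for a given seed.

## Known limitations

* The aligner is exact-seed based: a gene whose every exon diverges
  beyond seed density (or sits inside unmodeled repeats) can be missed;
  stage-2 sensitivity for transcripts (as opposed to SNP contexts) is
  not implemented.
* Intron placement trusts GT–AG snapping within ±10 bp; non-canonical
  splice sites keep the chain-determined junction, which may be off by a
  few bases (inside the 20 bp comparison margin).
* The protein classifier's effective-overhang construction uses a single
  best core; a protein with two well-conserved domains separated by a
  long scrambled insert classifies by the stronger domain.
* One direction of comparison is computed at a time (A onto B);
  reciprocal one-to-one analysis runs the mapping twice.
* GFF3 support covers the gene/mRNA/exon/CDS dialect this pipeline
  emits; GTF, BED and VCF are out of scope.
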