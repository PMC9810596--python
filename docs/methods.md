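# Methods

## Model and coordinate conventions

The mitochondrial genome is a single circular replicon; all coordinates are
0-based, half-open, on the forward axis, and strand affects only reading
direction. Annotations may wrap the origin, in which case `end` exceeds the
genome length and indexing is modular. An ORF's mRNA is the forward slice
(`+`) or reverse complement (`-`) of its genomic interval with
`polya_completion` (0–2) adenosines appended: several mitochondrial mRNAs end
in a partial stop (U or UA) completed to UAA by polyadenylation, and the
package treats the completion count as annotated biology, not something to be
inferred from sequence. Consequently `(end − start + polya_completion)` must
be divisible by 3, and A-site positions can only ever fall on the
genomically encoded bases of a polyA-completed terminal codon (1–2 of its
bases have no genomic coordinate). This caps terminal-codon sensitivity for
those genes and is a property of the data, not an implementation choice.

The genetic code is NCBI translation table 2 (vertebrate mitochondrial) with
the stop codons split into canonical (UAA/UAG) and non-canonical (AGA/AGG)
categories, reflecting the two release-factor specificities. Other codes can
be loaded by NCBI table id for cross-species use.

Bicistronic overlaps (ATP8/ATP6, ND4L/ND4) are allowed: a genomic position may
map into two same-strand ORFs, and counting attributes a read to **both**
frames while reporting the number of double-counted reads. The original
analyses of such data do not state their attribution rule; counting toward
both and flagging it was chosen over guessing.

## Read processing

- **Adapter trimming**: the 5'-most position at which an adapter prefix of at
  least `min_overlap` (default 3) nt matches the read suffix with mismatch
  fraction ≤ `max_error_rate` (default 0.1) truncates the read. These are
  standard small-RNA trimmer defaults; only the adapter sequence itself
  (`TGGAATTCTCGGGTGCCAAGG`) is dictated by the library design.
- **Length filter**: retain 25–35 nt. Untrimmed reads are dropped by default
  because with 50-nt raw reads and ≤ 40-nt inserts the adapter must appear; a
  flag retains them for other designs.
- **Mapping**: every circular offset on both strands is considered and ranked
  by mismatch count (default budget: 1 mismatch, approximating short-read
  aligner tolerance at these lengths). A read is UNIQUE only if a single locus
  attains the minimum; ties always yield MULTI and MULTI reads are excluded
  from counting, since codon-level attribution needs a unique locus. The
  search uses a k-mer index with a pigeonhole completeness guarantee (a read
  with ≤ m mismatches contains an exact seed in one of m+1 chunks), so it is
  exactly equivalent to a brute-force scan of the doubled genome — an
  equivalence the test suite enforces against an independently written scan —
  while handling 50k reads in seconds on one CPU. Reads too short to seed fall
  back to the full positional scan. The 5' coordinate convention is the
  lowest-coordinate aligned base on `+` and the highest on `-`, so the A-site
  offset is always applied along the read's own 5'→3' sense.

## A-site assignment

One fixed offset of 14 nt from the footprint 5' end to the first base of the
A-site codon, applied to all retained lengths (25–35 nt); a per-length offset
map is accepted in configuration but not default. A-sites outside every
same-strand ORF are tallied in an off-ORF counter rather than silently
dropped. The same geometric rule applies at stop codons regardless of how far
the footprint 3' end extends past the ORF.

## Stall statistics

- Relative transcript occupancy: gene total over grand total; sums to 1.
- Size factors: mean gene total divided by the gene's total (arithmetic mean
  over genes with nonzero counts; zero-count genes are excluded with a
  warning). After scaling, every gene total equals the pre-scaling mean.
- Terminal-window occupancy: sum of (scaled) counts over the gene's final 15
  codon positions divided by the (scaled) gene total. The default window is
  the stop codon plus 14 upstream sense codons; `include_stop=False` selects
  the 15 sense codons before the stop instead. Both variants exist because the
  two natural readings of "the last 15 codons" differ on whether the stop is
  included; the report header records which was used. Within one gene the
  size factor cancels; it is applied anyway so window and total columns are
  comparable across samples.
- Fold changes (terminal-window and codon-identity) use a Haldane-style
  pseudocount of 0.5, applied only when a raw count on either side is zero,
  and such cells are flagged. Counts stay exact integers until the final
  division.
- Codon-identity profiles support two normalizations — by sample total and
  per codon occurrence — and carry both presentation orderings (by mtDNA
  codon frequency and by sequencing coverage), since the ordering is a
  display key, not part of the statistic.
- The upstream queue scan searches 10–16 codons upstream of the stop for the
  maximal count, reports its offset and its fold over the gene's median
  per-codon count, and marks folds below 2 as non-significant. The 12-codon
  expectation comes from footprint geometry: a ~35-nt footprint covers ~12
  codons, so a ribosome queued immediately behind a stalled one sits 12–13
  codons upstream.
- No multiple-testing machinery is attached: these are descriptive fold
  changes over 13 genes and 64 codon identities.

## Release-assay arithmetic

Released fraction = supernatant / (supernatant + pellet) scintillation
counts. Background (spontaneous release without any factor, typically 10–15%
of total peptide) is corrected by simple subtraction clamped at zero; a
rescaled variant (sample − bg)/(1 − bg) is available behind a flag and the
report records which was used — the plain subtraction is the default because
the source protocols state only that the no-factor value "is used as
background". Replicate summaries report mean and SD (ddof = 1, n ≥ 2) and an
unpaired two-tailed t-test with the 0.05/0.01/0.001 star convention. The
active-ribosome fraction is moles of synthesized peptide per mole of
ribosomes; values above 1 trigger a unit-error warning.

## Synthetic data generator

The generator emulates a mitoribosome-profiling library: per-gene read mass
proportional to transcript weight times total codon density; per-codon density
uniform except programmed stall peaks (multiplier at a codon or at the stop
via the TERMINAL sentinel) and queue peaks (multiplier at
`codon_index − queue_offset`, default 12); footprint lengths drawn from a
distribution peaking at 33–35 nt over 25–40 nt (lengths above 35 exist
specifically to exercise the max-length filter); the A-site first base exactly
14 nt from the footprint 5' end for every length, mirroring the analysis
pipeline's single-offset model; reads are footprint + adapter truncated to
50 nt with constant quality. Footprints at ORF starts extend into upstream
genomic sequence, as mitochondrial transcripts are essentially UTR-less.
Identical seeds give byte-identical FASTQ and truth tables.

What it deliberately does **not** model: sequencing errors by default (an
optional substitution rate exists for mismatch-tolerant mapping tests),
ligation bias, PCR duplicates, quality-score structure, length-dependent
A-site offsets, and the shorter footprints produced by stalled ribosomes with
an empty A-site (real analyses exclude those footprints; a generator for them
would be guessing their length distribution). Passing tests on simulated data
therefore demonstrate the correctness of the pipeline's arithmetic and
geometry, not robustness to library artifacts of real data.

The bundled reference is a **synthetic** genome mirroring the human mtDNA
layout qualitatively: 13 ORFs with realistic codon counts, ND6 alone on the
light strand, COX1 ending AGA and ND6 ending AGG, exactly one CGG codon in
all ORFs (planted as ND6's penultimate codon, its only occurrence in the real
transcriptome as well), ATP8/ATP6 overlapping by 46 nt and ND4L/ND4 by 7 nt,
four genes with polyA-completed stops, and tRNA-like spacers. Its coordinates
are not those of the reference human genome; real references load via the
FASTA/TSV/GFF3 readers. Construction is deterministic (fixed internal seed)
with rejection sampling at the bicistronic junctions so both reading frames
are clean, and the builder asserts the layout facts above on every build.

## Problem sizes and numerics

Simulation-based tests and the acceptance script use 50,000-read libraries —
enough that per-gene window occupancies have relative standard errors of a few
percent while the whole suite runs in well under a minute per sample on one
CPU. Stochastic checks compare against closed-form expectations computed from
the planted density vectors (e.g. a terminal multiplier *m* on an *n*-codon
gene gives expected window occupancy (14 + *m*)/(*n* − 1 + *m*) with the
stop-inclusive window) within 3 standard errors via the delta method, with all
seeds fixed. Conservation and normalization identities (occupancies summing
to 1, size-factor-scaled totals equal, self-fold-change of 1) are asserted to
1e-9 or tighter on integer-count inputs.

## Known limitations

- The mapper's mismatch and multimapper defaults approximate, but are not
  asserted equivalent to, the general-purpose aligner settings used in
  published pipelines, which are not fully specified.
- Nuclear-genome contamination filtering is out of scope; input reads are
  assumed to come from purified monosome fractions.
- Reproducing published per-gene occupancy numbers (e.g. COX1 at ~20% of
  wild-type mtRPFs dropping to ~10% upon mtRF1 loss, with terminal fold
  changes of ~4.5/3.5 on COX1 and ~2.5/3.0 on ND6) requires the deposited
  sequencing libraries (ArrayExpress E-MTAB-11687) and the real mitochondrial
  genome; that is an integration experiment to run with the FASTA/annotation
  loaders and this same pipeline, not part of the test suite.
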