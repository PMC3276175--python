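# Methods

## Scope and model

`plastidnc` implements threshold-based discovery of noncoding and
antisense RNAs from strand-specific RNA-Seq coverage of a chloroplast
genome, plus the surrounding plumbing (annotation handling, abundance
comparison between genotypes, ORF scanning) and a stylized read simulator
that provides ground truth. The method is deliberately non-statistical:
the discovery unit is a coverage run, not a model fit. There is no
dispersion model, replicate handling, or FDR control, because the
procedure being implemented is a fixed-threshold rule.

### Coordinates and conventions

All interval arithmetic is 1-based inclusive, matching GenBank and the
packaged candidate catalog; BED6 and bedGraph writers convert to 0-based
half-open at the boundary. Strands are `+`/`-`. Candidate *size* is
reported as the endpoint difference `stop - start`: on the packaged
catalog this single convention reproduces both the published minimum
(48 nt, the as-psbT row) and the published mean (217 nt); the inclusive
length is exposed as a second accessor. Features and queries may not wrap
the circular origin; wrap-around inputs are rejected (no cataloged
candidate wraps).

### Peak calling

A strand's qualifying runs are the maximal stretches of bases with depth
≥ `end_threshold` (default 10) containing at least one base with depth
≥ `peak_threshold` (default 50). Both comparisons are inclusive on the
"in" side: "fell below 10×" terminates a run at the first base of depth
≤ 9, and "a minimum of 50× coverage" triggers at depth exactly 50. With
several genotypes, runs overlapping by ≥ 1 nt on the same strand are
grouped; the group's end source is the highest-priority genotype present
(wild type before the ribonuclease mutant, so wild-type termini win when
both genotypes trigger), and one candidate is emitted per end-source run
so that separate wild-type peaks are never artificially fused by a
broader mutant peak. `trigger_genotypes` records every genotype whose
maximum depth within the final span reaches the peak threshold — this is
what makes "mutant-only" candidates queryable. Optional gap merging
(`merge_gap`) is off by default: split peaks are reported as observed.

### Classification and naming

Candidates overlapping ≥ 1 opposite-strand gene or intron are antisense;
otherwise a candidate lying inside the span of a cluster (operon /
transcription unit label from the annotation) without same-strand
overlap is intergenic, with the flanking cluster genes as its context;
same-strand overlaps are rejected as probable fragments of the known
sense transcript, and everything else as unassigned. Antisense wins over
intergenic when both apply. Pairing-region flags test overlap with ±25 nt
windows around the target's strand-aware 5′ and 3′ terminal bases
(`internal` when only the body is touched); the window half-width is a
free parameter — no published width exists — chosen small because the
5′ flag is meant to capture the translation-initiation region.
Systematic names follow the catalog's conventions (`as-X`, `as-Xi`,
`nc-X-Yint`, `-5'`/`-3'` when exactly one terminus window is hit,
ordinals in genomic order for shared base names). rRNA-targeting
candidates are not filtered by default; an `rrna_mask` option exists for
rRNA-depleted libraries.

### Abundance and genotype comparison

Abundance is the count of read starts within a candidate's interval on
its strand, normalized to counts per million placed reads (cpm).
Per-candidate fold changes add a pseudocount of 0.5 cpm to both sides so
mutant-only species stay finite. The global antisense ratio is pooled —
the ratio of summed cpm — not a mean of ratios, matching its intended
reading as "antisense reads overall were ~4-fold higher". Note that cpm
normalization compresses the pooled ratio below the true amplification
factor by (1 + f)/(1 + a·f), where f is the antisense fraction of the
wild-type library and a the amplification; at the simulator's default
f ≈ 0.06 and a = 4 the expectation is ≈ 3.5, and the acceptance
experiment checks the ±20 % band around 4 accordingly. Doubly-placed
reads (inverted repeat) count at full weight at both placements by
default, mirroring an aligner run that reports up to two hits; a
half-weight option exists.

### ORF scanning

Scanning is single-stranded on the candidate's own strand (the genomic
interval is reverse-complemented for minus-strand candidates). Starts are
ATG only by default — the reported conserved ORFs have conventional
starts — with a configurable start-codon set; stops are TAA/TAG/TGA;
codons containing N match neither. Per frame, each stop-delimited segment
yields at most one ORF anchored at its first ATG, and ORFs without an
in-frame stop are not reported. `aa_length` counts Met through the
residue before the stop, so a 49-aa ORF spans 150 nt with its stop.

## The simulator

The generator emulates, on a 50 kb toy plastome, the features of the real
system that stress the pipeline: gene clusters on both strands (one
intron, one rRNA gene mirrored into a reverse-complementary inverted
repeat whose reads are doubly placed); sense transcription with
inefficient termination (30 % of molecules gain a geometric 3′
read-through, mean 150 nt); dedicated antisense transcription units;
a mutant genotype with 4× antisense amplification and geometric 3′
extensions (mean 60 nt) on all molecules; hydrolysis fragmentation with
uniform breakpoints under an 80 nt retention floor (mean fragment
~150 nt); 85 nt reads tiling each fragment at ~1×, so per-base depth
approximates transcript copy number; and ligation end-bias.

End-bias is modeled as sequence-anchored *structured spans* (40 nt):
each transcription unit's 5′ and 3′ terminal spans, plus roughly one
potential interior span per 250 nt of transcript, are each "structured"
with probability `prob_structured_end` (default 0.3), and reads
overlapping an active span are dropped. Anchoring the spans to genomic
positions (drawn from the configuration seed, hence shared by both
genotypes) is what reproduces the observed artifact: terminal spans
under-represent transcript ends, and interior spans split one transcript
into multiple coverage peaks across all molecules, which per-molecule
random dropout cannot do at realistic depth. The total-dropout rule is a
stylization of structured regions being depleted from ligation-based
libraries.

Default conditions: sense mRNAs at 300 expected copies (tRNA 200, rRNA
100 — the library is rRNA-depleted), antisense units at 80, i.e. well
above the 50× trigger in the wild type and an antisense read fraction of
a few percent, which is what a total-RNA chloroplast library looks like
after rRNA depletion. Scenario factories provide: a recovery benchmark
(20 antisense units of 300 nt at 80 copies opposite the long genes,
suppression off, sense at 150 copies — sized so a single-CPU run takes
seconds); and a mutant-only scenario (one unit at 30 wild-type / 80
mutant copies, below vs. above the trigger). Molecule counts are Poisson;
all randomness flows through one numpy generator per call, so a fixed
seed gives bit-identical placements.

What the simulator does **not** model: sequencing errors and quality,
PCR duplicates, real secondary-structure prediction, spliced alignment,
nuclear/mitochondrial contamination, and biological variation between
replicates. Passing recovery tests therefore show that the pipeline's
logic is correct under the stated generative model, not that the
thresholds are optimal for any particular real library.

### Recovery scoring

A planted unit is recovered when some same-strand candidate matches it at
interval Jaccard ≥ 0.5; precision is the fraction of candidates matching
a unit; the fragmentation ratio is (candidates overlapping truth) /
(recovered units), > 1 when transcripts split. Conventions: no candidates
→ precision 1.0 with an explicit flag; no recovered units → ratio NaN.
In the end-to-end experiments candidates are first classified and only
antisense-classified candidates are scored against antisense units, so
sense transcription peaks (which the classifier rejects by design) do not
count as false positives.

## Problem sizes and numerical choices

The test suite and acceptance script use: 1,000 random tracks (length
≤ 2,000, depths 0–100) for peak-caller oracle equivalence; 500 random
300-mers for ORF-scanner equivalence; one seeded recovery run (20 units)
and 100 seeded replicates for the fragmentation experiment; 200k reads
per genotype for the fold-change experiment, averaged over three
replicates to damp Monte-Carlo error. These sizes keep a full single-CPU
run to a few minutes while leaving the stochastic checks far from their
pass boundaries. Ties in ORF selection break toward the smaller offset;
candidate ids are assigned in genomic order; merging iterates to a fixed
point.

## Known limitations

- The catalog's RT-PCR/blot tallies are parsed as printed; the published
  prose count of blot-detected species (48) differs by one from what the
  published table itself contains (49 rows with at least one band), and
  the computed statistic follows the table.
- Wrap-around (origin-spanning) features are rejected rather than
  handled.
- bedGraph ingestion yields depth-only coverage; abundance estimation
  then refuses, since read starts cannot be reconstructed from depth.
- The multi-genotype unifier assumes genotypes share one genome build;
  there is no lift-over.
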