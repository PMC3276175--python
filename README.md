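# plastidnc

Strand-specific RNA-Seq discovery of chloroplast noncoding and antisense
RNAs, for researchers studying organellar transcriptomes and
posttranscriptional regulation.

Chloroplast transcription terminates inefficiently, so both strands of the
plastome are pervasively transcribed and a population of noncoding RNAs
(ncRNAs) — mostly antisense RNAs (asRNAs) opposite protein-coding and tRNA
genes — accumulates in wild-type plants and overaccumulates when the
3′→5′ exoribonuclease polynucleotide phosphorylase (cpPNPase, null mutant
*pnp1-1*) is missing. `plastidnc` implements the coverage-threshold
discovery pipeline used to catalog this population from directional
RNA-Seq, together with a ground-truthed read simulator so every stage is
testable without sequencing data.

## The method

Given per-base stranded depth *d(x)* for each genotype *g*:

1. **Transcription peaks.** A candidate ncRNA is triggered wherever
   *d(x) ≥ 50* at one or more nucleotides and extends in both directions
   until *d(x) < 10*. Runs are computed per strand per genotype;
   overlapping runs from different genotypes are unified, with candidate
   termini taken from the highest-priority genotype that triggered
   (wild type before mutant). Candidates whose 50× trigger is reached in
   only one genotype are reported as genotype-specific.
2. **Classification.** A candidate overlapping an opposite-strand gene or
   intron is an asRNA (`as-X`, with `-5'`/`-3'` suffixes locating the
   pairing region against the target's termini); a candidate inside a gene
   cluster's span with no same-strand exon overlap is a strictly noncoding
   intergenic RNA (`nc-X-Yint`); same-strand overlaps are rejected as
   fragments of known transcripts.
3. **Abundance.** Transcript abundance is estimated by binning reads by
   start position; counts are normalized to counts per million placed
   reads (cpm), and the pooled mutant/wild-type ratio over asRNA regions
   summarizes the global antisense amplification.
4. **ORFs.** Candidates are scanned on their own strand for ATG→stop open
   reading frames (standard code), since some ncRNAs carry small conserved
   ORFs.

Reads may map to both copies of the plastome's large inverted repeat; up
to two placements per read are accepted and, by default, counted at full
weight in both copies.

The package also ships the published 107-candidate catalog (coordinates,
strand, RT-PCR and RNA gel blot results) as a parsed fixture with summary
statistics.

## Worked example

Simulate a two-genotype toy plastome experiment and run the pipeline:

```
plastidnc simulate --seed 7 --out-prefix scratch/toy
cat > scratch/run.cfg <<EOF
genotype.WT=scratch/toy.WT.placements.tsv
genotype.pnp1-1=scratch/toy.pnp1-1.placements.tsv
annotation=scratch/toy.gff3
genome_fasta=scratch/toy.fasta
priority=WT,pnp1-1
out_dir=scratch/toy_out
EOF
plastidnc report --config scratch/run.cfg
```

which prints (abridged):

```
n_candidates    14
n_antisense     12
n_intergenic    2
n_rejected      39
min_length      151
max_length      306
mean_length     232.28571428571428
n_mutant_only   6
global_antisense_ratio  4.243082618993963
```

14 candidates survive classification (12 antisense, 2 intergenic within a
cluster gap); the 39 rejections are sense-strand transcription peaks —
the annotated genes themselves. Six candidates cross the 50× trigger
only in the *pnp1-1* reads, and the pooled antisense read ratio (4.24)
reflects the simulated 4-fold antisense amplification in the mutant. `scratch/toy_out/` holds BED6/GFF3/TSV exports and the
summary. The catalog fixture is summarized with:

```
plastidnc catalog-stats
```

whose output includes `n_total 107`, `n_antisense 95`, `n_intergenic 12`,
`min_len 48`, `mean_len 217.21`.

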