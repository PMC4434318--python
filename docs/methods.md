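# Methods

This document records the analysis conventions and algorithms implemented in
`tssqc`.

## Coordinates and offsets

All internal coordinates are 1-based and inclusive on both ends. Strand-aware
"offset" coordinates relative to a gene's start codon place the A of the ATG
at +1; the base immediately upstream is −1 and **there is no offset 0**. The
helper `start_codon_analysis._shift` moves along this axis, skipping zero.
On the minus strand, "downstream" means decreasing genomic coordinate;
`_util.sense_slice(genome, chrom, strand, pos, n)` returns `n` bases of
transcription-sense sequence whose first base sits at `pos` on both strands.

## Read processing

Library reads begin with a ligation tag: 4 random nucleotides, the fixed
cassette `CGCGCG`, then 2 random nucleotides (a fragmented variant
`NNNNGCCGCG NN` is also recognised). The 4+2 random bases form the UMI;
the remainder is the RNA insert. Reads failing the cassette are counted by
failure reason. Inserts are mapped exactly (k-mer index, unique placements
only, with a first-base-mismatch fallback because template-switching can
replace the first nucleotide). PCR duplicates are removed on the key
(chromosome, 5'-end position, strand, UMI), keeping first occurrences in
input order. Unique molecules become per-sample, per-base, stranded 5'-end
count tracks.

Reverse-transcriptase slippage is diagnosed from first-base mismatches: at
sites where a pyrimidine is followed by AAA (with A at −7 of the mapped
position), slipped reads map one base upstream of the true start with an A
in place of the genomic pyrimidine. `mismatch_slippage_profile` reports
per-site and genome-wide rates.

## Peak calling

TSS positions across all TAP-treated samples are merged per (chromosome,
strand) and chained by single linkage: two adjacent positions join the same
cluster when their distance is at most `max_gap` (default 50, inclusive).
A cluster is kept when at least one sample contributes `min_reads` (default
4) unique molecules to the whole cluster (a per-position variant exists).
The summit is the position with the highest pooled count; ties break towards
the transcription-upstream position. Identifiers `TSSC#####` are assigned
in (chromosome, strand, start) order, so they are independent of input
ordering.

## Genomic categories

Each cluster is categorised at its summit (configurable to "any member
position") against the annotation, in strict priority order:

| code | meaning |
|------|---------|
| O | sense 5'UTR of a verified ORF — `[transcript 5' end, ATG)`, half-open at the ATG |
| F | inside a stable annotated ncRNA (incl. transposons) |
| C / X / S | inside a CUT / XUT / SUT (in that priority) |
| B | sense CDS or 3'UTR of a verified ORF |
| A | antisense to a verified ORF |
| I | intergenic |

Dubious ORFs are ignored entirely. Ties between overlapping ORFs resolve to
the gene with the nearest downstream ATG.

## Filters and normalisation

Two filters separate genuine capped 5' ends from background:

- **Signal-to-noise**: `log2((tap + 1) / (notap + 1)) >= 0.55` on
  normalised cluster totals. TAP+ and TAP− libraries are put on a common
  per-molecule scale with spike-in median-of-ratios factors computed across
  *all* samples (the spike-in is ligated independently of TAP treatment);
  without a spike-in, total library counts are the fallback.
- **Initiation accuracy**: the fraction of member positions whose sense base
  is a purine preceded by a pyrimidine must be at least 0.80 (unique
  positions by default; a read-weighted variant exists).

Size factors for differential tests use the median-of-ratios estimator over
either spike-in positions or an internal standard: per-ORF counts in the
window −50..−10 relative to the ATG, a region whose initiation is expected
to be stable across the studied genotypes.

## Differential initiation

Counts per cluster are compared between two conditions with a
negative-binomial Wald test: per-unit moment dispersion estimates are
shrunk 50/50 (geometric mean, clamped to 8×) towards a fitted mean–
dispersion trend `a0 + a1/mu`; the Wald statistic on `log2((mu_b + 0.5) /
(mu_a + 0.5))` is referred to a t distribution with `n1 + n2 − 2` degrees
of freedom and corrected with Benjamini–Hochberg. A cluster is "significant"
when `padj < alpha` and the fold change is positive.

## Start-codon (isoform) analysis

For a TSS at offset `off` relative to a gene's ATG (window −200..+100), the
first two ATGs at or downstream of the TSS (scanning transcription-sense,
including the TSS base, up to 1 kb past the annotated stop or the transcript
end) determine the isoform class:

- `ANNOTATED_FIRST` — TSS upstream of the ATG and no intervening ATG;
- `UORF` — TSS upstream, but another ATG precedes the annotated one;
- `ITSS_INFRAME` / `ITSS_OUTFRAME` — TSS at/after the ATG; the first
  downstream ATG is in frame iff `(offset − 1) % 3 == 0`;
- `NO_ATG_FOUND` — no ATG before the search limit.

Supporting statistics: metagene profiles of initiation around the ATG
(boxcar-smoothed, edges left unsmoothed), per-offset ANOVA between
condition groups, in-frame codon-bias profiles (9-nt bins tiling +4..+1000,
normalised to the 500–1000 reference region) with both a bin-level and a
more powerful gene-level ANOVA, N-terminal methionine frequencies from
translated ORFs, and spurious-ORF metrics (first ATG to first in-frame
stop) for pervasive transcripts.

## Sequence and chromatin profiles

Position frequency matrices are accumulated over transcription-sense windows
(default −10..+5, no offset 0) around sites, weighted per site or per read;
windows crossing contig edges are skipped and counted. The genome-wide
initiation consensus scan finds every position with A at −8, a pyrimidine
at −1 and a purine at +1, on both strands, and reports the fraction used by
observed TSSs. Nucleosome metaprofiles average an occupancy track in signed
transcription-sense distance around anchors.

## Synthetic validation data

`synthetic_data.simulate` builds a fully ground-truthed study: random
genomes with planted promoters (major blocks of 8 consensus-conforming
positions, minor blocks of 4), uORF / internal-start / slippage isoforms,
pervasive transcripts with short first ORFs and long 3' tails, a
second-species spike-in, four genotypes (wild type, *upf1*-like,
*rrp6*-like, double) with class-specific stabilisation effects, negative-
binomial molecule counts, PCR duplicates, TAP− residual background, and a
nucleosome track with NFRs. Every read carries its originating TSS in the
ground truth, which the test-suite and `scripts/acceptance.py` use to score
recovery, classification, normalisation accuracy, calibration and power.
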