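# tssqc

Analysis toolkit for capped-RNA 5'-end (TSS) sequencing in budding-yeast
RNA-quality-control mutants. The package covers the full path from tagged
reads to biological conclusions:

- **`read_processing`** — ligation-tag / UMI extraction, exact read mapping,
  UMI deduplication, per-base 5'-end count tracks, and a mismatch profile
  that flags reverse-transcriptase slippage at pyrimidine–AAA sites.
- **`peak_calling`** — single-linkage clustering of TSS positions into TSS
  clusters (TSSCs) with deterministic identifiers and summits.
- **`annotate_classify`** — genomic category assignment (5'UTR, CDS/3'UTR,
  antisense, CUT/XUT/SUT, stable ncRNA, intergenic) against a feature
  annotation, with start-codon corrections.
- **`filter_quantify`** — signal-to-noise (TAP+ vs TAP−) and initiation-
  accuracy filters, spike-in and internal-standard size factors, and a
  negative-binomial Wald test for differential initiation.
- **`start_codon_analysis`** — transcript-isoform classification relative to
  the annotated ATG (uORF, internal in/out-of-frame starts), metagene
  profiles, in-frame codon-bias statistics, N-terminal methionine
  frequencies, and spurious-ORF metrics for pervasive transcripts.
- **`motif_profiles`** — position frequency matrices around summits, a
  genome-wide scan for the initiation consensus (A at −8, pyrimidine at −1,
  purine at +1) and nucleosome-occupancy metaprofiles.
- **`synthetic_data`** — a fully ground-truthed simulator of the whole
  experiment (genomes, annotations, isoforms, effects, spike-ins, libraries)
  used for validation.
- **`cli_io`** — file formats (FASTA, GFF3/TSV/BED, bedGraph, alignment
  tables, FASTQ), a YAML-driven pipeline configuration and the end-to-end
  orchestrator `run_pipeline`.

## Quick start

```sh
tssqc simulate --seed 1 --out data/          # synthetic dataset + ground truth
tssqc run --config config.yaml               # full pipeline from a YAML config
tssqc tss-extract data/alignments_wt_tap_1.tsv --out-prefix tracks/wt_1
tssqc callpeaks tracks/wt_1 --out clusters.tsv
tssqc motif data/genome.fa --clusters clusters.tsv
```

A minimal `config.yaml`:

```yaml
data_dir: data
out_dir: results
contrast: [wt, upf1_rrp6]
normalization: internal
```

Or from Python:

```python
from tssqc import PipelineConfig, run_pipeline
res = run_pipeline(PipelineConfig(data_dir="data", out_dir="results"))
print(res.summary)
```

## Conventions

All internal coordinates are 1-based inclusive; BED/bedGraph files are
converted at the I/O boundary. Offsets relative to an ATG place the A at
+1 with no offset 0. See `docs/methods.md` for the analysis details.

## Testing

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
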