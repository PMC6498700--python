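# platepipe

Preprocessing for plate-based UMI single-cell RNA-seq (CEL-Seq / CEL-Seq2 /
SORT-seq style chemistry: cell barcode + UMI on read 1, transcript sequence
on read 2).

The pipeline:

1. **demultiplex** — split paired-end FASTQ into per-cell transcript FASTQ
   files by whitelist barcode (Hamming matching with tie rejection),
   filtering on barcode/UMI base quality, and appending the UMI to each
   read header as `<id>:UMI:<seq>`.
2. **align** — run any external aligner per cell (command template with
   `{fastq} {out} {index}` placeholders) or adopt pre-existing SAM/BAM
   files; the aligner must preserve read names so the UMI tag survives.
3. **count** — assign each aligned read to at most one gene by
   featureCounts-style union-mode exon overlap, deduplicate UMIs per gene
   per cell, and write a genes × cells count matrix (TSV) plus per-cell QC
   metrics (mapped reads, gene reads, total/mito/protein-coding UMIs,
   genes detected, reads per raw and directionally corrected UMI, …).
4. **qcplots** — per-metric boxplots across experiments with cells
   overlaid as points; plus `rview_data`/`gview_data`/`combine_tracks` for
   UMI-colored read-alignment tracks over gene isoform structure at
   arbitrary genomic coordinates.
5. **tenx-qc** — per-cell mapped-read / gene-read tallies from Cell
   Ranger-style BAMs (CB/GX tags) restricted to a filtered-barcode list.
6. **simulate** — a synthetic fixture generator (miniature FASTA + GTF,
   whitelist, paired FASTQ, per-cell SAMs) with exact, seeded ground-truth
   bookkeeping of every read's fate, so the whole pipeline is testable at
   desk scale.

## CLI walkthrough

```sh
# generate a seeded synthetic dataset with ground truth
platepipe simulate --seed 1 --out-dir sim/

# demultiplex (barcode = read-1 bases 0-8, UMI = bases 8-14)
platepipe demultiplex --r1 sim/r1.fastq.gz --r2 sim/r2.fastq.gz \
    --whitelist sim/whitelist.tsv --bc-len 8 --umi-start 8 --umi-len 6 \
    --min-phred 10 --max-mismatch 1 --experiment-id sim --out-dir demux/

# adopt the simulator's per-cell alignments (or use --cmd "<aligner template>")
platepipe align --cells demux/cells.tsv --pre-aligned sim/sam --out-dir aln/

# union-mode UMI counting
platepipe count --cells aln/cells.tsv --gtf sim/annotation.gtf \
    --strand sense --out-dir counts/

# QC boxplots (multi-page PDF, or a directory of SVGs)
platepipe qcplots --cells counts/cells.tsv --out qc.pdf

# Cell Ranger BAM QC
platepipe tenx-qc --bam run.bam --barcodes barcodes.tsv --label v3 --out tenx.tsv
```

`counts/counts.tsv` is tab-delimited with a `gene_id` header column and
one column per cell; with the default (error-free) simulation config it
reproduces `sim/truth/counts.tsv` exactly.

## Conventions

- Genomic coordinates are 0-based half-open internally; GTF input and
  plot axis labels use the 1-based conventions of their formats.
- The reported count matrix uses raw distinct-UMI counts; directional
  UMI collapse (absorb a UMI into a Hamming-1 neighbor with ≥2× support)
  feeds only the reads-per-corrected-UMI metrics.
- Spike-in genes (`ERCC-` id prefix by default) are counted in the matrix
  but excluded from biological summary metrics.
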