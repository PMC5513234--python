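# barcodevar

Mitochondrial COI-barcode diversity analysis for population geneticists and
barcoding practitioners: how much sequence variation does a species carry,
is the standard 648-bp COI barcode window representative of the whole
coding mitogenome, is that variation synonymous, and how does diversity
relate to census population size?

## What it computes

* **Average pairwise difference (APD = π)** — for a group of aligned
  sequences, the mean uncorrected p-distance over all unordered pairs,
  as a percent, with pairwise deletion of gaps/N/ambiguities:
  `APD = 100 · (2 / n(n−1)) · Σ_{i<j} d_ij`. Within-group, between-group,
  and seeded subsampling variants.
* **Klee diagrams** — every sequence encoded as a binary indicator vector
  (4 entries per column), pairwise Pearson correlation, and an objective
  sequence ordering from deterministic UPGMA on the p-distance matrix.
  Reproductively isolated clusters appear as contiguous diagonal blocks;
  no labels are used to find them.
* **Codon-aware variant classification** — polymorphic columns classified
  as synonymous / nonsynonymous against the majority consensus under the
  vertebrate mitochondrial genetic code (NCBI table 2: AGA/AGG stop,
  ATA Met, TGA Trp); per-gene SNP evenness (χ² goodness of fit against
  gene length); sliding-window APD profiles; and the barcode-window
  percentile among all 648-bp windows of the codome.
* **Diversity vs census** — per-species APD against census population
  size, Spearman rank correlation on log10 census, and a
  subspecies-structure flag from deep UPGMA splits (between/within mean
  distance ratio ≥ 3).
* **A structured-population simulator** — star-phylogeny mitogenome sets
  with K clusters, transition bias, purifying selection as a
  nonsynonymous-acceptance probability, and exact realized-rate
  bookkeeping, so every stage is testable without downloading data.
  Presets: `human-like` (one population, APD ≈ 0.1%), `chimp-like`
  (three subspecies-like clusters, within ≈ 0.4%, between ≈ 2.4%),
  `bird-grid` (a census sweep).

Inputs are pre-aligned FASTA (gap `-`), TSV gene/group/census tables, and
YAML run configs. Real mitogenome alignments (e.g. PhyloTree-derived human
sets or GenBank ape mitogenomes) can be dropped in through the same file
interfaces; no network retrieval is included.

## Worked example

Simulate a chimpanzee-like species (three reproductively isolated
clusters), then measure diversity and draw the Klee diagram of its barcode
region:

```
$ barcodevar simulate --preset chimp-like --n 60 --seed 7 --out-prefix demo
n=60 expected within-cluster APD 0.3908%

$ barcodevar apd --fasta demo.fasta --groups demo.groups.tsv --out apd.tsv
$ cat apd.tsv
group    n   APD_percent  mean_comparable_sites
cluster1 27  0.39852      11394
cluster2 21  0.384246     11394
cluster3 12  0.373934     11394
```

Measured within-cluster APD (0.37–0.40%) matches the generator's exact
expectation (0.3908% = 2 × realized per-lineage rate × 100). The codome
report:

```
$ barcodevar codome --fasta demo.fasta --genes demo.genes.tsv --out-prefix cod
evenness: chi2=8.436 df=12 p=0.7502
variant_codon_fraction: 0.36019
barcode_apd_percent: 1.93023
codome_apd_percent: 1.78764
barcode_codome_ratio: 1.07977
barcode_percentile: 61.7647
```

SNPs are spread evenly across the 13 genes (χ² p = 0.75), and the barcode
window is unremarkable among 648-bp windows (62nd percentile, ratio ≈ 1.1)
— the barcode is representative of the whole codome. Pooled APD (1.79%)
far exceeds within-cluster APD because cross-cluster pairs differ by
~2.4%: exactly the "high diversity from isolated subgroups" signature, and
`barcodevar klee ... --region barcode` renders it as three contiguous
diagonal blocks (plus `klee_barcode.matrix.tsv`, `.order.txt`,
`.tree.nwk` for exact downstream use).

The full pipeline (`barcodevar run --config run.yaml`) chains extraction →
diversity → Klee per region (barcode, 5'/3' halves, whole) → codon
analysis → census comparison, writing everything under one directory with
a SHA-256 MANIFEST; same config + seed reproduces byte-identical tables.

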