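# Methods

## Statistical model and procedure

### Average pairwise difference (APD / π)

The central statistic is the average pairwise difference: the mean
uncorrected p-distance over all unordered pairs of sequences in a group,
expressed as a percent. For sequences *i*, *j* the p-distance is

    d_ij = (# columns where both bases are in {A,C,G,T} and differ)
           / (# columns where both bases are in {A,C,G,T})

and APD = 100 × mean over pairs of d_ij. This equals the nucleotide
diversity π computed with pairwise deletion. No multiple-hit correction
(Jukes–Cantor, K2P) is applied: at the sub-1% within-species divergences
this package targets, the correction is smaller than sampling noise, and
the raw proportion is what barcode surveys report.

**Missing-data policy.** Gaps (`-`), `N`, and all IUPAC ambiguity letters
are treated as missing and excluded pair-by-pair (pairwise deletion, not
complete deletion). Each pair's comparable-site count is carried through to
the output tables so the effect of the policy is auditable. Ambiguity codes
are never treated as partial matches. A pair with zero comparable sites is
an error, not a silent zero.

**Computation.** The contract is the full O(n²) pair enumeration. When a
group contains no missing data, every pair is compared over all L columns
and the mean of per-pair ratios collapses algebraically to
(total mismatches) / (pairs × L); total mismatches are then obtained from
per-column base counts in O(nL). With missing data the per-pair mismatch
and comparable counts are computed by four indicator matrix products. Both
routes return values identical to a literal double loop (asserted to
1e-12 in the test suite).

### Klee diagrams

Each sequence is encoded as a 4L-dimensional binary indicator vector (one
length-4 sub-vector per column, 1 at the observed base in A,C,G,T order;
all-zero for missing). Similarity between sequences is the Pearson
correlation of their indicator vectors. Missing columns are encoded as
zeros and not renormalised — a deliberate, documented convention; its main
consequence is a slight downward pull on correlations involving
high-missingness sequences. A sequence with no callable base has zero
variance and is rejected.

The display order is computed without any labels: UPGMA (average-linkage
agglomeration) of the p-distance matrix, with deterministic tie-breaking —
among minimum-distance pairs the lexicographically smallest (row, column)
pair of the working matrix is merged, and at each internal node the child
subtree containing the smallest original index is placed first. UPGMA is
used rather than neighbour joining because it yields a rooted ultrametric
tree with a natural left-to-right leaf order. Outputs are byte-for-byte
reproducible. Merge heights agree with SciPy's average-linkage to 1e-12
(cross-checked in tests); the ordering conventions are this package's own.

For sequence sets without missing data, indicator correlation is a strictly
decreasing function of p-distance, so contiguous high-correlation blocks on
the diagonal are exactly low-APD clusters.

### Codon-aware variant classification

Variant sites are alignment columns carrying ≥ 2 distinct bases among
A,C,G,T, each in at least `min_count` sequences (default 1: presence, not
frequency, defines a variant; configurable). The reference for
classification is the majority-consensus base per column, ties broken
alphabetically. Each minor allele is substituted into the consensus codon
and translated under the vertebrate mitochondrial genetic code (NCBI
translation table 2, via Biopython): AGA/AGG are stops, ATA is Met, TGA is
Trp. A change that leaves the translation unchanged — including stop→stop —
is synonymous; stop gain/loss is nonsynonymous. Sites whose minor alleles
disagree are labelled `mixed`; untranslatable consensus codons give
`unknown`. When two columns of the same codon vary in different sequences,
each column is classified independently against the consensus codon (a
documented simplification; at within-species densities double-variant
codons are rare). Minus-strand genes are classified in coding orientation.

### Evenness and barcode representativeness

Per-gene SNP evenness is a Pearson goodness-of-fit test of genic variant
counts against a gene-length-proportional expectation; genes with expected
count < 5 are pooled into one class before the test (degrees of freedom =
classes − 1). The statistic matches a hand-computed Pearson χ² to 1e-9.
The χ² reference conditions on the observed total, which makes the test
mildly conservative at small totals (observed type-I rate ≈ 4.3% at the
default simulation scale, inside the nominal 5% ± 2% band).

Representativeness of the barcode asks whether a 648-bp window behaves like
any other same-length window of the codome. Windows are tiled
non-overlapping (step = window by default), *anchored at the barcode
start*, so the barcode is exactly one of the compared windows rather than
straddling two tiles; its percentile among the window APDs is the mid-rank
(Hazen-type) value 100·(#below + ½·#ties)/W. With the 11.4-kb codome and
648-bp windows, W = 17 and every rank maps strictly inside (2.9, 97.1), so
a two-sided 95% call never fires under the null purely from rank
granularity — the property the null-calibration acceptance check requires.
The price is that the degenerate extremes report ≈ 97.1 / ≈ 2.9 rather
than exactly 100 / 0. The report also includes the ratio of barcode APD to
whole-codome APD (≈ 1 under uniform mutation).

### Census comparison and structure flag

Species records (n, APD, census) are rank-correlated: Spearman ρ of APD
against log10 census, ties mid-ranked (SciPy). Spearman is this package's
convention — the underlying claim is about the *absence* of a monotone
relation, and ρ is invariant to the log transform (tested).

The subspecies-structure flag is a heuristic for "distinct reproductively
isolated clusters": from the UPGMA tree, every internal node whose two
blocks each contain at least max(2, ⌈5% n⌉) sequences is scored by
(mean between-block p-distance) / (pooled mean within-block p-distance),
and the statistic is the maximum over qualifying nodes; a species is
flagged at ratio ≥ 3 (configurable). Evaluating nested nodes — not only
the root split — matters: with three clusters the two closest merge first
and the informative split sits one level below the root, where a root-only
ratio is diluted to ~2.4 and misses. The block-size floor excludes tiny
twin-sequence subtrees whose ratios are sampling noise; homogeneous
single-population sets produce caterpillar-like UPGMA trees where few nodes
qualify and qualifying ratios sit near 1, keeping the false-positive rate
at ~0 (≤ 5% required). Undefined ratios (all within-block distances zero,
or no qualifying node) never flag.

## Synthetic-data generator

The generator emulates the regimes the analysis must distinguish, on a
concatenated coding-mitogenome ("codome") layout.

**Genome model.** Default: the 13 human mitochondrial protein-coding genes
with codon-rounded CDS lengths (ND1 957 … CYTB 1140; total 11,394 bp),
contiguous, plus strand, frame 0. Each gene starts ATG, ends TAA, and has
no internal stop under table 2. A rescaled variant with the same relative
proportions is available for arbitrary codon-multiple total lengths.

**Evolution model.** Star phylogeny: every sequence receives independent
substitutions from its cluster ancestor; with K > 1 clusters, each cluster
ancestor independently diverges from a common root by the extra rate D.
Substitutions are sampled as at most one event per site per lineage
(candidate rate capped at 0.05), transitions favoured by κ (default 20,
the mammalian mtDNA regime): P(transition | substitution) = κ/(κ+2).
Purifying selection is an acceptance filter: a candidate that changes the
encoded amino acid (against the current codon) is kept with probability
p_ns.

**Rate convention and calibration.** `d` and `D` are *realized* expected
substitutions per site per lineage. The generator computes the exact mean
acceptance probability over all sites of the ancestor (enumerating the
three alternate bases per site with their κ-weights) and inflates the
candidate rate by its inverse, so E[APD] = 2·d·100% holds for any p_ns.
Realized per-lineage rates are reported exactly in the truth table.

**Presets.**

* `human-like`: K = 1, d = 5×10⁻⁴ (target APD 0.1%, the value reported for
  modern humans), p_ns = 0.03 (variation predominantly synonymous).
* `chimp-like`: K = 3 unequal clusters (45/35/20% of n, default n = 133),
  d = 2×10⁻³ (within ≈ 0.4%), D = 10⁻² (between ≈ 2.4%,
  between/within ≈ 6) — the subspecies-structured ape regime.
* `bird-grid`: 12 species, censuses 10⁴–3×10⁸, APD targets 0.05–0.5%
  deliberately uncorrelated with census, for exercising the census
  comparison.

**What the generator does not emulate** — hence what passing tests do not
show about real data: genealogy (a star phylogeny has no shared internal
branches, so allele-frequency spectra and variant sharing are unrealistic;
in particular the fraction of variant codons at large n overshoots real
coalescent data), recombination-free linkage effects beyond the single
locus, indels, heteroplasmy, rate heterogeneity across sites and genes
(real mtDNA has hypervariable positions), sequencing error, and multiple
hits (d ≤ 0.05 enforced). Analyses validated here respond to marginal
pairwise divergence, which the generator does control exactly.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive everywhere in files; converted to
  0-based slices once, at the I/O boundary.
* The default barcode is a convention, not a published coordinate: a
  648-bp codon-aligned window starting 20 codons into the COI CDS (or
  rCRS 5904–6551 when working in whole-genome coordinates).
* Distance-matrix validation: symmetry to 1e-9, zero diagonal to 1e-12;
  UPGMA tie-breaks as described above, applied to exact float equality
  (average-linkage updates are deterministic arithmetic).
* Zero-variance indicator vectors, zero-comparable-site pairs, singleton
  groups, empty censuses and out-of-range windows all raise typed errors
  rather than returning silent defaults; undefined structure ratios are
  NaN and never flag.
* Pipeline runs are deterministic given config + seed: TSV artifacts are
  byte-identical across runs and MANIFEST.tsv lists every output with its
  SHA-256.

## Problem sizes

The test suite and the acceptance script regenerate everything they
measure. Sizes were chosen to make Monte-Carlo standard errors small
relative to the effects under test while keeping a laptop-scale run: the
distance-oracle comparison uses 100 random alignments (n ≤ 20, L ≤ 1000);
diversity recovery uses 50 seeds of n = 500 on a 15-kb codome; cluster
recovery 100 seeds of the chimp-like preset; the representativeness null
200 simulated codomes; the evenness null 1000 replicates; the selection
switch 5 seeds per setting.

## Known limitations

* APD confidence intervals are not computed; pairwise distances within a
  group are heavily correlated, so naive binomial intervals would be wrong
  and a block-resampling scheme is out of scope here.
* The structure flag is a heuristic with a configurable threshold, not a
  test with a calibrated null distribution.
* Klee rendering fixes the colour scale to [−0.2, 1] by default; strongly
  diverged panels may need a wider `vmin`.
* Real mitogenome alignments with many ambiguity codes reduce comparable
  sites per pair; APD remains unbiased under missingness at random, but
  systematic missingness (e.g. degraded ancient-DNA ends) can bias
  windowed profiles.
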