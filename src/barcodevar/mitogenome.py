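"""Mitochondrial genome conventions.

Two coordinate systems appear in practice:

* whole-mitogenome coordinates (e.g. the human rCRS reference, where the COI
  gene spans 5904..7445), used when the input alignment is a full mitogenome;
* "codome" coordinates — an alignment built by concatenating the 13
  protein-coding CDSs in genome order, which is how mitogenome coding
  alignments are typically exported and how the synthetic generator lays out
  its genomes.

The standard animal barcode is a 648-bp segment of COI. Published coordinates
for the segment vary by a few bases between primer sets; this package's
convention, used wherever a barcode region is derived from an annotation
rather than supplied explicitly, is a 648-bp codon-aligned window inside COI
starting 60 bp downstream of the CDS start (:func:`default_barcode`). The
rCRS-coordinate default is shipped in :data:`RCRS_REGIONS` and is
configurable.
"""

from __future__ import annotations

from .errors import AnnotationError
from .seqio import Gene, GeneTable, RegionSpec

#: Standard barcode width in bp.
BARCODE_LENGTH = 648

#: Gene names accepted as "the COI gene".
COI_ALIASES = ("COI", "COX1", "CO1", "COXI")

#: Human rCRS protein-coding CDS lengths, rounded down to whole codons.
#: Genome order; total 11,394 bp (17 full 648-bp windows).
HUMAN_CODOME_GENES: tuple[tuple[str, int], ...] = (
    ("ND1", 957),
    ("ND2", 1044),
    ("COI", 1542),
    ("COII", 684),
    ("ATP8", 207),
    ("ATP6", 681),
    ("COIII", 783),
    ("ND3", 345),
    ("ND4L", 297),
    ("ND4", 1377),
    ("ND5", 1812),
    ("ND6", 525),
    ("CYTB", 1140),
)

#: rCRS whole-genome convention: COI CDS and the default barcode window
#: (first 648 bp of the CDS; a convention of this package, not a published
#: coordinate).
RCRS_REGIONS: dict[str, RegionSpec] = {
    "COI": RegionSpec("COI", 5904, 7445, "+", 0),
    "COI-barcode": RegionSpec("COI-barcode", 5904, 6551, "+", 0),
}


def concatenated_gene_table(
    lengths: tuple[tuple[str, int], ...] = HUMAN_CODOME_GENES,
) -> GeneTable:
    """Gene table for a codome-style alignment: genes contiguous from column 1,
    plus strand, frame 0."""
    genes = []
    pos = 1
    for name, ln in lengths:
        if ln % 3 != 0:
            raise AnnotationError(f"gene {name!r}: length {ln} not a codon multiple")
        genes.append(Gene(name=name, region=RegionSpec(name, pos, pos + ln - 1)))
        pos += ln
    return GeneTable(genes=genes)


def scaled_gene_table(total_length: int) -> GeneTable:
    """Human-proportioned codome gene table rescaled to ``total_length`` bp.

    Gene lengths keep the human relative proportions, rounded to whole
    codons; the last gene absorbs the rounding remainder. ``total_length``
    must be a multiple of 3.
    """
    if total_length % 3 != 0 or total_length <= 0:
        raise AnnotationError("total_length must be a positive codon multiple")
    base_total = sum(ln for _, ln in HUMAN_CODOME_GENES)
    lengths = []
    for name, ln in HUMAN_CODOME_GENES[:-1]:
        scaled = max(3, 3 * round(ln * total_length / base_total / 3))
        lengths.append((name, scaled))
    used = sum(ln for _, ln in lengths)
    last_name = HUMAN_CODOME_GENES[-1][0]
    last = total_length - used
    if last < 9:
        raise AnnotationError("total_length too small for 13-gene model")
    lengths.append((last_name, last))
    return concatenated_gene_table(tuple(lengths))


def find_coi(genes: GeneTable) -> Gene:
    for g in genes:
        if g.name.upper() in COI_ALIASES:
            return g
    raise AnnotationError(f"no COI gene found among {[g.name for g in genes]!r}")


def default_barcode(genes: GeneTable, offset_codons: int = 20) -> RegionSpec:
    """Barcode region derived from a gene table: a 648-bp codon-aligned window
    starting ``offset_codons`` codons into the COI CDS.

    The offset keeps the window inside the CDS the way PCR barcodes sit inside
    COI rather than at its very start; 20 codons (60 bp) is this package's
    documented convention.
    """
    g = find_coi(genes)
    start = g.region.start + g.region.frame_offset + 3 * offset_codons
    end = start + BARCODE_LENGTH - 1
    if end > g.region.end:
        raise AnnotationError(
            f"COI gene ({g.region.width} bp) too short for a {BARCODE_LENGTH}-bp "
            f"barcode at codon offset {offset_codons}"
        )
    return RegionSpec("COI-barcode", start, end, g.region.strand, 0)


def half_regions(length: int) -> dict[str, RegionSpec]:
    """5' and 3' halves of an alignment, split at a codon boundary."""
    mid = 3 * (length // 6)
    return {
        "5prime-half": RegionSpec("5prime-half", 1, mid),
        "3prime-half": RegionSpec("3prime-half", mid + 1, length),
    }
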