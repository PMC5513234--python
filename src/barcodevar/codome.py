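"""Codon-aware characterisation of variation in the coding mitogenome.

Variant sites are polymorphic alignment columns (>= 2 distinct bases among
A,C,G,T). Each minor allele is classified as synonymous or nonsynonymous by
substituting it into the majority-consensus codon and translating under the
vertebrate mitochondrial genetic code (NCBI translation table 2, which
differs from the standard code at AGA/AGG -> stop, ATA -> Met, TGA -> Trp).
Stop gain/loss counts as nonsynonymous; a change between stop codons leaves
the translation unchanged and is synonymous.

The module also profiles diversity in barcode-length windows and tests
whether the barcode window is representative of the whole codome: SNP counts
per gene against a length-proportional expectation (Pearson goodness of
fit), and the barcode window's percentile among all same-length windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .diversity import apd
from .errors import AnnotationError, InsufficientDataError, ParameterError
from .seqio import AlignedSeqSet, Gene, GeneTable, RegionSpec

_TABLE2 = CodonTable.unambiguous_dna_by_id[2]

#: codon -> one-letter amino acid, with "*" for stops, under table 2.
CODON_TO_AA: dict[str, str] = dict(_TABLE2.forward_table)
for _stop in _TABLE2.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: Marker returned for a codon that cannot be translated (gap/N/ambiguity).
UNTRANSLATABLE = "?"

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
MIXED = "mixed"
NONCODING = "noncoding"
UNKNOWN = "unknown"


def translate_codon(codon: str) -> str:
    """Amino acid (one letter, ``*`` for stop) under the vertebrate
    mitochondrial code; ``?`` if the codon is not a clean ACGT 3-mer."""
    if len(codon) != 3:
        raise ParameterError(f"codon must be a 3-mer, got {codon!r}")
    return CODON_TO_AA.get(codon.upper(), UNTRANSLATABLE)


def classify_variant(ref_codon: str, codon_pos: int, alt_base: str) -> str:
    """Classify one substitution against a reference codon.

    ``codon_pos`` is 1/2/3. Returns ``synonymous`` / ``nonsynonymous`` /
    ``unknown`` (untranslatable reference or alternate codon).
    """
    if codon_pos not in (1, 2, 3):
        raise ParameterError(f"codon_pos must be 1/2/3, got {codon_pos}")
    ref_aa = translate_codon(ref_codon)
    alt_codon = (
        ref_codon[: codon_pos - 1] + alt_base.upper() + ref_codon[codon_pos:]
    )
    alt_aa = translate_codon(alt_codon)
    if UNTRANSLATABLE in (ref_aa, alt_aa):
        return UNKNOWN
    return SYNONYMOUS if ref_aa == alt_aa else NONSYNONYMOUS


@dataclass
class VariantSite:
    """One polymorphic alignment column."""

    column: int  # 1-based alignment column
    gene: str | None
    codon_index: int | None  # 1-based codon within the gene, coding orientation
    codon_pos: int | None  # 1/2/3
    alleles: dict[str, int]  # base -> carrier count (A,C,G,T only)
    classification: str  # synonymous | nonsynonymous | mixed | noncoding | unknown


@dataclass
class ColumnAnnotation:
    """Where an alignment column falls in the coding frame (internal)."""

    gene: Gene
    codon_index: int
    codon_pos: int
    codon_columns: tuple[int, int, int]  # 1-based alignment columns, coding order


def _annotate_columns(genes: GeneTable) -> dict[int, ColumnAnnotation]:
    """Map 1-based alignment column -> coding-frame annotation."""
    ann: dict[int, ColumnAnnotation] = {}
    for g in genes:
        r = g.region
        if r.strand == "+":
            coding_cols = list(range(r.start + r.frame_offset, r.end + 1))
        else:
            coding_cols = list(range(r.end - r.frame_offset, r.start - 1, -1))
        n_codons = len(coding_cols) // 3  # trailing partial codon dropped
        for ci in range(n_codons):
            triplet = tuple(coding_cols[3 * ci : 3 * ci + 3])
            for pos, col in enumerate(triplet, start=1):
                ann[col] = ColumnAnnotation(
                    gene=g, codon_index=ci + 1, codon_pos=pos, codon_columns=triplet
                )
    return ann


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def consensus_sequence(s: AlignedSeqSet) -> str:
    """Majority base per column among A,C,G,T; ties broken alphabetically;
    columns with no callable base become ``N``."""
    codes = s.codes()
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])
    best = np.argmax(counts, axis=0)  # first max => alphabetical tie-break
    cons = np.array(list("ACGT"))[best]
    cons[counts.sum(axis=0) == 0] = "N"
    return "".join(cons)


def call_variant_sites(
    s: AlignedSeqSet, genes: GeneTable | None = None, min_count: int = 1
) -> list[VariantSite]:
    """One :class:`VariantSite` per polymorphic column.

    A column is a variant site when >= 2 distinct bases among A,C,G,T each
    occur in >= ``min_count`` sequences (ambiguity codes never count). Each
    minor allele is classified against the consensus codon; a site whose
    minor alleles disagree is labelled ``mixed``.
    """
    codes = s.codes()
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])
    qualifying = (counts >= min_count).sum(axis=0)
    poly_cols = np.nonzero(qualifying >= 2)[0]
    ann = _annotate_columns(genes) if genes is not None else {}
    cons = consensus_sequence(s)
    sites: list[VariantSite] = []
    for c0 in poly_cols:
        col = int(c0) + 1
        col_counts = {
            "ACGT"[b]: int(counts[b, c0])
            for b in range(4)
            if counts[b, c0] > 0
        }
        a = ann.get(col)
        if a is None:
            sites.append(
                VariantSite(col, None, None, None, col_counts, NONCODING)
            )
            continue
        cons_base = cons[c0]
        minors = [
            b
            for b, cnt in sorted(col_counts.items())
            if b != cons_base and cnt >= min_count
        ]
        ref_codon = "".join(cons[cc - 1] for cc in a.codon_columns)
        pos = a.codon_pos
        if a.gene.region.strand == "-":
            ref_codon = "".join(_COMP.get(ch, "N") for ch in ref_codon)
            minors = [_COMP.get(b, "N") for b in minors]
        classes = {classify_variant(ref_codon, pos, b) for b in minors}
        if classes == {SYNONYMOUS}:
            cls = SYNONYMOUS
        elif classes == {NONSYNONYMOUS}:
            cls = NONSYNONYMOUS
        elif UNKNOWN in classes:
            cls = UNKNOWN
        else:
            cls = MIXED
        sites.append(
            VariantSite(col, a.gene.name, a.codon_index, pos, col_counts, cls)
        )
    return sites


def evenness_test(
    sites: list[VariantSite], genes: GeneTable
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of per-gene SNP counts against gene lengths.

    Expected count per gene is total genic sites × gene length / total
    length. Genes with expected count < 5 are pooled into one class before
    the test. Returns ``(chi2, df, p)``.
    """
    if len(genes) < 2:
        raise InsufficientDataError("evenness test needs >= 2 genes")
    obs_by_gene = {g.name: 0 for g in genes}
    for v in sites:
        if v.gene is not None:
            obs_by_gene[v.gene] += 1
    total = sum(obs_by_gene.values())
    if total == 0:
        raise InsufficientDataError("no genic variant sites")
    total_len = sum(g.region.width for g in genes)
    obs, exp = [], []
    pooled_obs = pooled_exp = 0.0
    for g in genes:
        e = total * g.region.width / total_len
        if e < 5:
            pooled_obs += obs_by_gene[g.name]
            pooled_exp += e
        else:
            obs.append(float(obs_by_gene[g.name]))
            exp.append(e)
    if pooled_exp > 0:
        obs.append(pooled_obs)
        exp.append(pooled_exp)
    if len(obs) < 2:
        raise InsufficientDataError("fewer than 2 classes after pooling")
    chi2, p = stats.chisquare(f_obs=obs, f_exp=exp)
    return float(chi2), len(obs) - 1, float(p)


@dataclass
class WindowProfile:
    """APD computed in fixed-width windows along the alignment."""

    starts: list[int]  # 1-based window start columns
    window: int
    step: int
    apd_percent: list[float]


def window_profile(
    s: AlignedSeqSet,
    window: int = 648,
    step: int | None = None,
    offset: int = 0,
) -> WindowProfile:
    """APD per window. Non-overlapping by default (step = window).

    ``offset`` shifts the tiling start (0-based columns skipped before the
    first window); only full-width windows are profiled.
    """
    if window > s.length:
        raise ParameterError(
            f"window {window} exceeds alignment length {s.length}"
        )
    if step is None:
        step = window
    if step < 1 or not 0 <= offset < window:
        raise ParameterError("need step >= 1 and 0 <= offset < window")
    codes = s.codes()
    starts, values = [], []
    from .diversity import _apd_codes

    pos = offset
    while pos + window <= s.length:
        starts.append(pos + 1)
        values.append(_apd_codes(codes[:, pos : pos + window])[0])
        pos += step
    return WindowProfile(starts=starts, window=window, step=step, apd_percent=values)


@dataclass
class RepresentativenessReport:
    """How typical the barcode window is of the whole codome."""

    barcode_apd: float
    codome_apd: float
    ratio: float  # barcode APD / codome APD
    percentile: float  # mid-rank percentile of barcode among windows
    profile: WindowProfile


def representativeness(
    s: AlignedSeqSet,
    barcode: RegionSpec,
    window: int = 648,
    step: int | None = None,
) -> RepresentativenessReport:
    """Barcode-window APD percentile among all same-length windows.

    Windows are tiled anchored at the barcode start, so the barcode is
    exactly one of the compared windows rather than straddling two; its
    percentile is the mid-rank (Hazen-type) percentile
    ``100 * (#below + 0.5 * #ties) / #windows``, which for a tiling of at
    most 20 windows is strictly inside (2.5, 97.5) at every rank — the
    appropriate null behaviour for a two-sided 95% representativeness call.
    Also reports the ratio of barcode APD to whole-alignment APD.
    """
    if barcode.width != window:
        raise ParameterError(
            f"barcode width {barcode.width} != window {window}"
        )
    if barcode.end > s.length:
        raise ParameterError("barcode region outside alignment")
    offset = (barcode.start - 1) % window
    profile = window_profile(s, window=window, step=step, offset=offset)
    from .seqio import extract_region

    barcode_apd = apd(extract_region(s, barcode))
    codome_apd = apd(s)
    w = np.asarray(profile.apd_percent)
    below = int((w < barcode_apd).sum())
    ties = int((w == barcode_apd).sum())
    percentile = 100.0 * (below + 0.5 * ties) / w.size
    ratio = barcode_apd / codome_apd if codome_apd > 0 else float("nan")
    return RepresentativenessReport(
        barcode_apd=barcode_apd,
        codome_apd=codome_apd,
        ratio=ratio,
        percentile=percentile,
        profile=profile,
    )


def variant_codon_fraction(sites: list[VariantSite], genes: GeneTable) -> float:
    """Fraction of codons (across all genes) containing >= 1 variant site."""
    total_codons = sum(g.coding_length // 3 for g in genes)
    if total_codons == 0:
        raise InsufficientDataError("gene table has no complete codons")
    hit = {
        (v.gene, v.codon_index)
        for v in sites
        if v.gene is not None and v.codon_index is not None
    }
    return len(hit) / total_codons


def classification_counts(sites: list[VariantSite]) -> dict[str, int]:
    """Tally of site classifications (genic classes plus noncoding)."""
    out: dict[str, int] = {}
    for v in sites:
        out[v.classification] = out.get(v.classification, 0) + 1
    return out
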