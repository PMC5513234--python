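"""Sequence, region and table I/O.

The central container is :class:`AlignedSeqSet`, a fixed-width nucleotide
alignment with unique names and optional group (species/population) labels.
Coordinates throughout the package are 1-based inclusive, the GenBank
convention used by mitochondrial annotations; they are converted to 0-based
slices exactly once, inside this module.

Missing-data policy: ``-`` is the only gap character (``.`` on input is
converted), ``U`` is mapped to ``T``, and IUPAC ambiguity codes are retained
at parse time — downstream statistics treat anything outside {A,C,G,T} as
missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentError,
    AlphabetError,
    AnnotationError,
    FormatError,
    RegionBoundsError,
    ReferenceMappingError,
)

#: Allowed characters after input normalisation.
ALPHABET = frozenset("ACGTN-RYSWKMBDHV")

#: Strict bases; everything else is treated as missing downstream.
BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV-", "TGCANYRSWMKVHDB-")

# Integer codes for vectorised work: A=0 C=1 G=2 T=3, missing = -1.
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware; gaps stay gaps."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(raw: str, name: str) -> str:
    s = raw.upper().replace("U", "T").replace(".", "-")
    bad = set(s) - ALPHABET
    if bad:
        raise AlphabetError(
            f"sequence {name!r} contains illegal characters: {sorted(bad)!r}"
        )
    return s


@dataclass(eq=False)
class AlignedSeqSet:
    """A fixed-width alignment of named, group-labelled sequences.

    Parameters
    ----------
    names
        Unique sequence identifiers, one per row.
    seqs
        Equal-length uppercase strings over ``ACGTN-`` plus IUPAC ambiguity
        letters.
    groups
        Optional map name -> group label (species or population). May cover
        any subset of names; use :func:`attach_groups` to enforce a complete
        mapping read from a file.
    """

    names: list[str]
    seqs: list[str]
    groups: dict[str, str] = field(default_factory=dict)
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.seqs):
            raise AlignmentError("names and seqs differ in length")
        if not self.seqs:
            raise AlignmentError("empty sequence set")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise AlignmentError(f"duplicate sequence names: {dupes!r}")
        width = len(self.seqs[0])
        if width == 0:
            raise AlignmentError("zero-length alignment")
        for name, s in zip(self.names, self.seqs):
            if len(s) != width:
                raise AlignmentError(
                    f"ragged alignment: record {name!r} has length {len(s)}, "
                    f"expected {width}"
                )
            bad = set(s) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"sequence {name!r} contains illegal characters: {sorted(bad)!r}"
                )
        unknown = set(self.groups) - set(self.names)
        if unknown:
            raise ReferenceMappingError(
                f"group labels refer to unknown sequences: {sorted(unknown)!r}"
            )

    def __len__(self) -> int:
        return len(self.names)

    @property
    def length(self) -> int:
        """Alignment width in columns."""
        return len(self.seqs[0])

    def codes(self) -> np.ndarray:
        """Integer-coded matrix (n, L): A=0 C=1 G=2 T=3, missing=-1. Cached."""
        if self._codes is None:
            buf = np.frombuffer(
                "".join(self.seqs).encode("ascii"), dtype=np.uint8
            ).reshape(len(self.seqs), self.length)
            self._codes = _CODE_LUT[buf]
        return self._codes

    def group_of(self, name: str) -> str | None:
        return self.groups.get(name)

    def group_members(self, label: str) -> list[int]:
        """Row indices of the sequences carrying ``label``."""
        return [i for i, n in enumerate(self.names) if self.groups.get(n) == label]

    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for n in self.names:
            g = self.groups.get(n)
            if g is not None:
                seen.setdefault(g, None)
        return list(seen)

    def subset(self, indices: Sequence[int]) -> "AlignedSeqSet":
        names = [self.names[i] for i in indices]
        return AlignedSeqSet(
            names=names,
            seqs=[self.seqs[i] for i in indices],
            groups={n: self.groups[n] for n in names if n in self.groups},
        )


@dataclass(frozen=True)
class RegionSpec:
    """A named interval on the alignment, 1-based inclusive.

    ``frame_offset`` is the codon phase at ``start`` (0 means ``start`` is the
    first position of a codon, on the coding strand).
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise RegionBoundsError(
                f"region {self.name!r}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise RegionBoundsError(f"region {self.name!r}: bad strand {self.strand!r}")
        if self.frame_offset not in (0, 1, 2):
            raise RegionBoundsError(
                f"region {self.name!r}: frame_offset must be 0/1/2"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Gene:
    name: str
    region: RegionSpec
    incomplete_stop: bool = False

    @property
    def coding_length(self) -> int:
        """Length of the in-frame coding part (frame offset removed)."""
        return self.region.width - self.region.frame_offset


@dataclass
class GeneTable:
    """Protein-coding gene annotations on alignment coordinates.

    Regions must be non-overlapping; each gene's in-frame length must be a
    multiple of 3 unless flagged ``incomplete_stop`` (GenBank-style truncated
    terminal codon completed by polyadenylation).
    """

    genes: list[Gene]

    def __post_init__(self) -> None:
        ivs = sorted((g.region.start, g.region.end, g.name) for g in self.genes)
        for (s1, e1, n1), (s2, e2, n2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise AnnotationError(f"genes {n1!r} and {n2!r} overlap")
        for g in self.genes:
            if g.coding_length % 3 != 0 and not g.incomplete_stop:
                raise AnnotationError(
                    f"gene {g.name!r} length {g.coding_length} not divisible by 3 "
                    "and not flagged incomplete-stop"
                )

    def __iter__(self) -> Iterable[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, name: str) -> Gene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def total_length(self) -> int:
        return sum(g.region.width for g in self.genes)

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(g.region.start for g in self.genes),
            max(g.region.end for g in self.genes),
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> AlignedSeqSet:
    """Read an aligned FASTA file.

    Sequences are uppercased, ``U`` -> ``T``, ``.`` -> ``-``. Unequal record
    lengths raise :class:`AlignmentError` naming the offending record; an
    empty file raises :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    names: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(_normalize(str(rec.seq), rec.id))
    if not names:
        raise FormatError(f"{path}: no FASTA records found")
    return AlignedSeqSet(names=names, seqs=seqs)


def write_fasta(s: AlignedSeqSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(s.names, s.seqs):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

def extract_region(s: AlignedSeqSet, r: RegionSpec) -> AlignedSeqSet:
    """Cut a coordinate-defined region out of every sequence.

    Minus-strand regions are reverse-complemented so the result reads in
    coding orientation. Group labels are preserved.
    """
    if r.end > s.length:
        raise RegionBoundsError(
            f"region {r.name!r} ({r.start}..{r.end}) exceeds alignment "
            f"length {s.length}"
        )
    lo, hi = r.start - 1, r.end
    if r.strand == "+":
        cut = [seq[lo:hi] for seq in s.seqs]
    else:
        cut = [reverse_complement(seq[lo:hi]) for seq in s.seqs]
    return AlignedSeqSet(names=list(s.names), seqs=cut, groups=dict(s.groups))


# ---------------------------------------------------------------------------
# Tables (TSV with header)
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = ["gene", "start", "end", "strand", "frame"]


def read_gene_table(path: str | Path) -> GeneTable:
    """Read a gene annotation TSV: gene, start, end, strand, frame[, flags]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene table {path}: missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        flags = getattr(row, "flags", "") or ""
        genes.append(
            Gene(
                name=row.gene,
                region=RegionSpec(
                    name=row.gene,
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    frame_offset=int(row.frame),
                ),
                incomplete_stop="incomplete-stop" in str(flags),
            )
        )
    return GeneTable(genes=genes)


def write_gene_table(t: GeneTable, path: str | Path) -> None:
    rows = [
        {
            "gene": g.name,
            "start": g.region.start,
            "end": g.region.end,
            "strand": g.region.strand,
            "frame": g.region.frame_offset,
            "flags": "incomplete-stop" if g.incomplete_stop else "",
        }
        for g in t.genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_group_table(path: str | Path) -> dict[str, str]:
    """Read a name -> group label TSV (columns: name, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("name", "group"):
        if col not in df.columns:
            raise FormatError(f"group table {path}: missing column {col!r}")
    return dict(zip(df["name"], df["group"]))


def write_group_table(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"name": list(groups), "group": [groups[k] for k in groups]}
    ).to_csv(path, sep="\t", index=False)


def attach_groups(s: AlignedSeqSet, groups: Mapping[str, str]) -> AlignedSeqSet:
    """Attach a *complete* group mapping to a sequence set.

    Every sequence must be labelled and every label must refer to an existing
    sequence; any mismatch raises :class:`ReferenceMappingError`.
    """
    have, want = set(groups), set(s.names)
    if have - want:
        raise ReferenceMappingError(
            f"group table names not in alignment: {sorted(have - want)!r}"
        )
    if want - have:
        raise ReferenceMappingError(
            f"sequences missing from group table: {sorted(want - have)!r}"
        )
    return AlignedSeqSet(names=list(s.names), seqs=list(s.seqs), groups=dict(groups))


def read_census_table(path: str | Path) -> dict[str, float]:
    """Read species -> census population size (columns: species, census)."""
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    for col in ("species", "census"):
        if col not in df.columns:
            raise FormatError(f"census table {path}: missing column {col!r}")
    return dict(zip(df["species"], df["census"].astype(float)))


def write_matrix(
    matrix: np.ndarray, labels: Sequence[str], path: str | Path
) -> None:
    """Write a labelled square matrix as TSV (labels in first row/column)."""
    pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_tsv(rows: Iterable[Mapping], path: str | Path) -> None:
    pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False)
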