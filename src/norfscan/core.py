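"""Domain types and interval arithmetic shared by every pipeline stage.

Coordinates are 0-based half-open internally. GTF I/O converts from the
1-based inclusive convention at the boundary; BED I/O is pass-through.
Chromosome names are normalized to carry a ``chr`` prefix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

#: closed vocabulary of upstream ORF category labels
NORF_CATEGORIES = frozenset(
    {
        "canonical",
        "truncated",
        "extended",
        "uORF",
        "overlapping_uORF",
        "internal",
        "external",
        "polycistronic",
        "readthrough",
        "non_coding_transcript",
    }
)

FRAME_CLASSES = ("in_frame_cds", "alt_frame_cds", "non_cds", "intergenic")


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome name: add the ``chr`` prefix if missing."""
    if not chrom:
        raise ValueError("chromosome name must be non-empty")
    return chrom if chrom.startswith("chr") else "chr" + chrom


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base (half-open)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bases between two intervals; 0 if they overlap or abut.

    Different chromosomes have infinite distance.
    """
    if a.chrom != b.chrom:
        return math.inf
    return max(0, max(a.start, b.start) - min(a.end, b.end))


@dataclass(frozen=True)
class MergedInterval:
    """A merged interval together with the records that contributed to it."""

    interval: GenomicInterval
    members: tuple = ()


def merge_intervals(
    intervals: Sequence[GenomicInterval],
    provenance: Optional[Sequence] = None,
) -> list[MergedInterval]:
    """Merge overlapping and bookended intervals, keeping member provenance.

    Strand is ignored. Output is sorted, pairwise disjoint and non-abutting;
    each merged interval carries the provenance records (or the input
    intervals themselves when ``provenance`` is None) of every contributing
    interval.
    """
    if provenance is None:
        provenance = list(intervals)
    if len(provenance) != len(intervals):
        raise ValueError("provenance length must match intervals")
    order = sorted(
        range(len(intervals)),
        key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end),
    )
    merged: list[MergedInterval] = []
    cur = None  # (chrom, start, end, [members])
    for i in order:
        iv = intervals[i]
        if cur is not None and iv.chrom == cur[0] and iv.start <= cur[2]:
            cur[3].append(provenance[i])
            cur[2] = max(cur[2], iv.end)
        else:
            if cur is not None:
                merged.append(
                    MergedInterval(GenomicInterval(cur[0], cur[1], cur[2]), tuple(cur[3]))
                )
            cur = [iv.chrom, iv.start, iv.end, [provenance[i]]]
    if cur is not None:
        merged.append(
            MergedInterval(GenomicInterval(cur[0], cur[1], cur[2]), tuple(cur[3]))
        )
    return merged


def _validate_chain(exons: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    exons = tuple((int(s), int(e)) for s, e in exons)
    if not exons:
        raise ValueError("exon chain must be non-empty")
    for s, e in exons:
        if not (0 <= s < e):
            raise ValueError(f"bad exon [{s}, {e})")
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 < e1:
            raise ValueError("exons must be sorted and pairwise disjoint")
    return exons


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded exon chain with a biotype and an optional CDS sub-chain."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple  # ((start, end), ...) sorted, disjoint
    biotype: str = ""
    cds: Optional[tuple] = None  # ((start, end), ...) contained in exon union

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "exons", _validate_chain(self.exons))
        if self.cds is not None:
            cds = _validate_chain(self.cds)
            for cs, ce in cds:
                if not any(s <= cs and ce <= e for s, e in self.exons):
                    raise ValueError(
                        f"CDS segment [{cs},{ce}) of {self.transcript_id} "
                        "not contained in any exon"
                    )
            object.__setattr__(self, "cds", cds)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0][0], self.exons[-1][1], self.strand
        )

    @property
    def introns(self) -> tuple:
        """Ordered (donor, acceptor) junction pairs between adjacent exons."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class NorfRecord:
    """A novel ORF: exon chain + upstream category + frame classification."""

    norf_id: str
    chrom: str
    strand: str
    exons: tuple
    category: str
    frame_class: Optional[str] = None
    aa_sequence: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "exons", _validate_chain(self.exons))
        if self.category not in NORF_CATEGORIES:
            raise ValueError(f"unknown nORF category {self.category!r}")
        if self.frame_class is not None and self.frame_class not in FRAME_CLASSES:
            raise ValueError(f"unknown frame class {self.frame_class!r}")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0][0], self.exons[-1][1], self.strand
        )

    @property
    def introns(self) -> tuple:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    def chain_key(self) -> tuple:
        """Identity of the genomic structure, used for deduplication."""
        return (self.chrom, self.strand, self.exons)

    def with_frame_class(self, frame_class: str) -> "NorfRecord":
        return replace(self, frame_class=frame_class)


VALID_UNITS = ("count", "TPM", "logCPM")


@dataclass
class ExpressionMatrix:
    """Feature x sample expression values with a unit tag.

    ``values`` is a pandas DataFrame indexed by feature id with sample ids as
    columns. ``lengths`` (feature -> bases) is needed for TPM conversion.
    """

    values: pd.DataFrame
    unit: str
    lengths: Optional[pd.Series] = None

    def __post_init__(self):
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}: {self.unit!r}")
        if self.unit != "logCPM" and (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")
        if self.lengths is not None:
            missing = self.values.index.difference(self.lengths.index)
            if len(missing):
                raise ValueError(f"lengths missing for features: {list(missing)[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


REQUIRED_METADATA_COLUMNS = ("sample_id", "diagnosis", "individual_id", "sex")
DIAGNOSES = ("CNT", "SCZ", "BD")


def validate_metadata(metadata: pd.DataFrame, sample_ids: Iterable[str]) -> pd.DataFrame:
    """Check one metadata row per sample and return the frame indexed by sample."""
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in metadata.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    meta = metadata.set_index("sample_id", drop=False)
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample_id in metadata")
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    bad = set(meta["diagnosis"]) - set(DIAGNOSES)
    if bad:
        raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")
    return meta
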