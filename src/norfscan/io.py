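"""Readers and writers for GTF, BED and the TSV tables used by the pipeline.

GTF is the Ensembl/GENCODE attribute dialect; its 1-based inclusive
coordinates are converted to the internal 0-based half-open convention on
read (and back on write). BED coordinates pass through unchanged. All
writers emit a deterministic column order.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import ExpressionMatrix, GenomicInterval, NorfRecord, TranscriptModel

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    pass


def _parse_attributes(attr_field: str) -> dict:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models.

    exon features are grouped by ``transcript_id`` and sorted; CDS features
    are attached to their transcript. Raises :class:`GtfParseError` with the
    offending line number on malformed input.
    """
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    info: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise GtfParseError(f"line {lineno}: bad coordinate range {start}-{end}")
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            if feature in ("exon", "CDS", "transcript") and not tid:
                raise GtfParseError(f"line {lineno}: missing transcript_id")
            if feature not in ("exon", "CDS", "transcript"):
                continue
            rec = info.setdefault(
                tid,
                {
                    "gene_id": attr.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attr.get("transcript_biotype", attr.get("gene_biotype", "")),
                    "bounds": None,
                },
            )
            if attr.get("transcript_biotype"):
                rec["biotype"] = attr["transcript_biotype"]
            # GTF 1-based inclusive -> 0-based half-open
            iv = (start_i - 1, end_i)
            if feature == "transcript":
                rec["bounds"] = iv
            elif feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:
                cds.setdefault(tid, []).append(iv)

    out = []
    for tid, rec in info.items():
        ex = sorted(exons.get(tid, []))
        if not ex:
            continue
        if rec["bounds"] is not None:
            lo, hi = rec["bounds"]
            if ex[0][0] < lo or ex[-1][1] > hi:
                raise GtfParseError(
                    f"transcript {tid}: exon outside declared transcript bounds"
                )
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(ex),
                biotype=rec["biotype"],
                cds=tuple(sorted(cds[tid])) if tid in cds else None,
            )
        )
    return out


def write_gtf(transcripts: Sequence[TranscriptModel], path) -> None:
    """Write transcript models as GTF (transcript + exon + CDS lines)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{t.biotype}";'
            )
            span = t.span
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        "norfscan",
                        "transcript",
                        str(span.start + 1),
                        str(span.end),
                        ".",
                        t.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for s, e in t.exons:
                fh.write(
                    "\t".join(
                        [t.chrom, "norfscan", "exon", str(s + 1), str(e), ".", t.strand, ".", attrs]
                    )
                    + "\n"
                )
            for s, e in t.cds or ():
                fh.write(
                    "\t".join(
                        [t.chrom, "norfscan", "CDS", str(s + 1), str(e), ".", t.strand, "0", attrs]
                    )
                    + "\n"
                )


def read_bed(path, extra_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Read BED3/BED6(+extra) into a DataFrame with normalized chrom names."""
    base = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    names = base[:ncol] if ncol <= 6 else base + list(extra_columns)[: ncol - 6]
    if len(names) != ncol:
        raise ValueError(f"BED file has {ncol} columns, names cover {len(names)}")
    df.columns = names
    df["chrom"] = df["chrom"].map(lambda c: c if str(c).startswith("chr") else "chr" + str(c))
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def intervals_from_bed(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), getattr(r, "strand", "."))
        for r in df.itertuples(index=False)
    ]


def read_norf_bed12(path) -> list[NorfRecord]:
    """Read nORFs from BED12 with the category label in column 13."""
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
        "blockStarts", "category",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    records = []
    for r in df.itertuples(index=False):
        sizes = [int(x) for x in str(r.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(r.blockStarts).rstrip(",").split(",")]
        if len(sizes) != int(r.blockCount) or len(starts) != int(r.blockCount):
            raise ValueError(f"nORF {r.name}: block count mismatch")
        exons = tuple(
            (int(r.start) + off, int(r.start) + off + size)
            for off, size in zip(starts, sizes)
        )
        records.append(
            NorfRecord(
                norf_id=str(r.name),
                chrom=str(r.chrom),
                strand=str(r.strand),
                exons=exons,
                category=str(r.category),
            )
        )
    return records


def write_norf_bed12(norfs: Iterable[NorfRecord], path) -> None:
    rows = []
    for n in norfs:
        start = n.exons[0][0]
        end = n.exons[-1][1]
        sizes = ",".join(str(e - s) for s, e in n.exons)
        offsets = ",".join(str(s - start) for s, _ in n.exons)
        rows.append(
            [
                n.chrom, start, end, n.norf_id, 0, n.strand, start, end, "0",
                len(n.exons), sizes, offsets, n.category,
            ]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_expression_tsv(path, unit: str, lengths_path=None) -> ExpressionMatrix:
    """Read a feature x sample TSV (first column = feature id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = lt.iloc[:, 0]
    return ExpressionMatrix(values=df, unit=unit, lengths=lengths)


def write_expression_tsv(matrix: ExpressionMatrix, path, float_format: Optional[str] = "%.6g") -> None:
    matrix.values.to_csv(path, sep="\t", float_format=float_format)


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str})


def write_tsv(df: pd.DataFrame, path, float_format: Optional[str] = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
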