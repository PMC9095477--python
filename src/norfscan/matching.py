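"""Matching nORFs to assembled transcripts.

A transcript is a candidate when it survives the TPM expression filter and
is not a pseudoautosomal (PAR) feature. An nORF matches a transcript when
their intron chains are identical (class "=") or the nORF is contained in
the transcript, the nORF's exon boundaries lie inside the transcript's exon
structure, and the transcript's biotype is not protein-coding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GenomicInterval, NorfRecord, TranscriptModel, overlaps

logger = logging.getLogger(__name__)

PAR_SUFFIXES = ("_PAR_Y", "_PAR_X")


@dataclass(frozen=True)
class NorfTranscriptMatch:
    norf_id: str
    transcript_id: str
    match_class: str  # intron_chain_equal | contained
    biotype: str


def expression_filter(
    matrix: ExpressionMatrix, tpm_min: float = 0.1, sample_frac: float = 0.10
) -> list[str]:
    """Keep features with TPM strictly above ``tpm_min`` in at least
    ceil(sample_frac * n_samples) samples."""
    if matrix.unit != "TPM":
        raise ValueError(f"expression filter expects TPM, got {matrix.unit!r}")
    if not (0 <= sample_frac <= 1):
        raise ValueError("sample_frac must be in [0, 1]")
    n = matrix.values.shape[1]
    if n == 0 or matrix.values.shape[0] == 0:
        return []
    needed = math.ceil(sample_frac * n)
    counts = (matrix.values > tpm_min).sum(axis=1)
    return list(matrix.values.index[counts >= needed])


def remove_par_features(
    transcripts: Sequence[TranscriptModel],
    par_regions: Sequence[GenomicInterval] = (),
) -> list[TranscriptModel]:
    """Drop transcripts in pseudoautosomal regions (span overlap) or whose
    id carries a PAR suffix tag."""
    out = []
    for t in transcripts:
        if any(t.transcript_id.endswith(suf) for suf in PAR_SUFFIXES):
            continue
        if any(overlaps(t.span, par) for par in par_regions):
            continue
        out.append(t)
    return out


def _introns(exons) -> tuple:
    return tuple((e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:]))


def intron_chain_equal(a_exons: Sequence, b_exons: Sequence) -> bool:
    """True iff both chains are multi-exon with identical ordered junctions.

    Single-exon chains have no junctions and never match here; they are
    handled by containment.
    """
    for exons in (a_exons, b_exons):
        if list(exons) != sorted(exons):
            raise ValueError("exon chain must be sorted")
    ia, ib = _introns(a_exons), _introns(b_exons)
    if not ia or not ib:
        return False
    return ia == ib


def norf_contained_in(norf: NorfRecord, transcript: TranscriptModel) -> bool:
    """True iff every nORF exon base lies in the transcript's exon union and
    every internal nORF junction is a transcript junction."""
    if norf.chrom != transcript.chrom or norf.strand != transcript.strand:
        return False
    t_junctions = set(transcript.introns)
    for j in norf.introns:
        if j not in t_junctions:
            return False
    for s, e in norf.exons:
        if not any(ts <= s and e <= te for ts, te in transcript.exons):
            # an nORF exon may be split by a shared junction: check coverage
            # base-wise against the exon union
            covered = 0
            for ts, te in transcript.exons:
                lo, hi = max(s, ts), min(e, te)
                if lo < hi:
                    covered += hi - lo
            if covered != e - s:
                return False
    return True


def match_norfs(
    norfs: Sequence[NorfRecord],
    transcripts: Sequence[TranscriptModel],
    retained_ids: Iterable[str],
) -> list[NorfTranscriptMatch]:
    """Record (nORF, transcript) matches per the class-"="/containment rule.

    Transcripts must be in ``retained_ids`` (expression filter) and not
    protein-coding; a missing biotype is treated as non-protein-coding and
    logged. One nORF may match many transcripts.
    """
    retained = set(retained_ids)
    matches = []
    cands = [t for t in transcripts if t.transcript_id in retained]
    cands.sort(key=lambda t: t.transcript_id)
    for t in cands:
        if t.biotype == "protein-coding":
            continue
        if not t.biotype:
            logger.info("transcript %s has no biotype; kept", t.transcript_id)
    for norf in norfs:
        for t in cands:
            if t.biotype == "protein-coding":
                continue
            if t.chrom != norf.chrom or t.strand != norf.strand:
                continue
            if not norf_contained_in(norf, t):
                continue
            if intron_chain_equal(norf.exons, t.exons):
                cls = "intron_chain_equal"
            else:
                cls = "contained"
            matches.append(
                NorfTranscriptMatch(norf.norf_id, t.transcript_id, cls, t.biotype)
            )
    return matches


def matches_to_frame(matches: Sequence[NorfTranscriptMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.norf_id, m.transcript_id, m.match_class, m.biotype) for m in matches],
        columns=["norf_id", "transcript_id", "match_class", "biotype"],
    )


def biotype_composition(matches: Sequence[NorfTranscriptMatch]) -> pd.DataFrame:
    """Percentage of nORF-containing transcripts per biotype."""
    df = matches_to_frame(matches)
    if df.empty:
        return pd.DataFrame(columns=["biotype", "n_transcripts", "percent"])
    uniq = df.drop_duplicates("transcript_id")
    counts = uniq["biotype"].value_counts()
    out = counts.rename_axis("biotype").reset_index(name="n_transcripts")
    out["percent"] = 100.0 * out["n_transcripts"] / out["n_transcripts"].sum()
    return out
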