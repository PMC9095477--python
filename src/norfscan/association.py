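"""HAR and TE association with nORFs.

Human accelerated regions (HARs) compiled from multiple source lists are
overlap-merged into unique HARs that remember their members' conservation
groups (vHAR/mHAR/pHAR: conserved in vertebrates, mammals, or non-human
primates). An nORF is HAR-associated when a unique HAR overlaps the nORF or
lies within a +/-100 kb window around it, and TE-associated when a
transposable element overlaps the 2 kb region immediately upstream of the
nORF without touching the nORF itself (the alternative-promoter scenario).
Features overlapping differentially expressed transcripts are designated DE
HARs / DE TEs, and DE nORF-DE TE expression pairs are screened with a dual
Pearson + Spearman correlation gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ExpressionMatrix,
    GenomicInterval,
    MergedInterval,
    NorfRecord,
    TranscriptModel,
    distance,
    merge_intervals,
    overlaps,
)

HAR_GROUPS = ("vHAR", "mHAR", "pHAR")


@dataclass(frozen=True)
class HarMember:
    source: str
    har_id: str
    group: str


@dataclass(frozen=True)
class UniqueHar:
    har_id: str
    interval: GenomicInterval
    members: tuple  # HarMember
    group_set: frozenset


@dataclass(frozen=True)
class AssociationPair:
    norf_id: str
    feature_id: str
    relation: str  # overlap | within_window | upstream
    distance: int  # signed gap; 0 if overlap; negative = feature left of nORF


def build_unique_hars(har_table: pd.DataFrame) -> list[UniqueHar]:
    """Merge multi-source HAR lists into unique HARs with provenance.

    ``har_table`` needs columns chrom, start, end, name, source, group.
    """
    bad = set(har_table["group"]) - set(HAR_GROUPS)
    if bad:
        raise ValueError(f"unknown HAR group labels: {sorted(bad)}")
    intervals, members = [], []
    for r in har_table.itertuples(index=False):
        intervals.append(GenomicInterval(r.chrom, int(r.start), int(r.end)))
        members.append(HarMember(str(r.source), str(r.name), str(r.group)))
    merged = merge_intervals(intervals, provenance=members)
    out = []
    for i, m in enumerate(merged):
        out.append(
            UniqueHar(
                har_id=f"uhar_{i + 1}",
                interval=m.interval,
                members=m.members,
                group_set=frozenset(mm.group for mm in m.members),
            )
        )
    return out


def unique_har_summary(unique_hars: Sequence[UniqueHar]) -> pd.DataFrame:
    """Count and per-group fractions; a HAR may count toward several groups."""
    n = len(unique_hars)
    rows = [("unique_hars", n, 1.0 if n else 0.0)]
    for g in HAR_GROUPS:
        k = sum(1 for h in unique_hars if g in h.group_set)
        rows.append((g, k, k / n if n else 0.0))
    return pd.DataFrame(rows, columns=["group", "count", "fraction"])


def associate_norf_har(
    norfs: Sequence[NorfRecord],
    unique_hars: Sequence[UniqueHar],
    window: int = 100_000,
) -> list[AssociationPair]:
    """Pair each nORF with unique HARs overlapping it or within the window.

    The window is inclusive: a HAR whose gap to the nORF span equals
    ``window`` is associated. Strand-agnostic.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    pairs = []
    for norf in norfs:
        span = norf.span
        for har in unique_hars:
            if har.interval.chrom != span.chrom:
                continue
            d = distance(har.interval, span)
            if d > window:
                continue
            if overlaps(har.interval, span):
                rel, signed = "overlap", 0
            else:
                rel = "within_window"
                signed = -int(d) if har.interval.end <= span.start else int(d)
            pairs.append(AssociationPair(norf.norf_id, har.har_id, rel, signed))
    return pairs


def upstream_window(
    norf: NorfRecord, size: int = 2000, strand_aware: bool = True
) -> Optional[GenomicInterval]:
    """The ``size``-base region immediately upstream of an nORF.

    Upstream is 5' of the span: left of the start on the + strand, right of
    the end on the - strand (left-of-start for every record when
    ``strand_aware`` is off). None when clipping at the contig edge empties
    the window.
    """
    span = norf.span
    if strand_aware and norf.strand not in ("+", "-"):
        raise ValueError(f"nORF {norf.norf_id} is unstranded; upstream undefined")
    if not strand_aware or norf.strand == "+":
        lo, hi = max(0, span.start - size), span.start
    else:
        lo, hi = span.end, span.end + size
    if lo >= hi:
        return None
    return GenomicInterval(span.chrom, lo, hi)


def associate_norf_te(
    norfs: Sequence[NorfRecord],
    tes: pd.DataFrame,
    upstream_size: int = 2000,
    strand_aware: bool = True,
) -> list[AssociationPair]:
    """Pair nORFs with TEs overlapping their upstream window only.

    ``tes`` needs columns chrom, start, end, name. A TE touching both the
    window and the nORF span itself is excluded.
    """
    te_iv = [
        (str(r.name), GenomicInterval(r.chrom, int(r.start), int(r.end)))
        for r in tes.itertuples(index=False)
    ]
    pairs = []
    for norf in norfs:
        win = upstream_window(norf, upstream_size, strand_aware)
        if win is None:
            continue
        span = norf.span
        for te_id, iv in te_iv:
            if overlaps(iv, win) and not overlaps(iv, span):
                gap = distance(iv, span)
                signed = -int(gap) if iv.end <= span.start else int(gap)
                pairs.append(AssociationPair(norf.norf_id, te_id, "upstream", signed))
    return pairs


def designate_de_features(
    features: pd.DataFrame,
    de_transcripts: Sequence[TranscriptModel],
    exon_level: bool = False,
) -> pd.DataFrame:
    """Flag features overlapping >=1 DE transcript.

    By default the transcript's genomic span (start-end, introns included)
    is used, so features inside retained introns are designated DE; set
    ``exon_level`` to require exonic overlap.
    """
    out = features.copy()
    flags = []
    n_de_with_feature = 0
    for r in out.itertuples(index=False):
        iv = GenomicInterval(r.chrom, int(r.start), int(r.end))
        hit = False
        for t in de_transcripts:
            if exon_level:
                hit = any(
                    overlaps(iv, GenomicInterval(t.chrom, s, e)) for s, e in t.exons
                )
            else:
                hit = overlaps(iv, t.span)
            if hit:
                break
        flags.append(hit)
    out["is_de"] = flags
    return out


@dataclass(frozen=True)
class CorrelationResult:
    norf_id: str
    te_id: str
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    significant: bool


def correlate_pairs(
    expr: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    r_min: float = 0.5,
    p_max: float = 0.05,
) -> list[CorrelationResult]:
    """Dual Pearson + Spearman screen of nORF/TE expression pairs.

    A pair is significant iff both |r| and |rho| exceed ``r_min`` and both
    p values fall below ``p_max``. Zero-variance vectors give undefined
    coefficients and an insignificant pair.
    """
    if expr.values.shape[1] < 4:
        raise ValueError("need at least 4 samples for the correlation screen")
    out = []
    for norf_id, te_id in pairs:
        x = expr.values.loc[norf_id].to_numpy(dtype=float)
        y = expr.values.loc[te_id].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(
                CorrelationResult(norf_id, te_id, np.nan, np.nan, np.nan, np.nan, False)
            )
            continue
        pr = stats.pearsonr(x, y)
        sr = stats.spearmanr(x, y)
        sig = (
            abs(pr.statistic) > r_min
            and abs(sr.statistic) > r_min
            and pr.pvalue < p_max
            and sr.pvalue < p_max
        )
        out.append(
            CorrelationResult(
                norf_id, te_id,
                float(pr.statistic), float(pr.pvalue),
                float(sr.statistic), float(sr.pvalue),
                bool(sig),
            )
        )
    return out


def correlation_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.norf_id, r.te_id, r.pearson_r, r.pearson_p, r.spearman_rho, r.spearman_p, r.significant)
            for r in results
        ],
        columns=[
            "norf_id", "te_id", "pearson_r", "pearson_p", "spearman_rho", "spearman_p", "significant",
        ],
    )


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "N.S."


def chisq_presence(
    presence: Sequence[bool], groups: Sequence
) -> tuple[float, float, str]:
    """Pearson chi-square of a presence/absence trait across groups."""
    presence = np.asarray(presence, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    table = np.array(
        [
            [int(presence[groups == g].sum()), int((~presence[groups == g]).sum())]
            for g in labels
        ]
    )
    if (table.sum(axis=1) == 0).any():
        raise ValueError("group with zero samples")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), significance_stars(float(p))
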