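"""nORF database construction: TPM conversion, the quantile-binned
expression-noise filter, frame-relative classification and deduplication.

The noise filter compares Ribo-seq expression variability of non-canonical
ORFs with canonical ORFs (cORFs) of similar mean abundance: ORF means are
cut into Q equal-count quantile bins and, within each bin, a non-canonical
ORF is called *low-noise* when its SD falls strictly below the median SD of
the canonical ORFs in that bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, NorfRecord, TranscriptModel

#: categories exempt from in-frame removal
INFRAME_EXCEPTIONS = frozenset(
    {"readthrough", "extended", "extension", "uORF", "truncated", "truncation"}
)


def counts_to_tpm(counts: ExpressionMatrix, lengths: pd.Series | None = None) -> ExpressionMatrix:
    """Convert raw counts to transcripts-per-million.

    Per sample: rate_i = count_i / length_i, TPM_i = 1e6 * rate_i / sum(rate).
    Every column of the result sums to 1e6.
    """
    if counts.unit != "count":
        raise ValueError(f"expected count unit, got {counts.unit!r}")
    if lengths is None:
        lengths = counts.lengths
    if lengths is None:
        raise ValueError("feature lengths required for TPM conversion")
    missing = counts.values.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing length for features: {list(missing)[:5]}")
    lens = lengths.reindex(counts.values.index).astype(float)
    if (lens <= 0).any():
        raise ValueError("feature lengths must be positive")
    rates = counts.values.div(lens, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample columns (TPM undefined): {list(zero.index)}")
    tpm = rates.div(totals, axis=1) * 1e6
    return ExpressionMatrix(values=tpm, unit="TPM", lengths=lengths)


@dataclass
class NoiseFilterResult:
    """Per-ORF noise-filter report plus the list of bins without cORFs."""

    table: pd.DataFrame  # orf_id, mean, sd, bin, bin_median_corf_sd, low_noise
    empty_bins: list = field(default_factory=list)

    @property
    def low_noise_ids(self) -> list[str]:
        t = self.table
        return list(t.loc[t["low_noise"] == True, "orf_id"])  # noqa: E712


def low_noise_filter(
    tpm: ExpressionMatrix, is_canonical: pd.Series, q: int = 4000
) -> NoiseFilterResult:
    """Flag low-noise non-canonical ORFs via equal-count quantile binning.

    ORFs are sorted by mean TPM (ties broken by ORF id) and cut into ``q``
    contiguous bins whose sizes differ by at most one. Within a bin the
    median SD over canonical ORFs is the noise yardstick; a non-canonical
    ORF is low-noise iff its SD is strictly below it. Bins holding no
    canonical ORF flag nothing and are listed in ``empty_bins``.
    """
    n = tpm.values.shape[0]
    if tpm.values.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute an SD")
    if q < 1:
        raise ValueError("q must be >= 1")
    if q > n:
        raise ValueError(f"q={q} exceeds number of ORFs ({n})")
    canon = is_canonical.reindex(tpm.values.index)
    if canon.isna().any():
        raise ValueError("is_canonical flag missing for some ORFs")

    means = tpm.values.mean(axis=1)
    sds = tpm.values.std(axis=1, ddof=1)
    order = pd.DataFrame({"mean": means, "sd": sds, "canonical": canon.astype(bool)})
    # stable sort by mean with ties broken by ORF id
    order = order.sort_index(kind="mergesort").sort_values("mean", kind="mergesort")

    # equal-count bins; first (n % q) bins take the extra ORF
    base, extra = divmod(n, q)
    sizes = [base + 1] * extra + [base] * (q - extra)
    bins = np.repeat(np.arange(1, q + 1), sizes)
    order["bin"] = bins

    empty_bins = []
    medians = {}
    for b, grp in order.groupby("bin"):
        corf_sds = grp.loc[grp["canonical"], "sd"]
        if len(corf_sds) == 0:
            empty_bins.append(int(b))
            medians[b] = np.nan
        else:
            medians[b] = float(corf_sds.median())
    if empty_bins:
        warnings.warn(
            f"{len(empty_bins)} quantile bins contain no canonical ORF; "
            "their nORFs are left unflagged"
        )
    order["bin_median_corf_sd"] = order["bin"].map(medians)
    order["low_noise"] = (
        (~order["canonical"])
        & order["bin_median_corf_sd"].notna()
        & (order["sd"] < order["bin_median_corf_sd"])
    )
    out = order.reset_index(names="orf_id")[
        ["orf_id", "mean", "sd", "bin", "bin_median_corf_sd", "low_noise"]
    ]
    return NoiseFilterResult(table=out, empty_bins=empty_bins)


def _spliced_offsets(exons, strand):
    """Map genomic base -> transcription-order offset within the chain."""
    total = sum(e - s for s, e in exons)
    offsets = {}
    pos = 0
    for s, e in exons:
        for g in range(s, e):
            offsets[g] = pos if strand == "+" else total - 1 - pos
            pos += 1
    return offsets


def classify_norf_frame(
    norf: NorfRecord, reference: list[TranscriptModel]
) -> str:
    """Classify an nORF's reading frame relative to annotated CDS.

    Projection is through shared exonic bases in spliced coordinates: a
    genomic base covered by both the nORF and a CDS carries a codon phase in
    each; matching phases on the same strand mean in-frame. Precedence:
    in_frame_cds > alt_frame_cds > non_cds > intergenic.
    """
    if sum(e - s for s, e in norf.exons) % 3 != 0:
        warnings.warn(
            f"nORF {norf.norf_id} length not a multiple of 3; "
            "classifying on the first overlapping codon"
        )
    norf_off = _spliced_offsets(norf.exons, norf.strand)
    span = norf.span

    any_transcript = False
    any_alt = False
    for t in reference:
        if t.chrom != norf.chrom:
            continue
        tspan = t.span
        if not (span.start < tspan.end and tspan.start < span.end):
            continue
        any_transcript = True
        if t.cds is None or t.strand != norf.strand:
            continue
        cds_off = _spliced_offsets(t.cds, t.strand)
        shared = sorted(set(norf_off) & set(cds_off))
        if not shared:
            continue
        # decide on the first shared base in transcription order
        first = shared[0] if norf.strand == "+" else shared[-1]
        if norf_off[first] % 3 == cds_off[first] % 3:
            return "in_frame_cds"
        any_alt = True
    if any_alt:
        return "alt_frame_cds"
    if any_transcript:
        return "non_cds"
    return "intergenic"


def classify_norfs(
    norfs: list[NorfRecord], reference: list[TranscriptModel]
) -> list[NorfRecord]:
    return [n.with_frame_class(classify_norf_frame(n, reference)) for n in norfs]


def apply_inframe_removal(norfs: list[NorfRecord]) -> list[NorfRecord]:
    """Drop in-frame-to-CDS nORFs unless their category exempts them.

    Readthrough, extended, uORF and truncated ORFs legitimately share the
    canonical frame, so they survive; every non-in-frame record passes.
    """
    out = []
    for n in norfs:
        if n.frame_class is None:
            raise ValueError(f"nORF {n.norf_id} has no frame classification")
        if n.frame_class == "in_frame_cds" and n.category not in INFRAME_EXCEPTIONS:
            continue
        out.append(n)
    return out


def deduplicate_norfs(norfs: list[NorfRecord]) -> tuple[list[NorfRecord], dict]:
    """Collapse nORFs with identical (chrom, strand, exon chain).

    The lexicographically smallest id survives; the returned alias map sends
    every dropped id to its survivor.
    """
    by_chain: dict[tuple, list[NorfRecord]] = {}
    for n in norfs:
        by_chain.setdefault(n.chain_key(), []).append(n)
    survivors, aliases = [], {}
    for group in by_chain.values():
        group = sorted(group, key=lambda n: n.norf_id)
        survivors.append(group[0])
        for dup in group[1:]:
            aliases[dup.norf_id] = group[0].norf_id
    survivors.sort(key=lambda n: (n.chrom, n.exons[0][0], n.norf_id))
    return survivors, aliases
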