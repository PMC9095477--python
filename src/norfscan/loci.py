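"""Disorder-associated SNP loci and permutation enrichment of nORF sets.

GWAS summary statistics are quality-controlled (Hardy-Weinberg p and minor
allele frequency), stratified by association p value, and greedily clumped
into LD-independent sets (index SNP = smallest p; members joined by r2
within a 3 Mb window). The extreme-LD MHC region is collapsed to the single
clump whose index SNP position is the median. Loci are the genomic spans of
SNPs in strong LD (r2 > 0.5) within 250 kb of an index SNP.

Enrichment of a target nORF set within the loci uses a two-round
permutation scheme: round 1 resamples same-size subsets of the merged
reference nORF set to get an empirical p for the observed count of
target-overlapping loci; round 2 repeats the round-1 procedure on permuted
target sets across all tests of a family, building the null distribution of
the minimum empirical p, which yields a multiple-testing-corrected p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, merge_intervals, normalize_chrom, overlaps

SNP_COLUMNS = ("rsid", "chrom", "pos", "p", "maf", "hwe_p")

#: MHC region, hg19 1-based inclusive chr6:28,477,797-33,448,354
MHC_HG19 = GenomicInterval("chr6", 28_477_796, 33_448_354)

DEFAULT_STRATA = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7)


def validate_snps(snps: pd.DataFrame) -> pd.DataFrame:
    for col in SNP_COLUMNS:
        if col not in snps.columns:
            raise ValueError(f"SNP table missing column {col!r}")
    snps = snps.copy()
    snps["chrom"] = snps["chrom"].map(normalize_chrom)
    if ((snps["maf"] <= 0) | (snps["maf"] > 0.5)).any():
        raise ValueError("MAF must lie in (0, 0.5]")
    if ((snps["p"] <= 0) | (snps["p"] > 1)).any():
        raise ValueError("association p must lie in (0, 1]")
    return snps


def snp_qc(
    snps: pd.DataFrame, hwe_p_min: float = 1e-4, maf_min: float = 0.05
) -> pd.DataFrame:
    """Drop SNPs out of Hardy-Weinberg equilibrium or with low MAF (strict <)."""
    snps = validate_snps(snps)
    keep = (snps["hwe_p"] >= hwe_p_min) & (snps["maf"] >= maf_min)
    return snps[keep].reset_index(drop=True)


def stratify_snps(
    snps: pd.DataFrame, bounds: Sequence[float] = DEFAULT_STRATA
) -> dict[float, pd.DataFrame]:
    """Nested SNP subsets with association p strictly below each bound."""
    if list(bounds) != sorted(bounds, reverse=True):
        raise ValueError("bounds must be sorted descending")
    return {b: snps[snps["p"] < b].reset_index(drop=True) for b in bounds}


class LdTable:
    """Sparse symmetric pairwise r2 lookup; missing pairs are r2 = 0."""

    def __init__(self, table: pd.DataFrame):
        for col in ("rsid_a", "rsid_b", "r2"):
            if col not in table.columns:
                raise ValueError(f"r2 table missing column {col!r}")
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in table[["rsid_a", "rsid_b", "r2"]].itertuples(index=False):
            key = (a, b) if a <= b else (b, a)
            if key in self._r2 and abs(self._r2[key] - r2) > 1e-12:
                raise ValueError(f"asymmetric r2 entries for pair {key}")
            self._r2[key] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        return self._r2.get(key, 0.0)


@dataclass
class Clump:
    index_rsid: str
    index_pos: int
    chrom: str
    index_p: float
    members: list = field(default_factory=list)  # rsids incl. index


def ld_clump(
    snps: pd.DataFrame,
    ld: LdTable,
    index_p_max: float = 1e-4,
    r2_min: float = 0.1,
    window: int = 3_000_000,
) -> list[Clump]:
    """Greedy LD clumping.

    SNPs are processed in ascending p (ties by position then rsid). An
    unassigned SNP with p < index_p_max becomes an index; every unassigned
    SNP on the same chromosome within the window and with r2 >= r2_min
    joins its clump. Index SNPs therefore end up pairwise independent
    (r2 < r2_min or farther apart than the window).
    """
    snps = validate_snps(snps)
    order = snps.sort_values(["p", "pos", "rsid"], kind="mergesort")
    assigned: set[str] = set()
    clumps: list[Clump] = []
    rows = list(order.itertuples(index=False))
    for row in rows:
        if row.rsid in assigned or row.p >= index_p_max:
            continue
        clump = Clump(
            index_rsid=row.rsid,
            index_pos=int(row.pos),
            chrom=row.chrom,
            index_p=float(row.p),
            members=[row.rsid],
        )
        assigned.add(row.rsid)
        for other in rows:
            if other.rsid in assigned or other.chrom != row.chrom:
                continue
            if abs(int(other.pos) - int(row.pos)) > window:
                continue
            if ld.r2(row.rsid, other.rsid) >= r2_min:
                clump.members.append(other.rsid)
                assigned.add(other.rsid)
        clumps.append(clump)
    return clumps


def mhc_collapse(
    clumps: Sequence[Clump], mhc: GenomicInterval = MHC_HG19
) -> list[Clump]:
    """Keep only the clump with the median index position inside the MHC.

    Even counts take the lower median. Clumps outside the MHC pass through.
    """
    inside = [
        c
        for c in clumps
        if c.chrom == mhc.chrom and mhc.start <= c.index_pos - 1 < mhc.end
    ]
    if len(inside) <= 1:
        return list(clumps)
    inside_sorted = sorted(inside, key=lambda c: c.index_pos)
    keep = inside_sorted[(len(inside_sorted) - 1) // 2]
    dropped = {c.index_rsid for c in inside if c is not keep}
    return [c for c in clumps if c.index_rsid not in dropped]


@dataclass(frozen=True)
class Locus:
    interval: GenomicInterval
    index_rsid: str
    stratum: float


def define_loci(
    index_snps: Sequence[str],
    snps: pd.DataFrame,
    ld: LdTable,
    r2_locus: float = 0.5,
    span: int = 250_000,
    stratum: float = np.nan,
) -> list[Locus]:
    """Locus = span of the index SNP and all SNPs with r2 > r2_locus
    (strict) within ``span`` bases of it; 1-base when nothing is linked."""
    snps = validate_snps(snps)
    pos = dict(zip(snps["rsid"], snps["pos"].astype(int)))
    chrom = dict(zip(snps["rsid"], snps["chrom"]))
    missing = [r for r in index_snps if r not in pos]
    if missing:
        raise ValueError(f"index SNPs absent from SNP table: {missing[:5]}")
    loci = []
    for rsid in index_snps:
        ipos, ichrom = pos[rsid], chrom[rsid]
        linked = [
            (r, p)
            for r, p in pos.items()
            if chrom[r] == ichrom
            and abs(p - ipos) <= span
            and ld.r2(rsid, r) > r2_locus
        ]
        positions = [ipos] + [p for _, p in linked]
        lo, hi = min(positions), max(positions)
        loci.append(
            Locus(
                interval=GenomicInterval(ichrom, lo - 1, hi),  # 1-based -> half-open
                index_rsid=rsid,
                stratum=stratum,
            )
        )
    return loci


def loci_for_strata(
    snps: pd.DataFrame,
    ld: LdTable,
    bounds: Sequence[float] = DEFAULT_STRATA,
    index_p_max: float = 1e-4,
    r2_min: float = 0.1,
    clump_window: int = 3_000_000,
    r2_locus: float = 0.5,
    locus_span: int = 250_000,
    mhc: GenomicInterval = MHC_HG19,
) -> dict[float, list[Locus]]:
    """QC -> stratify -> clump -> MHC collapse -> loci, per p-value stratum."""
    clean = snp_qc(snps)
    strata = stratify_snps(clean, bounds)
    out = {}
    for bound, sub in strata.items():
        if sub.empty:
            out[bound] = []
            continue
        clumps = ld_clump(sub, ld, index_p_max=index_p_max, r2_min=r2_min, window=clump_window)
        clumps = mhc_collapse(clumps, mhc)
        out[bound] = define_loci(
            [c.index_rsid for c in clumps], sub, ld,
            r2_locus=r2_locus, span=locus_span, stratum=bound,
        )
    return out


# ---------------------------------------------------------------------------
# Permutation enrichment


@dataclass
class EnrichmentResult:
    stratum: float
    n_targets: int  # merged targets
    observed_loci: int  # loci overlapping >=1 merged target
    observed_targets: int  # merged targets overlapping >=1 locus
    empirical_p: float
    corrected_p: float
    n_permutations: int
    seed: Optional[int] = None


def _merge_spans(named: Sequence[tuple[str, GenomicInterval]]) -> list[GenomicInterval]:
    if not named:
        return []
    merged = merge_intervals([iv for _, iv in named], provenance=[n for n, _ in named])
    return [m.interval for m in merged]


def _overlap_matrix(loci: Sequence[Locus], units: Sequence[GenomicInterval]) -> np.ndarray:
    mat = np.zeros((len(loci), len(units)), dtype=bool)
    for i, locus in enumerate(loci):
        for j, u in enumerate(units):
            mat[i, j] = overlaps(locus.interval, u)
    return mat


def interval_enrichment(
    target_ids: Sequence[str],
    reference: Sequence[tuple[str, GenomicInterval]],
    loci: Sequence[Locus],
    n_perm: int = 5000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    stratum: float = np.nan,
) -> EnrichmentResult:
    """Round-1 permutation enrichment of a target nORF set within loci.

    Overlapping targets and overlapping reference nORFs are merged first.
    The statistic is the number of loci overlapping >=1 merged target; the
    null resamples same-size subsets of the merged reference uniformly
    without replacement. Empirical p uses the +1 correction. corrected_p is
    set equal to empirical_p here; use :func:`enrichment_scan` for the
    round-2 family correction.
    """
    if not loci:
        raise ValueError("loci must be non-empty")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small for a permutation test")
    ref_ids = {n for n, _ in reference}
    missing = set(target_ids) - ref_ids
    if missing:
        raise ValueError(f"targets not in reference: {sorted(missing)[:5]}")
    target_named = [(n, iv) for n, iv in reference if n in set(target_ids)]
    merged_targets = _merge_spans(target_named)
    merged_ref = _merge_spans(reference)
    k = len(merged_targets)
    if k > len(merged_ref):
        raise ValueError("more merged targets than merged reference units")
    t_mat = _overlap_matrix(loci, merged_targets)
    observed_loci = int(t_mat.any(axis=1).sum())
    observed_targets = int(t_mat.any(axis=0).sum())
    r_mat = _overlap_matrix(loci, merged_ref)
    if rng is None:
        rng = np.random.default_rng(seed)
    n_units = len(merged_ref)
    null = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        idx = rng.choice(n_units, size=k, replace=False)
        null[b] = int(r_mat[:, idx].any(axis=1).sum())
    emp_p = (1 + int((null >= observed_loci).sum())) / (1 + n_perm)
    return EnrichmentResult(
        stratum=stratum,
        n_targets=k,
        observed_loci=observed_loci,
        observed_targets=observed_targets,
        empirical_p=float(emp_p),
        corrected_p=float(emp_p),
        n_permutations=n_perm,
        seed=seed,
    )


def enrichment_scan(
    target_sets: dict[str, Sequence[str]],
    reference: Sequence[tuple[str, GenomicInterval]],
    loci_by_stratum: dict[float, Sequence[Locus]],
    n_perm: int = 5000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Strata x target-set enrichment with round-2 family correction.

    For each target set (family), every non-empty stratum is a test. Round
    2 draws ``n_perm`` replicate target sets, scores each test's replicate
    against its round-1 null to get a replicate empirical p, and corrects
    each observed empirical p by the fraction of replicates whose minimum
    across the family is at least as small. corrected_p is floored at
    empirical_p.
    """
    rng = np.random.default_rng(seed)
    merged_ref = _merge_spans(reference)
    n_units = len(merged_ref)
    rows = []
    for set_name, target_ids in target_sets.items():
        tests = []  # (stratum, result, null array, k, r_mat)
        for stratum, loci in loci_by_stratum.items():
            if not loci:
                continue
            res = interval_enrichment(
                target_ids, reference, loci, n_perm=n_perm, rng=rng, stratum=stratum
            )
            r_mat = _overlap_matrix(loci, merged_ref)
            # rebuild round-1 null for scoring round-2 replicates
            null = np.empty(n_perm, dtype=int)
            for b in range(n_perm):
                idx = rng.choice(n_units, size=res.n_targets, replace=False)
                null[b] = int(r_mat[:, idx].any(axis=1).sum())
            tests.append((stratum, res, null, res.n_targets, r_mat))
        if not tests:
            continue
        min_ps = np.empty(n_perm)
        for b in range(n_perm):
            reps = []
            for _, res, null, k, r_mat in tests:
                idx = rng.choice(n_units, size=k, replace=False)
                stat = int(r_mat[:, idx].any(axis=1).sum())
                reps.append((1 + int((null >= stat).sum())) / (1 + n_perm))
            min_ps[b] = min(reps)
        for stratum, res, null, k, _ in tests:
            corrected = (1 + int((min_ps <= res.empirical_p).sum())) / (1 + n_perm)
            corrected = max(corrected, res.empirical_p)
            rows.append(
                (
                    set_name, stratum, res.n_targets, res.observed_loci,
                    res.observed_targets, res.empirical_p, float(corrected), n_perm,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "target_set", "stratum", "n_targets", "n_overlap_loci",
            "n_overlap_targets", "empirical_p", "corrected_p", "n_permutations",
        ],
    )
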