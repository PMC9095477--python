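"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of real consortium-scale
inputs: negative-binomial RNA-seq counts with per-individual random
intercepts and planted fold changes, Ribo-seq count strata with matched
means and varying SDs, multi-source HAR and TE interval sets with planted
nORF co-locations, and block-LD GWAS summary statistics with planted causal
loci. Every generator is a pure function of (seed, parameters): the same
seed yields byte-identical output files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, NorfRecord, TranscriptModel
from . import io as nio

CHROM_LENGTHS = {"chrS1": 30_000_000, "chrS2": 30_000_000, "chrSY": 3_000_000}

DEFAULT_BIOTYPE_MIX = {
    "protein-coding": 0.4,
    "retained_intron": 0.25,
    "processed_transcript": 0.15,
    "lincRNA": 0.12,
    "antisense": 0.08,
}


@dataclass
class SimulationTruth:
    """Planted ground truth sufficient to score every downstream stage."""

    de_transcripts: dict = field(default_factory=dict)  # case -> {tid: lfc}
    low_noise_norfs: set = field(default_factory=set)
    norf_har_pairs: set = field(default_factory=set)  # (norf_id, har_id)
    norf_te_pairs: set = field(default_factory=set)
    causal_loci: list = field(default_factory=list)  # GenomicInterval
    causal_target_norfs: set = field(default_factory=set)
    correlated_pairs: dict = field(default_factory=dict)  # (norf, te) -> rho
    norf_transcript: dict = field(default_factory=dict)  # norf_id -> transcript_id
    skipped_plants: list = field(default_factory=list)
    intercept_sd: float = 0.0
    nb_dispersion: float = 0.0

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        rows = [
            (case, tid, lfc)
            for case, d in sorted(self.de_transcripts.items())
            for tid, lfc in sorted(d.items())
        ]
        nio.write_tsv(
            pd.DataFrame(rows, columns=["case", "transcript_id", "lfc"]),
            outdir / "truth_de_transcripts.tsv",
        )
        nio.write_tsv(
            pd.DataFrame(sorted(self.low_noise_norfs), columns=["orf_id"]),
            outdir / "truth_low_noise.tsv",
        )
        nio.write_tsv(
            pd.DataFrame(sorted(self.norf_har_pairs), columns=["norf_id", "har_id"]),
            outdir / "truth_norf_har.tsv",
        )
        nio.write_tsv(
            pd.DataFrame(sorted(self.norf_te_pairs), columns=["norf_id", "te_id"]),
            outdir / "truth_norf_te.tsv",
        )
        nio.write_tsv(
            pd.DataFrame(
                [(iv.chrom, iv.start, iv.end) for iv in self.causal_loci],
                columns=["chrom", "start", "end"],
            ),
            outdir / "truth_causal_loci.tsv",
        )
        nio.write_tsv(
            pd.DataFrame(sorted(self.causal_target_norfs), columns=["norf_id"]),
            outdir / "truth_causal_norfs.tsv",
        )
        nio.write_tsv(
            pd.DataFrame(
                sorted(self.norf_transcript.items()), columns=["norf_id", "transcript_id"]
            ),
            outdir / "truth_norf_transcript.tsv",
        )


# ---------------------------------------------------------------------------
# Annotation


def generate_annotation(
    seed: int,
    n_genes: int = 60,
    exons_per_gene: int = 3,
    biotype_mix: Optional[dict] = None,
    chroms: Sequence[str] = ("chrS1", "chrS2"),
    include_sex_features: bool = True,
) -> list[TranscriptModel]:
    """Non-overlapping single-transcript genes on >=2 synthetic chromosomes.

    Protein-coding transcripts carry a CDS covering their internal exonic
    span (frame 0 at the CDS start). With ``include_sex_features``, male-only
    genes are added on chrSY and an XIST-like feature on chrS1.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    mix = dict(DEFAULT_BIOTYPE_MIX if biotype_mix is None else biotype_mix)
    total = sum(mix.values())
    labels = sorted(mix)
    probs = np.array([mix[b] / total for b in labels])
    rng = np.random.default_rng(seed)
    cursors = {c: 150_000 for c in chroms}
    out: list[TranscriptModel] = []
    for g in range(n_genes):
        chrom = chroms[g % len(chroms)]
        biotype = labels[rng.choice(len(labels), p=probs)]
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[chrom] + int(rng.integers(120_000, 220_000))
        exons = []
        pos = start
        for e in range(exons_per_gene):
            size = int(rng.integers(150, 600)) * 3
            exons.append((pos, pos + size))
            pos += size + int(rng.integers(300, 2000))
        end = exons[-1][1]
        if end > CHROM_LENGTHS.get(chrom, 30_000_000) - 100_000:
            raise ValueError(f"cannot pack {n_genes} genes on {len(chroms)} chromosomes")
        cursors[chrom] = end
        cds = None
        if biotype == "protein-coding":
            cds = tuple(exons)
        tid = f"tx_{g + 1:04d}"
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=f"gene_{g + 1:04d}",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                biotype=biotype,
                cds=cds,
            )
        )
    if include_sex_features:
        for i in range(3):
            s = 200_000 + i * 400_000
            out.append(
                TranscriptModel(
                    transcript_id=f"chrY_gene_{i + 1}",
                    gene_id=f"chrY_gene_{i + 1}",
                    chrom="chrSY",
                    strand="+",
                    exons=((s, s + 900),),
                    biotype="protein-coding",
                    cds=((s, s + 900),),
                )
            )
        out.append(
            TranscriptModel(
                transcript_id="XIST",
                gene_id="XIST",
                chrom="chrS1",
                strand="-",
                exons=((50_000, 65_000),),
                biotype="lincRNA",
            )
        )
    return out


def generate_norfs(
    seed: int,
    transcripts: Sequence[TranscriptModel],
    contained_fraction: float = 0.8,
) -> tuple[list[NorfRecord], dict]:
    """One nORF per eligible non-protein-coding transcript, plus decoys.

    A contained nORF reuses its host transcript's internal junctions so the
    matching stage can recover it; the remainder are intergenic decoys.
    Returns the records and the truth map nORF -> host transcript.
    """
    rng = np.random.default_rng(seed)
    norfs = []
    host_of = {}
    i = 0
    hosts = [
        t
        for t in transcripts
        if t.biotype not in ("protein-coding",) and t.chrom != "chrSY"
        and t.transcript_id != "XIST"
    ]
    for t in hosts:
        i += 1
        if rng.random() < contained_fraction:
            # trim the terminal exons, keep every junction
            exons = list(t.exons)
            first = (exons[0][0] + 3 * int(rng.integers(1, 20)), exons[0][1])
            last = (exons[-1][0], exons[-1][1] - 3 * int(rng.integers(1, 20)))
            exons[0] = first
            exons[-1] = last
            norf = NorfRecord(
                norf_id=f"norf_{i:04d}",
                chrom=t.chrom,
                strand=t.strand,
                exons=tuple(exons),
                category="non_coding_transcript",
            )
            host_of[norf.norf_id] = t.transcript_id
        else:
            span = t.span
            s = span.end + int(rng.integers(20_000, 60_000))
            norf = NorfRecord(
                norf_id=f"norf_{i:04d}",
                chrom=t.chrom,
                strand="+" if rng.random() < 0.5 else "-",
                exons=((s, s + 3 * int(rng.integers(40, 120))),),
                category="non_coding_transcript",
            )
        norfs.append(norf)
    return norfs, host_of


# ---------------------------------------------------------------------------
# Ribo-seq counts


def generate_riboseq_counts(
    seed: int,
    n_corfs: int = 200,
    n_norfs: int = 200,
    n_samples: int = 50,
    noise_plan: Optional[dict] = None,
    base_cv: float = 0.3,
    orf_length: int = 300,
) -> tuple["pd.DataFrame", pd.Series, pd.Series, SimulationTruth]:
    """Ribo-seq count matrix with mean-matched cORF/nORF strata.

    cORFs and nORFs share a grid of mean abundances so equal-count quantile
    bins hold both classes. ``noise_plan`` maps nORF ids to SD multipliers
    relative to mean-matched cORFs (default: half at 0.5, half at 2.0);
    multipliers < 1 define the planted low-noise truth. Returns (counts,
    lengths, is_canonical, truth).
    """
    if n_samples < 2:
        raise ValueError("need >= 2 samples for an SD")
    rng = np.random.default_rng(seed)
    grid = np.unique(np.round(np.geomspace(30, 3000, 25)).astype(int))
    corf_ids = [f"corf_{i + 1:04d}" for i in range(n_corfs)]
    norf_ids = [f"rnorf_{i + 1:04d}" for i in range(n_norfs)]
    if noise_plan is None:
        noise_plan = {
            nid: (0.5 if i % 2 == 0 else 2.0) for i, nid in enumerate(norf_ids)
        }
    means = {}
    for i, oid in enumerate(corf_ids):
        means[oid] = int(grid[i % len(grid)])
    for i, oid in enumerate(norf_ids):
        means[oid] = int(grid[i % len(grid)])
    rows = {}
    for oid in corf_ids + norf_ids:
        m = means[oid]
        mult = noise_plan.get(oid, 1.0)
        sd = (mult if oid in noise_plan else 1.0) * base_cv * m
        vals = rng.normal(m, sd, size=n_samples)
        rows[oid] = np.round(np.clip(vals, 0, None)).astype(int)
    counts = pd.DataFrame(
        rows, index=[f"rs_{j + 1:03d}" for j in range(n_samples)]
    ).T
    lengths = pd.Series(orf_length, index=counts.index, dtype=int)
    is_canonical = pd.Series(
        [oid in set(corf_ids) for oid in counts.index], index=counts.index
    )
    truth = SimulationTruth(
        low_noise_norfs={nid for nid, m in noise_plan.items() if m < 1.0}
    )
    return counts, lengths, is_canonical, truth


# ---------------------------------------------------------------------------
# Case/control RNA-seq counts


def _assign_individuals(rng, n_samples: int, prefix: str, repeat_frac: float = 0.3):
    """Sample -> individual map where ~repeat_frac of individuals give 2 samples."""
    n_repeat = int(round(repeat_frac * n_samples / 2))
    n_ind = n_samples - n_repeat
    inds = [f"{prefix}_ind{i + 1:03d}" for i in range(n_ind)]
    assignment = list(inds)
    assignment += [inds[i] for i in range(n_repeat)]
    return assignment[:n_samples]


def generate_case_control_counts(
    seed: int,
    transcripts: Sequence[TranscriptModel],
    n_cnt: int = 40,
    n_scz: int = 30,
    n_bd: int = 20,
    de_fraction: float = 0.2,
    lfc_range: tuple[float, float] = (1.0, 2.0),
    nb_dispersion: float = 0.2,
    intercept_sd: float = 0.3,
    covariate_effect_sd: float = 0.1,
    de_transcripts: Optional[dict] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Negative-binomial counts for a CNT/SCZ/BD design with random intercepts.

    log mean = baseline + diagnosis lfc + covariate effects + per-individual
    intercept ~ N(0, intercept_sd); counts ~ NB via gamma-Poisson mixing
    with the given dispersion. Planted DE transcripts (``de_fraction`` per
    case group, |lfc| uniform in ``lfc_range``, random sign) make up the
    truth. Sex-linked features: chrSY genes are male-only and XIST is
    female-high. Returns (counts, metadata, truth).
    """
    if not (0 <= de_fraction <= 1):
        raise ValueError("de_fraction must lie in [0, 1]")
    lo, hi = lfc_range
    if de_fraction > 0 and hi <= lo:
        raise ValueError("lfc_range must have positive width when de_fraction > 0")
    rng = np.random.default_rng(seed)
    groups = [("CNT", n_cnt), ("SCZ", n_scz), ("BD", n_bd)]
    sample_ids, diagnoses, individuals = [], [], []
    for label, n in groups:
        inds = _assign_individuals(rng, n, label.lower())
        for j in range(n):
            sample_ids.append(f"{label.lower()}_s{j + 1:03d}")
            diagnoses.append(label)
            individuals.append(inds[j])
    n_samples = len(sample_ids)
    uniq_ind = sorted(set(individuals))
    ind_sex = {ind: ("M" if rng.random() < 0.5 else "F") for ind in uniq_ind}
    ind_intercept = {ind: rng.normal(0.0, intercept_sd) for ind in uniq_ind}
    sex = [ind_sex[i] for i in individuals]
    age = np.round(rng.uniform(20, 80, size=n_samples), 1)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "diagnosis": diagnoses,
            "individual_id": individuals,
            "sex": sex,
            "age": age,
        }
    )

    tids = [t.transcript_id for t in transcripts]
    autosomal = [
        t.transcript_id
        for t in transcripts
        if t.chrom != "chrSY" and t.transcript_id != "XIST"
    ]
    if de_transcripts is None:
        de_transcripts = {}
        for case in ("SCZ", "BD"):
            n_de = int(round(de_fraction * len(autosomal)))
            chosen = list(rng.choice(autosomal, size=n_de, replace=False))
            lfcs = rng.uniform(lo, hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
            de_transcripts[case] = dict(zip(chosen, np.round(lfcs, 3)))

    baseline = {tid: rng.uniform(np.log(30), np.log(600)) for tid in tids}
    age_beta = {tid: rng.normal(0.0, covariate_effect_sd / 30.0) for tid in tids}
    diag_idx = np.array(diagnoses)
    age_c = age - age.mean()
    counts = np.zeros((len(tids), n_samples), dtype=int)
    tx_by_id = {t.transcript_id: t for t in transcripts}
    for i, tid in enumerate(tids):
        t = tx_by_id[tid]
        log_mu = np.full(n_samples, baseline[tid])
        for case in ("SCZ", "BD"):
            if tid in de_transcripts.get(case, {}):
                log_mu[diag_idx == case] += de_transcripts[case][tid] * np.log(2)
        log_mu = log_mu + age_beta[tid] * age_c
        log_mu = log_mu + np.array([ind_intercept[ind] for ind in individuals])
        mu = np.exp(log_mu)
        if t.chrom == "chrSY":
            mu = mu * np.array([1.0 if s == "M" else 0.0 for s in sex])
        if tid == "XIST":
            mu = mu * np.array([1.0 if s == "F" else 0.02 for s in sex])
        if nb_dispersion > 0:
            lam = rng.gamma(shape=1.0 / nb_dispersion, scale=mu * nb_dispersion)
        else:
            lam = mu
        counts[i] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=tids, columns=sample_ids)
    truth = SimulationTruth(
        de_transcripts=de_transcripts,
        intercept_sd=intercept_sd,
        nb_dispersion=nb_dispersion,
    )
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# HAR / TE features


def generate_features(
    seed: int,
    norfs: Sequence[NorfRecord],
    n_hars: int = 40,
    n_tes: int = 60,
    planted_har_pairs: Optional[Sequence[tuple[str, str]]] = None,
    planted_te_pairs: Optional[Sequence[str]] = None,
    har_group_mix: tuple[float, float, float] = (0.454, 0.110, 0.436),
    har_window: int = 100_000,
    te_upstream: int = 2000,
    sources: Sequence[str] = ("src1", "src2", "src3"),
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """HAR and TE interval tables with planted nORF co-locations.

    ``planted_har_pairs`` is a list of (norf_id, group); each planted HAR is
    placed within the +/-har_window association window of its nORF.
    ``planted_te_pairs`` lists nORF ids; each planted TE lies inside the
    2 kb upstream window without touching the nORF. Decoys are placed far
    from every nORF. The group mix follows the curated unique-HAR
    composition (vHAR/mHAR/pHAR = 45.4/11.0/43.6%).
    """
    rng = np.random.default_rng(seed)
    by_id = {n.norf_id: n for n in norfs}
    truth = SimulationTruth()
    har_rows, te_rows = [], []
    groups = ("vHAR", "mHAR", "pHAR")
    hi = 0
    for norf_id, group in planted_har_pairs or []:
        norf = by_id[norf_id]
        span = norf.span
        hi += 1
        har_id = f"har_{hi:04d}"
        gap = int(rng.integers(1000, har_window - 5000))
        size = int(rng.integers(200, 800))
        if rng.random() < 0.5 and span.start - gap - size > 0:
            s = span.start - gap - size
        else:
            s = span.end + gap
        har_rows.append((span.chrom, s, s + size, har_id, sources[hi % len(sources)], group))
        truth.norf_har_pairs.add((norf_id, har_id))
    # decoy HARs: far beyond every gene/nORF
    far = {c: CHROM_LENGTHS[c] - 8_000_000 for c in ("chrS1", "chrS2")}
    for d in range(max(0, n_hars - hi)):
        hi += 1
        chrom = "chrS1" if d % 2 == 0 else "chrS2"
        s = far[chrom] + d * 9000 + int(rng.integers(0, 4000))
        size = int(rng.integers(200, 800))
        group = groups[rng.choice(3, p=np.array(har_group_mix) / sum(har_group_mix))]
        har_rows.append((chrom, s, s + size, f"har_{hi:04d}", sources[hi % len(sources)], group))
    ti = 0
    for norf_id in planted_te_pairs or []:
        norf = by_id[norf_id]
        span = norf.span
        ti += 1
        te_id = f"te_{ti:04d}"
        size = int(rng.integers(150, 600))
        if size >= te_upstream:
            size = te_upstream - 50
        off = int(rng.integers(0, te_upstream - size))
        if norf.strand == "+":
            s = span.start - te_upstream + off
            if s < 0:
                truth.skipped_plants.append((norf_id, "te_at_contig_edge"))
                warnings.warn(f"cannot place upstream TE for {norf_id}")
                continue
            e = min(s + size, span.start)
        else:
            s = span.end + off
            e = s + size
        te_rows.append((span.chrom, s, e, te_id, "L1MC2", "LINE", "Eutheria"))
        truth.norf_te_pairs.add((norf_id, te_id))
    for d in range(max(0, n_tes - ti)):
        ti += 1
        chrom = "chrS1" if d % 2 == 0 else "chrS2"
        s = far[chrom] + 4_000_000 + d * 7000 + int(rng.integers(0, 3000))
        size = int(rng.integers(150, 600))
        fam = ["AluJo", "MIRb", "MER65A", "L1MC2"][d % 4]
        cls = {"AluJo": "SINE", "MIRb": "SINE", "MER65A": "LTR", "L1MC2": "LINE"}[fam]
        te_rows.append((chrom, s, s + size, f"te_{ti:04d}", fam, cls, "Primates"))
    hars = pd.DataFrame(
        har_rows, columns=["chrom", "start", "end", "name", "source", "group"]
    )
    hars.insert(4, "score", 0)
    hars.insert(5, "strand", ".")
    tes = pd.DataFrame(
        te_rows, columns=["chrom", "start", "end", "name", "family", "class", "clade"]
    )
    tes.insert(4, "score", 0)
    tes.insert(5, "strand", ".")
    return hars, tes, truth


# ---------------------------------------------------------------------------
# GWAS summary statistics with block LD


def generate_gwas(
    seed: int,
    n_snps: int = 2000,
    block_size: int = 10,
    causal_loci: Optional[Sequence[GenomicInterval]] = None,
    chroms: Sequence[str] = ("chrS1", "chrS2"),
    within_block_r2: tuple[float, float] = (0.6, 0.99),
    causal_neglogp: tuple[float, float] = (5.0, 9.0),
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """SNP summary-statistic and sparse r2 tables in an LD-block structure.

    SNPs are evenly spread over the chromosomes in blocks of ``block_size``
    consecutive SNPs; within-block pairs get high r2, between-block pairs
    r2 = 0 (omitted from the sparse table). Association p values are
    Uniform(0,1) except inside planted causal loci, where -log10 p is drawn
    from ``causal_neglogp``. MAF and HWE columns include values below the QC
    thresholds so the QC stage has work to do.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rng = np.random.default_rng(seed)
    causal_loci = list(causal_loci or [])
    per_chrom = n_snps // len(chroms)
    rows = []
    idx = 0
    for chrom in chroms:
        length = CHROM_LENGTHS[chrom]
        positions = np.linspace(100_000, length - 100_000, per_chrom).astype(int)
        for p1 in positions:
            idx += 1
            rows.append((f"rs{idx:06d}", chrom, int(p1)))
    snps = pd.DataFrame(rows, columns=["rsid", "chrom", "pos"])
    for iv in causal_loci:
        inside = (
            (snps["chrom"] == iv.chrom)
            & (snps["pos"] - 1 >= iv.start)
            & (snps["pos"] - 1 < iv.end)
        )
        if not inside.any():
            raise ValueError(f"causal locus {iv} contains no SNPs")
    pvals = rng.uniform(0, 1, size=len(snps))
    for iv in causal_loci:
        inside = (
            (snps["chrom"] == iv.chrom)
            & (snps["pos"] - 1 >= iv.start)
            & (snps["pos"] - 1 < iv.end)
        ).to_numpy()
        pvals[inside] = 10.0 ** (
            -rng.uniform(causal_neglogp[0], causal_neglogp[1], size=int(inside.sum()))
        )
    snps["p"] = pvals
    maf = rng.uniform(0.05, 0.5, size=len(snps))
    low = rng.random(len(snps)) < 0.05
    maf[low] = rng.uniform(0.005, 0.0499, size=int(low.sum()))
    snps["maf"] = np.round(maf, 4)
    hwe = rng.uniform(0, 1, size=len(snps))
    bad = rng.random(len(snps)) < 0.02
    hwe[bad] = rng.uniform(1e-8, 9e-5, size=int(bad.sum()))
    snps["hwe_p"] = hwe

    ld_rows = []
    n = len(snps)
    for b0 in range(0, n, block_size):
        block = snps.iloc[b0 : b0 + block_size]
        if block["chrom"].nunique() > 1:
            # blocks never span chromosomes
            block = block[block["chrom"] == block["chrom"].iloc[0]]
        ids = list(block["rsid"])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                r2 = float(rng.uniform(*within_block_r2))
                ld_rows.append((ids[i], ids[j], round(r2, 4)))
    ld = pd.DataFrame(ld_rows, columns=["rsid_a", "rsid_b", "r2"])
    truth = SimulationTruth(causal_loci=causal_loci)
    return snps, ld, truth
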