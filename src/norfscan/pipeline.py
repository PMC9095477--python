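"""Config-driven orchestration of the full analysis on one input set.

Stages: nORF curation (Ribo-seq noise filter, frame classification,
deduplication) -> transcribed-nORF identification (TPM filter, PAR removal,
transcript matching) -> TMM/mixed-model differential expression -> HAR/TE
association and DE designation -> GWAS locus construction and permutation
enrichment. Every output file lands in the manifest with a content hash;
a single global seed fans out to per-stage seeds by stable hashing of the
stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import association, curation, diffexp, io as nio, loci as loci_mod, matching, simulate
from .core import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs, thresholds and the global seed for one pipeline run.

    Threshold defaults are the analysis' standard values: TPM > 0.1 in >= 10% of
    samples, FDR < 0.05, +/-100 kb HAR window (1 kb sensitivity variant),
    2 kb TE upstream window, p-value strata 1e-2..1e-7, 5000 permutations,
    4000 noise-filter quantiles.
    """

    annotation: str = ""
    norfs: str = ""
    riboseq_counts: str = ""
    riboseq_lengths: str = ""
    riboseq_canonical: str = ""
    rnaseq_counts: str = ""
    metadata: str = ""
    hars: str = ""
    tes: str = ""
    snps: str = ""
    ld: str = ""
    out_dir: str = "results"
    seed: int = 0
    tpm_min: float = 0.1
    sample_frac: float = 0.10
    q_threshold: float = 0.05
    har_window: int = 100_000
    te_upstream: int = 2000
    noise_q: int = 4000
    n_perm: int = 5000
    strata: tuple = loci_mod.DEFAULT_STRATA
    covariates: tuple = ("age",)
    cases: tuple = ("SCZ", "BD")
    mhc_chrom: str = "chr6"
    mhc_start: int = 28_477_796
    mhc_end: int = 33_448_354
    stages: tuple = ("curation", "matching", "diffexp", "association", "loci")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("strata", "covariates", "cases", "stages"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key in ("strata", "covariates", "cases", "stages"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


_INPUT_FIELDS = (
    "annotation", "norfs", "riboseq_counts", "riboseq_lengths",
    "riboseq_canonical", "rnaseq_counts", "metadata", "hars", "tes",
    "snps", "ld",
)

_STAGE_DEPS = {
    "matching": (),
    "diffexp": ("matching",),
    "association": ("matching", "diffexp"),
    "loci": ("matching", "association"),
    "curation": (),
}


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect (not fail-fast) every configuration error."""
    errors = []
    for f in _INPUT_FIELDS:
        p = getattr(config, f)
        if p and not Path(p).exists():
            errors.append(f"{f}: input path does not exist: {p}")
        if not p and _field_required(config, f):
            errors.append(f"{f}: path required by enabled stages")
    if config.tpm_min < 0:
        errors.append("tpm_min: must be >= 0")
    if not (0 <= config.sample_frac <= 1):
        errors.append("sample_frac: must lie in [0, 1]")
    if not (0 < config.q_threshold < 1):
        errors.append("q_threshold: must lie in (0, 1)")
    if config.har_window < 0:
        errors.append("har_window: must be >= 0")
    if config.te_upstream <= 0:
        errors.append("te_upstream: must be > 0")
    if config.noise_q < 1:
        errors.append("noise_q: must be >= 1")
    if config.n_perm < 1:
        errors.append("n_perm: must be >= 1")
    if list(config.strata) != sorted(config.strata, reverse=True):
        errors.append("strata: must be sorted descending")
    for stage in config.stages:
        for dep in _STAGE_DEPS.get(stage, ()):
            if dep not in config.stages:
                errors.append(f"stages: {stage} requires {dep}")
    return errors


def _field_required(config: PipelineConfig, f: str) -> bool:
    need = {
        "curation": ("riboseq_counts", "riboseq_lengths", "riboseq_canonical", "annotation", "norfs"),
        "matching": ("annotation", "norfs", "rnaseq_counts"),
        "diffexp": ("rnaseq_counts", "metadata"),
        "association": ("hars", "tes"),
        "loci": ("snps", "ld"),
    }
    return any(f in need[s] for s in config.stages if s in need)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: order changes do not reshuffle randomness."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; return the manifest."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str):
        path = out / name
        nio.write_tsv(df, path)
        written.append(path)
        return path

    transcripts = nio.read_gtf(config.annotation)
    norfs = nio.read_norf_bed12(config.norfs)
    tx_lengths = pd.Series(
        {t.transcript_id: t.exonic_length() for t in transcripts}
    )

    # ---- curation -------------------------------------------------------
    if "curation" in config.stages:
        rb_counts = nio.read_expression_tsv(config.riboseq_counts, unit="count")
        rb_lengths = pd.read_csv(config.riboseq_lengths, sep="\t", index_col=0).iloc[:, 0]
        canon = pd.read_csv(config.riboseq_canonical, sep="\t", index_col=0).iloc[:, 0].astype(bool)
        tpm = curation.counts_to_tpm(rb_counts, rb_lengths)
        q = config.noise_q
        n_orfs = tpm.values.shape[0]
        if q > n_orfs:
            warnings.warn(f"noise_q={q} exceeds {n_orfs} ORFs; capping")
            q = n_orfs
        noise = curation.low_noise_filter(tpm, canon, q=q)
        save(noise.table, "noise_filter.tsv")
        classified = curation.classify_norfs(norfs, transcripts)
        kept = curation.apply_inframe_removal(classified)
        deduped, aliases = curation.deduplicate_norfs(kept)
        bed_path = out / "curated_norfs.bed"
        nio.write_norf_bed12(deduped, bed_path)
        written.append(bed_path)
        save(
            pd.DataFrame(
                [(n.norf_id, n.frame_class, n.category) for n in deduped],
                columns=["norf_id", "frame_class", "category"],
            ),
            "curated_norfs.tsv",
        )
        norfs = deduped

    # ---- matching -------------------------------------------------------
    matches = []
    retained = []
    rn_counts = nio.read_expression_tsv(config.rnaseq_counts, unit="count")
    if "matching" in config.stages:
        rn_tpm = curation.counts_to_tpm(rn_counts, tx_lengths)
        retained = matching.expression_filter(
            rn_tpm, tpm_min=config.tpm_min, sample_frac=config.sample_frac
        )
        transcripts_nopar = matching.remove_par_features(transcripts)
        matches = matching.match_norfs(norfs, transcripts_nopar, retained)
        save(matching.matches_to_frame(matches), "norf_matches.tsv")
        save(matching.biotype_composition(matches), "biotype_composition.tsv")

    # ---- diffexp --------------------------------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    de_norf_tables: dict[str, pd.DataFrame] = {}
    if "diffexp" in config.stages:
        meta = nio.read_metadata_tsv(config.metadata)
        factors = diffexp.tmm_factors(rn_counts)
        logcpm = diffexp.log_cpm(rn_counts, factors)
        chry = [t.transcript_id for t in transcripts if t.chrom in ("chrY", "chrSY")]
        if chry:
            qc = diffexp.sex_qc(
                logcpm, meta, chry, "XIST" if "XIST" in logcpm.feature_ids else None
            )
            save(qc, "sex_qc.tsv")
        summary_rows = []
        fisher_rows = []
        for case in config.cases:
            de = diffexp.run_diffexp(
                logcpm, meta, case=case, covariates=config.covariates
            )
            de_tables[case] = de
            save(de, f"de_{case}.tsv")
            dn = diffexp.de_norfs(de, matches, q_threshold=config.q_threshold)
            de_norf_tables[case] = dn
            save(dn, f"de_norfs_{case}.tsv")
            sig = de[de["qvalue"] < config.q_threshold]
            summary_rows.append(
                (
                    f"{case}/CNT", len(sig),
                    int((sig["effect"] > 0).sum()), int((sig["effect"] < 0).sum()),
                    len(dn),
                )
            )
            with_norf = {m.transcript_id for m in matches}
            tested = de[de["pvalue"].notna()]
            is_de = tested["qvalue"] < config.q_threshold
            has_norf = tested["transcript_id"].isin(with_norf)
            a = int((is_de & has_norf).sum())
            b = int((is_de & ~has_norf).sum())
            c = int((~is_de & has_norf).sum())
            d = int((~is_de & ~has_norf).sum())
            try:
                oddsr, fp = diffexp.fisher_enrichment(a, b, c, d)
            except ValueError:
                oddsr, fp = np.nan, np.nan
            fisher_rows.append((case, a, b, c, d, oddsr, fp))
        save(
            pd.DataFrame(
                summary_rows,
                columns=["condition", "n_de", "n_up", "n_down", "n_de_norfs"],
            ),
            "de_summary.tsv",
        )
        save(
            pd.DataFrame(
                fisher_rows,
                columns=["case", "de_with_norf", "de_without", "nonde_with_norf", "nonde_without", "odds_ratio", "p"],
            ),
            "fisher_enrichment.tsv",
        )
        common = diffexp.de_norf_intersection(de_norf_tables)
        save(pd.DataFrame(common, columns=["norf_id"]), "de_norfs_common.tsv")

    # ---- association ----------------------------------------------------
    har_pairs = []
    norf_by_id = {n.norf_id: n for n in norfs}
    matched_norf_ids = sorted({m.norf_id for m in matches})
    transcribed = [norf_by_id[i] for i in matched_norf_ids if i in norf_by_id]
    uhars = []
    if "association" in config.stages:
        har_df = nio.read_bed(config.hars, extra_columns=("source", "group"))
        te_df = nio.read_bed(config.tes, extra_columns=("family", "class", "clade"))
        uhars = association.build_unique_hars(har_df)
        save(association.unique_har_summary(uhars), "unique_har_summary.tsv")
        har_pairs = association.associate_norf_har(
            transcribed, uhars, window=config.har_window
        )
        te_pairs = association.associate_norf_te(
            transcribed, te_df, upstream_size=config.te_upstream
        )
        save(
            pd.DataFrame(
                [(p.norf_id, p.feature_id, p.relation, p.distance) for p in har_pairs],
                columns=["norf_id", "feature_id", "relation", "distance"],
            ),
            "norf_har_pairs.tsv",
        )
        save(
            pd.DataFrame(
                [(p.norf_id, p.feature_id, p.relation, p.distance) for p in te_pairs],
                columns=["norf_id", "feature_id", "relation", "distance"],
            ),
            "norf_te_pairs.tsv",
        )
        if de_tables:
            tx_by_id = {t.transcript_id: t for t in transcripts}
            for case, de in de_tables.items():
                de_tx = [
                    tx_by_id[t]
                    for t in de.loc[de["qvalue"] < config.q_threshold, "transcript_id"]
                    if t in tx_by_id
                ]
                har_bed = pd.DataFrame(
                    [
                        (h.interval.chrom, h.interval.start, h.interval.end, h.har_id)
                        for h in uhars
                    ],
                    columns=["chrom", "start", "end", "name"],
                )
                save(
                    association.designate_de_features(har_bed, de_tx),
                    f"de_hars_{case}.tsv",
                )
                save(
                    association.designate_de_features(te_df, de_tx),
                    f"de_tes_{case}.tsv",
                )

    # ---- loci + enrichment ----------------------------------------------
    if "loci" in config.stages:
        snps = pd.read_csv(config.snps, sep="\t")
        ld = loci_mod.LdTable(pd.read_csv(config.ld, sep="\t"))
        mhc = GenomicInterval(config.mhc_chrom, config.mhc_start, config.mhc_end)
        loci_by_stratum = loci_mod.loci_for_strata(
            snps, ld, bounds=tuple(config.strata), mhc=mhc
        )
        save(
            pd.DataFrame(
                [
                    (b, lc.interval.chrom, lc.interval.start, lc.interval.end, lc.index_rsid)
                    for b, lcs in loci_by_stratum.items()
                    for lc in lcs
                ],
                columns=["stratum", "chrom", "start", "end", "index_rsid"],
            ),
            "loci.tsv",
        )
        # reference: expressed (matched) autosomal nORFs
        reference = [
            (n.norf_id, n.span)
            for n in transcribed
            if n.chrom not in ("chrX", "chrY", "chrSY")
        ]
        ref_ids = {n for n, _ in reference}
        har_assoc_ids = sorted({p.norf_id for p in har_pairs if p.norf_id in ref_ids})
        group_of = {h.har_id: h.group_set for h in uhars}
        target_sets = {"nORF-HAR": har_assoc_ids}
        for g in association.HAR_GROUPS:
            target_sets[f"nORF-{g}"] = sorted(
                {
                    p.norf_id
                    for p in har_pairs
                    if p.norf_id in ref_ids and g in group_of.get(p.feature_id, ())
                }
            )
        target_sets = {k: v for k, v in target_sets.items() if v}
        if target_sets and any(loci_by_stratum.values()):
            enr = loci_mod.enrichment_scan(
                target_sets,
                reference,
                loci_by_stratum,
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, "loci"),
            )
            save(enr, "enrichment.tsv")

    manifest = {
        "seed": config.seed,
        "thresholds": {
            "tpm_min": config.tpm_min,
            "sample_frac": config.sample_frac,
            "q_threshold": config.q_threshold,
            "har_window": config.har_window,
            "te_upstream": config.te_upstream,
            "noise_q": config.noise_q,
            "n_perm": config.n_perm,
        },
        "outputs": {p.name: _hash_file(p) for p in sorted(written)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Scenario simulation (writes every pipeline input + truth)


@dataclass
class Scenario:
    """Parameters of one synthetic study; defaults are the study conditions
    at desk scale."""

    seed: int = 0
    n_genes: int = 60
    exons_per_gene: int = 3
    n_cnt: int = 40
    n_scz: int = 30
    n_bd: int = 20
    de_fraction: float = 0.2
    lfc_range: tuple = (1.0, 2.0)
    nb_dispersion: float = 0.2
    intercept_sd: float = 0.3
    n_riboseq_samples: int = 50
    n_planted_phar: int = 8
    n_planted_other_har: int = 4
    n_planted_te: int = 6
    n_decoy_hars: int = 40
    n_decoy_tes: int = 40
    n_snps: int = 3000
    ld_block_size: int = 8
    noise_q: int = 25  # one bin per Ribo-seq mean-grid point

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "lfc_range" in data:
            data["lfc_range"] = tuple(data["lfc_range"])
        return cls(**data)


def simulate_scenario(scenario: Scenario, out_dir) -> tuple[PipelineConfig, simulate.SimulationTruth]:
    """Generate every pipeline input for a scenario; write truth alongside.

    Planted structure: pHAR-associated nORFs sit inside planted causal GWAS
    loci (the enrichment signal); vHAR/mHAR plants and upstream TEs go to
    other nORFs; decoy HARs/TEs are far from every nORF.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = scenario
    transcripts = simulate.generate_annotation(
        stage_seed(s.seed, "annotation"), n_genes=s.n_genes, exons_per_gene=s.exons_per_gene
    )
    norfs, host_of = simulate.generate_norfs(stage_seed(s.seed, "norfs"), transcripts)
    nio.write_gtf(transcripts, out / "annotation.gtf")
    nio.write_norf_bed12(norfs, out / "norfs.bed")

    rb_counts, rb_lengths, rb_canon, rb_truth = simulate.generate_riboseq_counts(
        stage_seed(s.seed, "riboseq"), n_samples=s.n_riboseq_samples
    )
    rb_counts.to_csv(out / "riboseq_counts.tsv", sep="\t", index_label="orf_id")
    rb_lengths.rename("length").to_frame().to_csv(
        out / "riboseq_lengths.tsv", sep="\t", index_label="orf_id"
    )
    rb_canon.rename("canonical").to_frame().to_csv(
        out / "riboseq_canonical.tsv", sep="\t", index_label="orf_id"
    )

    # force DE on the host transcripts of planted pHAR nORFs so the
    # DE -> HAR -> locus chain carries signal end to end
    rng = np.random.default_rng(stage_seed(s.seed, "planting"))
    contained = [n for n in norfs if n.norf_id in host_of]
    contained_ids = [n.norf_id for n in contained]
    n_phar = min(s.n_planted_phar, len(contained_ids))
    phar_norfs = list(rng.choice(contained_ids, size=n_phar, replace=False))
    rest = [i for i in contained_ids if i not in set(phar_norfs)]
    n_other = min(s.n_planted_other_har, len(rest))
    other_har_norfs = list(rng.choice(rest, size=n_other, replace=False))
    rest2 = [i for i in rest if i not in set(other_har_norfs)]
    n_te = min(s.n_planted_te, len(rest2))
    te_norfs = list(rng.choice(rest2, size=n_te, replace=False))

    counts, meta, cc_truth = simulate.generate_case_control_counts(
        stage_seed(s.seed, "rnaseq"),
        transcripts,
        n_cnt=s.n_cnt,
        n_scz=s.n_scz,
        n_bd=s.n_bd,
        de_fraction=s.de_fraction,
        lfc_range=tuple(s.lfc_range),
        nb_dispersion=s.nb_dispersion,
        intercept_sd=s.intercept_sd,
    )
    counts.to_csv(out / "rnaseq_counts.tsv", sep="\t", index_label="transcript_id")
    nio.write_tsv(meta, out / "metadata.tsv")

    planted_har_pairs = [(n, "pHAR") for n in phar_norfs]
    for i, n in enumerate(other_har_norfs):
        planted_har_pairs.append((n, "vHAR" if i % 2 == 0 else "mHAR"))
    hars, tes, feat_truth = simulate.generate_features(
        stage_seed(s.seed, "features"),
        norfs,
        n_hars=len(planted_har_pairs) + s.n_decoy_hars,
        n_tes=n_te + s.n_decoy_tes,
        planted_har_pairs=planted_har_pairs,
        planted_te_pairs=te_norfs,
    )
    nio.write_bed(hars, out / "hars.bed")
    nio.write_bed(tes, out / "tes.bed")

    norf_by_id = {n.norf_id: n for n in norfs}
    causal = [
        GenomicInterval(
            norf_by_id[nid].chrom,
            max(0, norf_by_id[nid].span.start - 40_000),
            norf_by_id[nid].span.end + 40_000,
        )
        for nid in phar_norfs
    ]
    snps, ld, gwas_truth = simulate.generate_gwas(
        stage_seed(s.seed, "gwas"),
        n_snps=s.n_snps,
        block_size=s.ld_block_size,
        causal_loci=causal,
    )
    nio.write_tsv(snps, out / "snps.tsv", float_format="%.8g")
    nio.write_tsv(ld, out / "ld.tsv")

    truth = simulate.SimulationTruth(
        de_transcripts=cc_truth.de_transcripts,
        low_noise_norfs=rb_truth.low_noise_norfs,
        norf_har_pairs=feat_truth.norf_har_pairs,
        norf_te_pairs=feat_truth.norf_te_pairs,
        causal_loci=causal,
        causal_target_norfs=set(phar_norfs),
        norf_transcript=host_of,
        skipped_plants=feat_truth.skipped_plants,
        intercept_sd=s.intercept_sd,
        nb_dispersion=s.nb_dispersion,
    )
    truth.write(out)

    config = PipelineConfig(
        annotation=str(out / "annotation.gtf"),
        norfs=str(out / "norfs.bed"),
        riboseq_counts=str(out / "riboseq_counts.tsv"),
        riboseq_lengths=str(out / "riboseq_lengths.tsv"),
        riboseq_canonical=str(out / "riboseq_canonical.tsv"),
        rnaseq_counts=str(out / "rnaseq_counts.tsv"),
        metadata=str(out / "metadata.tsv"),
        hars=str(out / "hars.bed"),
        tes=str(out / "tes.bed"),
        snps=str(out / "snps.tsv"),
        ld=str(out / "ld.tsv"),
        out_dir=str(out / "results"),
        seed=s.seed,
        noise_q=s.noise_q,
        mhc_chrom="chrS1",
        mhc_start=0,
        mhc_end=1,  # synthetic panel has no MHC; degenerate interval
    )
    config.to_yaml(out / "config.yaml")
    return config, truth


def score_against_truth(truth_dir, results_dir) -> pd.DataFrame:
    """Compare pipeline outputs with the planted truth of a scenario."""
    truth_dir, results_dir = Path(truth_dir), Path(results_dir)
    rows = []

    t_har = pd.read_csv(truth_dir / "truth_norf_har.tsv", sep="\t")
    got = pd.read_csv(results_dir / "norf_har_pairs.tsv", sep="\t")
    planted = set(map(tuple, t_har.values))
    found = set(zip(got["norf_id"], got["feature_id"]))
    # planted ids refer to source HARs; match on nORF id (unique HARs are renamed)
    norf_recall = (
        len({n for n, _ in planted} & {n for n, _ in found}) / len({n for n, _ in planted})
        if planted
        else np.nan
    )
    rows.append(("norf_har_recall", norf_recall))

    t_te = pd.read_csv(truth_dir / "truth_norf_te.tsv", sep="\t")
    got_te = pd.read_csv(results_dir / "norf_te_pairs.tsv", sep="\t")
    planted_te = set(zip(t_te["norf_id"], t_te["te_id"]))
    found_te = set(zip(got_te["norf_id"], got_te["feature_id"]))
    rows.append(
        ("norf_te_recall", len(planted_te & found_te) / len(planted_te) if planted_te else np.nan)
    )

    t_de = pd.read_csv(truth_dir / "truth_de_transcripts.tsv", sep="\t")
    for case in t_de["case"].unique():
        de_path = results_dir / f"de_{case}.tsv"
        if not de_path.exists():
            continue
        de = pd.read_csv(de_path, sep="\t")
        called = set(de.loc[de["qvalue"] < 0.05, "transcript_id"])
        planted_set = set(t_de.loc[t_de["case"] == case, "transcript_id"])
        tp = len(called & planted_set)
        rows.append((f"de_sensitivity_{case}", tp / len(planted_set) if planted_set else np.nan))
        rows.append((f"de_fdr_{case}", (len(called) - tp) / len(called) if called else 0.0))

    enr_path = results_dir / "enrichment.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t")
        phar = enr[enr["target_set"] == "nORF-pHAR"]
        if len(phar):
            rows.append(("phar_min_empirical_p", float(phar["empirical_p"].min())))
    return pd.DataFrame(rows, columns=["metric", "value"])
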