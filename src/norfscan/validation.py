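"""Calibration and planted-truth recovery experiments.

Each function runs a self-contained simulation experiment against the
package's own estimators: null calibration of the mixed-model and
permutation-enrichment p values, recovery of planted fold changes and DE
transcripts, power and null behaviour of the dual correlation screen, and
the end-to-end chain from planted pHAR-associated nORFs to GWAS-locus
enrichment. Problem sizes are desk-scale defaults chosen to give stable
Monte-Carlo estimates.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GenomicInterval
from .association import (
    associate_norf_har,
    associate_norf_te,
    build_unique_hars,
    correlate_pairs,
)
from .diffexp import fit_mixed_model, log_cpm, run_diffexp, tmm_factors
from .loci import LdTable, Locus, interval_enrichment, loci_for_strata
from .simulate import (
    generate_annotation,
    generate_case_control_counts,
    generate_features,
    generate_gwas,
    generate_norfs,
)


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.default_rng([seed, k]).integers(0, 2**31 - 1))


def mixed_model_null_pvalues(
    seed: int,
    n_reps: int = 250,
    n_individuals: int = 50,
    samples_per_individual: int = 2,
    intercept_sd: float = 0.3,
) -> np.ndarray:
    """Diagnosis-contrast p values under the null (no effect)."""
    rng = np.random.default_rng(seed)
    n = n_individuals * samples_per_individual
    groups = np.repeat(np.arange(n_individuals), samples_per_individual)
    ps = np.empty(n_reps)
    for r in range(n_reps):
        x = rng.binomial(1, 0.5, n_individuals)[groups].astype(float)
        y = (
            rng.normal(0, intercept_sd, n_individuals)[groups]
            + rng.normal(0, 1.0, n)
        )
        design = pd.DataFrame({"intercept": np.ones(n), "diagnosis": x})
        ps[r] = fit_mixed_model(y, design, groups, "diagnosis").pvalue
    return ps


def effect_recovery(
    seed: int,
    n_reps: int = 200,
    effect: float = 1.0,
    n_individuals: int = 100,
    samples_per_individual: int = 2,
    intercept_sd: float = 0.3,
) -> np.ndarray:
    """Mixed-model estimates of a planted diagnosis effect."""
    rng = np.random.default_rng(seed)
    n = n_individuals * samples_per_individual
    groups = np.repeat(np.arange(n_individuals), samples_per_individual)
    estimates = np.empty(n_reps)
    for r in range(n_reps):
        x = rng.binomial(1, 0.5, n_individuals)[groups].astype(float)
        y = (
            effect * x
            + rng.normal(0, intercept_sd, n_individuals)[groups]
            + rng.normal(0, 0.7, n)
        )
        design = pd.DataFrame({"intercept": np.ones(n), "diagnosis": x})
        estimates[r] = fit_mixed_model(y, design, groups, "diagnosis").effect
    return estimates


def de_recovery(seed: int, n_genes: int = 150) -> dict:
    """Planted-DE recovery through TMM -> logCPM -> mixed model -> BH."""
    transcripts = generate_annotation(_sub_seed(seed, 1), n_genes=n_genes)
    counts, meta, truth = generate_case_control_counts(
        _sub_seed(seed, 2), transcripts, n_cnt=40, n_scz=30, n_bd=0,
        de_fraction=0.2, lfc_range=(1.0, 2.0),
    )
    m = ExpressionMatrix(counts.astype(float), "count")
    lc = log_cpm(m, tmm_factors(m))
    de = run_diffexp(lc, meta, case="SCZ", covariates=("age",))
    called = set(de.loc[de["qvalue"] < 0.05, "transcript_id"])
    planted = set(truth.de_transcripts["SCZ"])
    tp = len(called & planted)
    est = dict(zip(de["transcript_id"], de["effect"]))
    planted_bias = float(
        np.mean([est[t] - lfc for t, lfc in truth.de_transcripts["SCZ"].items()])
    )
    return {
        "sensitivity": tp / len(planted) if planted else np.nan,
        "fdr": (len(called) - tp) / len(called) if called else 0.0,
        "n_called": len(called),
        "n_planted": len(planted),
        "lfc_bias": planted_bias,
    }


def _random_geometry(rng, n_ref=300, n_loci=80, n_targets=60):
    """Random reference spans and loci with no planted association.

    Sizes keep the null statistic fine-grained: with few loci the count of
    target-overlapping loci has large atoms and the (valid, mildly
    conservative) permutation p values become visibly lumpy.
    """
    ref = []
    pos = 100_000
    for i in range(n_ref):
        pos += int(rng.integers(40_000, 120_000))
        ref.append((f"n{i}", GenomicInterval("chr1", pos, pos + 2000)))
    span_end = pos + 100_000
    loci = []
    for j in range(n_loci):
        s = int(rng.integers(100_000, span_end))
        loci.append(
            Locus(GenomicInterval("chr1", s, s + int(rng.integers(20_000, 200_000))),
                  index_rsid=f"idx{j}", stratum=1e-4)
        )
    target_ids = [f"n{i}" for i in rng.choice(n_ref, size=n_targets, replace=False)]
    return ref, loci, target_ids


def enrichment_null_pvalues(
    seed: int, n_runs: int = 200, n_perm: int = 300
) -> np.ndarray:
    """Empirical enrichment p under a fully random geometry per run."""
    rng = np.random.default_rng(seed)
    ps = np.empty(n_runs)
    for r in range(n_runs):
        ref, loci, target_ids = _random_geometry(rng)
        res = interval_enrichment(
            target_ids, ref, loci, n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ps[r] = res.empirical_p
    return ps


def correlation_screen_rates(
    seed: int, rho: float = 0.8, n: int = 60, n_reps: int = 100
) -> tuple[float, float]:
    """(planted flag rate, null flag rate) of the dual correlation gate."""
    rng = np.random.default_rng(seed)
    planted_hits = null_hits = 0
    for _ in range(n_reps):
        x = rng.normal(0, 1, n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)
        m = ExpressionMatrix(
            pd.DataFrame({"norf": x, "te": y, "null_te": z}).T, "logCPM"
        )
        res = correlate_pairs(m, [("norf", "te"), ("norf", "null_te")])
        planted_hits += res[0].significant
        null_hits += res[1].significant
    return planted_hits / n_reps, null_hits / n_reps


def har_te_recall(seed: int, n_genes: int = 40) -> tuple[float, float]:
    """Recall of planted nORF-HAR and nORF-TE pairs at the stated windows."""
    transcripts = generate_annotation(_sub_seed(seed, 3), n_genes=n_genes)
    norfs, _ = generate_norfs(_sub_seed(seed, 4), transcripts)
    ids = [n.norf_id for n in norfs]
    k = min(8, len(ids) // 2)
    hars, tes, truth = generate_features(
        _sub_seed(seed, 5), norfs,
        planted_har_pairs=[(i, "pHAR") for i in ids[:k]],
        planted_te_pairs=ids[k : 2 * k],
    )
    uhars = build_unique_hars(hars[["chrom", "start", "end", "name", "source", "group"]])
    har_pairs = associate_norf_har(norfs, uhars, window=100_000)
    te_pairs = associate_norf_te(norfs, tes, upstream_size=2000)
    planted_har_norfs = {n for n, _ in truth.norf_har_pairs}
    har_recall = (
        len(planted_har_norfs & {p.norf_id for p in har_pairs}) / len(planted_har_norfs)
        if planted_har_norfs else np.nan
    )
    te_recall = (
        len(truth.norf_te_pairs & {(p.norf_id, p.feature_id) for p in te_pairs})
        / len(truth.norf_te_pairs)
        if truth.norf_te_pairs else np.nan
    )
    return har_recall, te_recall


def phar_decoy_enrichment(
    seed: int, n_genes: int = 40, n_planted: int = 8, n_perm: int = 500
) -> tuple[float, float]:
    """(pHAR-subset p, decoy-subset p) for one planted-locus scenario.

    pHAR-associated nORFs sit inside planted causal GWAS loci; the decoy
    subset is an equally sized random draw of non-planted nORFs.
    """
    transcripts = generate_annotation(_sub_seed(seed, 6), n_genes=n_genes)
    norfs, _ = generate_norfs(_sub_seed(seed, 7), transcripts)
    rng = np.random.default_rng(_sub_seed(seed, 8))
    ids = [n.norf_id for n in norfs]
    planted = list(rng.choice(ids, size=min(n_planted, len(ids)), replace=False))
    hars, _, _ = generate_features(
        _sub_seed(seed, 9), norfs,
        planted_har_pairs=[(i, "pHAR") for i in planted],
        n_tes=0,
    )
    by_id = {n.norf_id: n for n in norfs}
    causal = [
        GenomicInterval(
            by_id[i].chrom,
            max(0, by_id[i].span.start - 40_000),
            by_id[i].span.end + 40_000,
        )
        for i in planted
    ]
    snps, ld_df, _ = generate_gwas(
        _sub_seed(seed, 10), n_snps=1500, block_size=8, causal_loci=causal
    )
    ld = LdTable(ld_df)
    loci_by_stratum = loci_for_strata(
        snps, ld, bounds=(1e-4,), mhc=GenomicInterval("chrS1", 0, 1)
    )
    loci = loci_by_stratum[1e-4]
    reference = [(n.norf_id, n.span) for n in norfs]
    uhars = build_unique_hars(hars[["chrom", "start", "end", "name", "source", "group"]])
    har_pairs = associate_norf_har(norfs, uhars, window=100_000)
    phar_targets = sorted({p.norf_id for p in har_pairs})
    non_planted = [i for i in ids if i not in set(phar_targets)]
    decoy_targets = list(
        rng.choice(non_planted, size=min(len(phar_targets), len(non_planted)), replace=False)
    )
    p_phar = interval_enrichment(
        phar_targets, reference, loci, n_perm=n_perm, seed=_sub_seed(seed, 11)
    ).empirical_p
    p_decoy = interval_enrichment(
        decoy_targets, reference, loci, n_perm=n_perm, seed=_sub_seed(seed, 12)
    ).empirical_p
    return p_phar, p_decoy


def tmm_vs_edger_max_diff(seed: int, shape=(30, 6)) -> Optional[float]:
    """Max |difference| between package TMM factors and edgeR's, or None if
    Rscript/edgeR is unavailable."""
    import subprocess
    import tempfile
    from pathlib import Path

    rng = np.random.default_rng(seed)
    counts = rng.negative_binomial(5, 0.3, size=shape) + 1
    m = ExpressionMatrix(
        pd.DataFrame(
            counts,
            index=[f"g{i}" for i in range(shape[0])],
            columns=[f"s{j}" for j in range(shape[1])],
        ),
        "count",
    )
    ours = tmm_factors(m).factors.to_numpy()
    with tempfile.TemporaryDirectory() as td:
        csv = Path(td) / "counts.csv"
        pd.DataFrame(counts).to_csv(csv, index=False)
        try:
            out = subprocess.run(
                [
                    "Rscript", "-e",
                    f'suppressMessages(library(edgeR));'
                    f'x<-as.matrix(read.csv("{csv}"));'
                    f'cat(sprintf("%.12f ", calcNormFactors(x)))',
                ],
                capture_output=True, text=True, timeout=300,
            )
        except (OSError, subprocess.TimeoutExpired):
            return None
    if out.returncode != 0:
        return None
    theirs = np.array([float(v) for v in out.stdout.split()])
    return float(np.max(np.abs(ours - theirs)))
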