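"""Normalization and case/control differential expression.

Counts are scaled between samples with TMM (trimmed mean of M-values)
factors, transformed to log2(CPM + 0.5), and tested per transcript with a
linear model carrying a random intercept per individual — post-mortem brain
cohorts contribute several samples per donor, and ignoring that dependence
inflates the diagnosis test. Variance components are estimated by REML
profiled down to a one-dimensional search over the ratio of the intercept
variance to the residual variance; the diagnosis contrast is tested with a
Wald t statistic on residual degrees of freedom. p values are controlled at
FDR < 0.05 by Benjamini–Hochberg.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy

from .core import ExpressionMatrix, validate_metadata
from .matching import NorfTranscriptMatch

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# TMM normalization


@dataclass
class NormalizationFactors:
    factors: pd.Series
    lib_sizes: pd.Series

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    abs_trim: float,
    a_cutoff: float,
) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / n_obs) / (ref / n_ref))
        a = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / n_obs / obs + (n_ref - ref) / n_ref / ref
    fin = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: ExpressionMatrix,
    ref_sample: Optional[str] = None,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
    a_cutoff: float = -1e10,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper quartile of scaled counts is
    closest to the mean upper quartile. M (log ratio) and A (log abundance)
    are computed over features positive in both sample and reference, doubly
    trimmed (30% on M, 5% on A), and combined by a precision-weighted mean.
    """
    x = counts.values.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        bad = list(counts.values.columns[lib == 0])
        raise ValueError(f"samples with all-zero counts: {bad}")
    f75 = np.array(
        [np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])]
    )
    if ref_sample is None:
        if np.median(f75) < 1e-20:
            ref_idx = int(np.argmax(np.sqrt(x).sum(axis=0)))
        else:
            ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(counts.values.columns).index(ref_sample)
    f = np.array(
        [
            _tmm_pair(
                x[:, j], x[:, ref_idx], lib[j], lib[ref_idx],
                logratio_trim, abs_trim, a_cutoff,
            )
            for j in range(x.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    cols = counts.values.columns
    return NormalizationFactors(
        factors=pd.Series(f, index=cols), lib_sizes=pd.Series(lib, index=cols)
    )


def log_cpm(
    counts: ExpressionMatrix, factors: NormalizationFactors, prior: float = 0.5
) -> ExpressionMatrix:
    """log2(1e6 * count / effective library size + prior)."""
    eff = factors.effective_lib_sizes.reindex(counts.values.columns)
    if (eff <= 0).any():
        raise ValueError("effective library sizes must be positive")
    vals = np.log2(1e6 * counts.values.div(eff, axis=1) + prior)
    return ExpressionMatrix(values=vals, unit="logCPM")


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model (REML, profiled variance ratio)


@dataclass
class MixedFitResult:
    effect: float
    se: float
    pvalue: float
    sigma2_e: float
    sigma2_b: float
    converged: bool
    method: str  # "reml" or "ols"


def _reml_pieces(y, x, group_slices, lam):
    """GLS quantities for V = I + lam * ZZ' (block diagonal by group)."""
    n, p = x.shape
    # V^-1 w = w - sum_i lam/(1+lam*n_i) * 1_i 1_i' w
    def vinv(w):
        out = w.copy()
        for sl in group_slices:
            ni = sl.stop - sl.start
            out[sl] -= (lam / (1.0 + lam * ni)) * w[sl].sum(axis=0)
        return out

    xv = vinv(x)
    xvx = x.T @ xv
    xvy = xv.T @ y
    beta = np.linalg.solve(xvx, xvy)
    r = y - x @ beta
    rvr = float(r @ vinv(r))
    logdet_v = sum(
        np.log1p(lam * (sl.stop - sl.start)) for sl in group_slices
    )
    sign, logdet_xvx = np.linalg.slogdet(xvx)
    return beta, xvx, rvr, logdet_v + logdet_xvx


def _reml_criterion(y, x, group_slices, lam):
    n, p = x.shape
    _, _, rvr, logdets = _reml_pieces(y, x, group_slices, lam)
    return logdets + (n - p) * np.log(max(rvr, 1e-300))


def fit_mixed_model(
    y: np.ndarray,
    design: pd.DataFrame,
    groups: Sequence,
    contrast: str,
) -> MixedFitResult:
    """Fit y = X beta + b[individual] + e and Wald-test one coefficient.

    The REML log-likelihood is profiled over beta and the residual variance,
    leaving a 1-D minimization over lam = sigma_b^2 / sigma_e^2 >= 0. When
    every individual contributes a single sample the fit reduces exactly to
    ordinary least squares. The Wald test uses a t reference with
    n - rank(X) - 1 degrees of freedom.
    """
    x = design.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        # name aliased columns: those whose removal does not lower the rank
        aliased = [
            c
            for i, c in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(x, i, axis=1)) == rank
        ]
        raise ValueError(f"singular design; aliased columns: {aliased}")
    codes, _ = pd.factorize(np.asarray(groups))
    order = np.argsort(codes, kind="stable")
    y_s, x_s, codes_s = y[order], x[order], codes[order]
    boundaries = np.flatnonzero(np.diff(codes_s)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [n]])
    group_slices = [slice(int(a), int(b)) for a, b in zip(starts, stops)]
    if len(group_slices) < 2:
        raise ValueError("need at least 2 individuals")
    singleton = all(sl.stop - sl.start == 1 for sl in group_slices)

    method = "reml"
    converged = True
    if singleton:
        lam = 0.0
        method = "ols"
    else:
        try:
            res = optimize.minimize_scalar(
                lambda t: _reml_criterion(y_s, x_s, group_slices, np.expm1(t)),
                bounds=(0.0, np.log(1e4)),
                method="bounded",
                options={"xatol": 1e-8},
            )
            lam = float(np.expm1(res.x))
            if _reml_criterion(y_s, x_s, group_slices, 0.0) <= res.fun:
                lam = 0.0
            converged = bool(res.success)
        except (np.linalg.LinAlgError, FloatingPointError):
            lam, converged, method = 0.0, False, "ols"
            logger.warning("REML failed; falling back to OLS")

    beta, xvx, rvr, _ = _reml_pieces(y_s, x_s, group_slices, lam)
    sigma2_e = rvr / (n - p)
    cov_beta = sigma2_e * np.linalg.inv(xvx)
    ci = list(design.columns).index(contrast)
    effect = float(beta[ci])
    se = float(np.sqrt(cov_beta[ci, ci]))
    df = n - rank - 1
    if se == 0 or df <= 0:
        pvalue = np.nan
    else:
        pvalue = float(2.0 * stats.t.sf(abs(effect) / se, df))
    return MixedFitResult(
        effect=effect,
        se=se,
        pvalue=pvalue,
        sigma2_e=float(sigma2_e),
        sigma2_b=float(lam * sigma2_e),
        converged=converged,
        method=method,
    )


# ---------------------------------------------------------------------------
# Multiple testing and DE tables


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values.

    NaN entries propagate as NaN and do not count toward the number of
    tests.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


def build_design(
    metadata: pd.DataFrame,
    case: str,
    control: str = "CNT",
    covariates: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Design matrix (intercept + diagnosis indicator + covariates) for the
    case-vs-control subset; returns (design, metadata subset)."""
    sub = metadata[metadata["diagnosis"].isin([case, control])].copy()
    design = pd.DataFrame(index=sub.index)
    design["intercept"] = 1.0
    design["diagnosis"] = (sub["diagnosis"] == case).astype(float)
    for cov in covariates:
        col = sub[cov]
        if pd.api.types.is_numeric_dtype(col):
            design[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                design[c] = dummies[c]
    return design, sub


def run_diffexp(
    logcpm: ExpressionMatrix,
    metadata: pd.DataFrame,
    case: str,
    control: str = "CNT",
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-transcript mixed-model DE test of ``case`` against ``control``.

    Returns a table with effect (log2 scale), se, p, BH q and direction.
    Zero-variance transcripts are skipped and reported with NaN statistics.
    """
    meta = validate_metadata(metadata, logcpm.sample_ids)
    design, sub = build_design(meta, case, control, covariates)
    vals = logcpm.values[sub["sample_id"]]
    groups = sub["individual_id"].to_numpy()
    rows = []
    for tid, y in vals.iterrows():
        arr = y.to_numpy(dtype=float)
        if np.ptp(arr) == 0:
            rows.append((tid, np.nan, np.nan, np.nan, "none", "zero_variance"))
            continue
        fit = fit_mixed_model(arr, design, groups, "diagnosis")
        direction = "up" if fit.effect > 0 else "down"
        rows.append((tid, fit.effect, fit.se, fit.pvalue, direction, fit.method))
    out = pd.DataFrame(
        rows, columns=["transcript_id", "effect", "se", "pvalue", "direction", "method"]
    )
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out[["transcript_id", "effect", "se", "pvalue", "qvalue", "direction", "method"]]


def de_norfs(
    de_results: pd.DataFrame,
    matches: Sequence[NorfTranscriptMatch],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Map DE transcripts (q < threshold) to DE nORFs via the match table.

    Direction is inherited from the matched DE transcript; an nORF matched
    to DE transcripts in both directions is reported as "both" and logged.
    """
    de = de_results[de_results["qvalue"] < q_threshold]
    dirs = dict(zip(de["transcript_id"], de["direction"]))
    per_norf: dict[str, set] = {}
    tr_of: dict[str, set] = {}
    for m in matches:
        if m.transcript_id in dirs:
            per_norf.setdefault(m.norf_id, set()).add(dirs[m.transcript_id])
            tr_of.setdefault(m.norf_id, set()).add(m.transcript_id)
    rows = []
    for norf_id in sorted(per_norf):
        ds = per_norf[norf_id]
        if len(ds) > 1:
            logger.info("nORF %s matched DE transcripts in both directions", norf_id)
            direction = "both"
        else:
            direction = next(iter(ds))
        rows.append((norf_id, direction, ",".join(sorted(tr_of[norf_id]))))
    return pd.DataFrame(rows, columns=["norf_id", "direction", "de_transcripts"])


def de_norf_intersection(tables: dict[str, pd.DataFrame]) -> list[str]:
    """nORF ids DE in every condition (e.g. shared between SCZ and BD)."""
    sets = [set(t["norf_id"]) for t in tables.values()]
    if not sets:
        return []
    return sorted(set.intersection(*sets))


def fisher_enrichment(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Sample odds ratio (a*d)/(b*c) and two-tailed Fisher exact p.

    Zero cells give an infinite or zero OR (NaN when doubly degenerate); a
    zero table margin is an error.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cells must be non-negative integers")
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin: Fisher test undefined")
    if b * c == 0:
        oddsratio = np.nan if a * d == 0 else np.inf
    else:
        oddsratio = (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(oddsratio), float(p)


# ---------------------------------------------------------------------------
# Sex-metadata QC


def sex_qc(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    chry_feature_ids: Sequence[str],
    xist_id: Optional[str] = None,
) -> pd.DataFrame:
    """Concordance of annotated sex with chrY expression and XIST clusters.

    Reports mean chrY expression per sample and, when XIST is available and
    informative, a two-group single-linkage clustering of XIST expression;
    a sample is flagged when its annotated sex disagrees with its cluster's
    majority sex.
    """
    if not len(chry_feature_ids):
        raise ValueError("chrY feature list must be non-empty")
    meta = validate_metadata(metadata, matrix.sample_ids)
    chry = [f for f in chry_feature_ids if f in matrix.values.index]
    report = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "sex": meta.loc[matrix.sample_ids, "sex"].to_numpy(),
            "mean_chry": matrix.values.loc[chry].mean(axis=0).to_numpy(),
        }
    )
    report["xist"] = np.nan
    report["xist_cluster"] = 0
    report["flagged"] = False
    if xist_id is None or xist_id not in matrix.values.index:
        warnings.warn("XIST feature absent; reporting chrY expression only")
        return report
    xist = matrix.values.loc[xist_id].to_numpy(dtype=float)
    report["xist"] = xist
    if np.ptp(xist) == 0:
        warnings.warn("XIST expression constant; clustering degenerate, no flags")
        return report
    link = hierarchy.linkage(xist.reshape(-1, 1), method="single")
    clusters = hierarchy.fcluster(link, t=2, criterion="maxclust")
    report["xist_cluster"] = clusters
    for c in np.unique(clusters):
        members = report["xist_cluster"] == c
        majority = report.loc[members, "sex"].mode().iloc[0]
        report.loc[members & (report["sex"] != majority), "flagged"] = True
    return report
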