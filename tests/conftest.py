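import numpy as np
import pandas as pd
import pytest

from norfscan import pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """One simulated scenario plus a completed pipeline run, shared by
    pipeline-level tests."""
    root = tmp_path_factory.mktemp("scenario")
    cfg, truth = pipeline.simulate_scenario(
        pipeline.Scenario(seed=7, n_genes=40), root
    )
    cfg.n_perm = 300
    manifest = pipeline.run_pipeline(cfg)
    return {"dir": root, "config": cfg, "truth": truth, "manifest": manifest}


# ---------------------------------------------------------------------------
# independent brute-force oracles


def bitmap_merge(intervals):
    """Per-base bitmap union of intervals -> sorted disjoint intervals."""
    by_chrom = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    out = []
    for chrom in sorted(by_chrom):
        bases = sorted(by_chrom[chrom])
        start = prev = bases[0]
        for b in bases[1:]:
            if b != prev + 1:
                out.append((chrom, start, prev + 1))
                start = b
            prev = b
        out.append((chrom, start, prev + 1))
    return out


def bitmap_overlaps(a, b):
    if a.chrom != b.chrom:
        return False
    return bool(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def bitmap_distance(a, b):
    if a.chrom != b.chrom:
        return float("inf")
    sa = set(range(a.start, a.end))
    sb = set(range(b.start, b.end))
    if sa & sb:
        return 0
    return min(abs(x - y) for x in (a.start, a.end - 1) for y in (b.start, b.end - 1)) - 1


def bh_bruteforce(pvals):
    """BH step-up from the definition: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def fisher_p_enumeration(a, b, c, d):
    """Two-tailed Fisher p by full enumeration of tables with fixed margins."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


def chisq_formula(table):
    """Pearson chi-square statistic from the textbook formula."""
    table = np.asarray(table, dtype=float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum @ colsum / table.sum()
    return float(((table - expected) ** 2 / expected).sum())
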