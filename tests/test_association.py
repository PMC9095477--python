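"""HAR merging/provenance, window association, DE designation, correlation
screen and chi-square metadata tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from norfscan.association import (
    associate_norf_har,
    associate_norf_te,
    build_unique_hars,
    chisq_presence,
    correlate_pairs,
    designate_de_features,
    significance_stars,
    unique_har_summary,
)
from norfscan.core import ExpressionMatrix, NorfRecord, TranscriptModel
from norfscan.simulate import generate_annotation, generate_features, generate_norfs

from conftest import bitmap_merge, chisq_formula


def har_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "source", "group"])


def norf(nid, start, end, strand="+", chrom="chr1"):
    return NorfRecord(
        norf_id=nid, chrom=chrom, strand=strand, exons=((start, end),),
        category="non_coding_transcript",
    )


class TestUniqueHars:
    def test_disjoint_sources_all_kept(self):
        t = har_table(
            [
                ("chr1", 100, 200, "h1", "s1", "vHAR"),
                ("chr1", 500, 600, "h2", "s2", "pHAR"),
            ]
        )
        assert len(build_unique_hars(t)) == 2

    def test_overlap_unions_group_set(self):
        t = har_table(
            [
                ("chr1", 100, 200, "h1", "s1", "vHAR"),
                ("chr1", 150, 250, "h2", "s2", "pHAR"),
            ]
        )
        (u,) = build_unique_hars(t)
        assert u.group_set == {"vHAR", "pHAR"}
        assert {m.har_id for m in u.members} == {"h1", "h2"}

    def test_unknown_group_rejected(self):
        t = har_table([("chr1", 0, 10, "h1", "s1", "xHAR")])
        with pytest.raises(ValueError, match="group"):
            build_unique_hars(t)

    def test_random_multisource_matches_bitmap_oracle(self, rng):
        rows = []
        for i in range(300):
            s = int(rng.integers(0, 5000))
            rows.append(
                (
                    "chr1" if rng.random() < 0.6 else "chr2",
                    s, s + int(rng.integers(50, 300)),
                    f"h{i}", f"s{i % 4}",
                    ["vHAR", "mHAR", "pHAR"][i % 3],
                )
            )
        t = har_table(rows)
        uhars = build_unique_hars(t)
        got = [(u.interval.chrom, u.interval.start, u.interval.end) for u in uhars]
        from norfscan.core import GenomicInterval

        expected = bitmap_merge(
            [GenomicInterval(r[0], r[1], r[2]) for r in rows]
        )
        assert got == expected
        assert sum(len(u.members) for u in uhars) == len(rows)
        summary = unique_har_summary(uhars)
        assert summary.loc[0, "count"] == len(uhars)

    def test_summary_fractions_multi_membership(self):
        t = har_table(
            [
                ("chr1", 100, 200, "h1", "s1", "vHAR"),
                ("chr1", 150, 250, "h2", "s2", "pHAR"),
                ("chr1", 500, 600, "h3", "s1", "pHAR"),
            ]
        )
        s = unique_har_summary(build_unique_hars(t)).set_index("group")
        assert s.loc["vHAR", "fraction"] == 0.5
        assert s.loc["pHAR", "fraction"] == 1.0


class TestHarAssociation:
    def uhars(self, rows):
        return build_unique_hars(har_table(rows))

    def test_gap_equal_to_window_included(self):
        n = norf("n1", 10_000, 11_000)
        u = self.uhars([("chr1", 11_100, 11_200, "h1", "s1", "vHAR")])
        pairs = associate_norf_har([n], u, window=100)
        assert len(pairs) == 1
        assert pairs[0].relation == "within_window"
        assert pairs[0].distance == 100

    def test_gap_window_plus_one_excluded(self):
        n = norf("n1", 10_000, 11_000)
        u = self.uhars([("chr1", 11_101, 11_200, "h1", "s1", "vHAR")])
        assert associate_norf_har([n], u, window=100) == []

    def test_overlap_relation_distance_zero(self):
        n = norf("n1", 10_000, 11_000)
        u = self.uhars([("chr1", 10_500, 10_600, "h1", "s1", "vHAR")])
        (p,) = associate_norf_har([n], u, window=100)
        assert p.relation == "overlap" and p.distance == 0

    def test_window_zero_reduces_to_overlap(self, rng):
        from norfscan.core import overlaps

        norfs = [
            norf(f"n{i}", int(s), int(s) + 500)
            for i, s in enumerate(rng.integers(0, 50_000, 30))
        ]
        u = self.uhars(
            [
                ("chr1", int(s), int(s) + 300, f"h{i}", "s1", "vHAR")
                for i, s in enumerate(rng.integers(0, 50_000, 30))
            ]
        )
        pairs = associate_norf_har(norfs, u, window=0)
        expected = {
            (n.norf_id, h.har_id)
            for n in norfs
            for h in u
            if overlaps(n.span, h.interval)
        }
        assert {(p.norf_id, p.feature_id) for p in pairs} == expected

    def test_monotone_in_window(self, rng):
        norfs = [norf(f"n{i}", int(s), int(s) + 400) for i, s in enumerate(rng.integers(0, 80_000, 20))]
        u = self.uhars(
            [("chr1", int(s), int(s) + 200, f"h{i}", "s1", "pHAR") for i, s in enumerate(rng.integers(0, 80_000, 20))]
        )
        small = {(p.norf_id, p.feature_id) for p in associate_norf_har(norfs, u, window=1000)}
        large = {(p.norf_id, p.feature_id) for p in associate_norf_har(norfs, u, window=100_000)}
        assert small <= large


class TestTeAssociation:
    def te_table(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def test_upstream_te_associated(self):
        n = norf("n1", 10_000, 11_000)
        t = self.te_table([("chr1", 8_500, 9_500, "te1")])
        (p,) = associate_norf_te([n], t)
        assert p.relation == "upstream"

    def test_te_touching_norf_excluded(self):
        n = norf("n1", 10_000, 11_000)
        t = self.te_table([("chr1", 9_500, 10_100, "te1")])
        assert associate_norf_te([n], t) == []

    def test_minus_strand_mirror(self):
        plus = norf("n1", 10_000, 11_000, strand="+")
        minus = norf("n1", 10_000, 11_000, strand="-")
        upstream_of_plus = self.te_table([("chr1", 9_000, 9_500, "te1")])
        downstream_of_plus = self.te_table([("chr1", 11_200, 11_700, "te1")])
        assert len(associate_norf_te([plus], upstream_of_plus)) == 1
        assert associate_norf_te([plus], downstream_of_plus) == []
        assert associate_norf_te([minus], upstream_of_plus) == []
        assert len(associate_norf_te([minus], downstream_of_plus)) == 1

    def test_unstranded_rejected(self):
        n = norf("n1", 10_000, 11_000, strand=".")
        with pytest.raises(ValueError, match="unstranded"):
            associate_norf_te([n], self.te_table([("chr1", 9_000, 9_100, "te1")]))

    def test_no_pair_ever_overlaps_its_norf(self, rng):
        from norfscan.core import GenomicInterval, overlaps

        norfs = [
            norf(f"n{i}", int(s), int(s) + 800, strand="+" if i % 2 else "-")
            for i, s in enumerate(rng.integers(3000, 40_000, 25))
        ]
        tes = self.te_table(
            [
                ("chr1", int(s), int(s) + 400, f"te{i}")
                for i, s in enumerate(rng.integers(0, 42_000, 60))
            ]
        )
        by_id = {n.norf_id: n for n in norfs}
        te_iv = {r["name"]: GenomicInterval(r.chrom, r.start, r.end) for _, r in tes.iterrows()}
        for p in associate_norf_te(norfs, tes):
            assert not overlaps(te_iv[p.feature_id], by_id[p.norf_id].span)

    def test_planted_pairs_fully_recovered(self):
        transcripts = generate_annotation(41, n_genes=40)
        norfs, _ = generate_norfs(42, transcripts)
        ids = [n.norf_id for n in norfs]
        hars, tes, truth = generate_features(
            43, norfs,
            planted_har_pairs=[(i, "pHAR") for i in ids[:6]],
            planted_te_pairs=ids[6:12],
        )
        uhars = build_unique_hars(
            hars[["chrom", "start", "end", "name", "source", "group"]]
        )
        har_pairs = associate_norf_har(norfs, uhars)
        te_pairs = associate_norf_te(norfs, tes)
        assert {n for n, _ in truth.norf_har_pairs} <= {p.norf_id for p in har_pairs}
        assert truth.norf_te_pairs <= {(p.norf_id, p.feature_id) for p in te_pairs}


class TestDeDesignation:
    def test_intronic_har_flagged_by_span(self):
        t = TranscriptModel(
            transcript_id="t1", gene_id="t1", chrom="chr1", strand="+",
            exons=((100, 200), (900, 1000)), biotype="retained_intron",
        )
        features = pd.DataFrame(
            [("chr1", 400, 500, "h1")], columns=["chrom", "start", "end", "name"]
        )
        assert designate_de_features(features, [t])["is_de"].item()
        assert not designate_de_features(features, [t], exon_level=True)["is_de"].item()

    def test_other_chrom_unflagged(self):
        t = TranscriptModel(
            transcript_id="t1", gene_id="t1", chrom="chr2", strand="+",
            exons=((100, 200),), biotype="lincRNA",
        )
        features = pd.DataFrame(
            [("chr1", 100, 200, "h1")], columns=["chrom", "start", "end", "name"]
        )
        assert not designate_de_features(features, [t])["is_de"].item()


class TestCorrelation:
    def expr(self, rows):
        return ExpressionMatrix(pd.DataFrame(rows).T, "logCPM")

    def test_linear_pair_significant(self):
        x = np.arange(10, dtype=float)
        m = self.expr({"n1": x, "te1": 2 * x + 1})
        (r,) = correlate_pairs(m, [("n1", "te1")])
        assert r.pearson_r == pytest.approx(1.0)
        assert r.spearman_rho == pytest.approx(1.0)
        assert r.significant

    def test_magnitude_gate_blocks_weak_correlation(self, rng):
        # |r| ~ 0.4 with large n: tiny p but below the magnitude gate
        n = 2000
        x = rng.normal(0, 1, n)
        y = 0.4 * x + np.sqrt(1 - 0.16) * rng.normal(0, 1, n)
        m = self.expr({"n1": x, "te1": y})
        (r,) = correlate_pairs(m, [("n1", "te1")])
        assert r.pearson_p < 1e-6
        assert not r.significant

    def test_zero_variance_undefined_and_insignificant(self):
        m = self.expr({"n1": np.ones(8), "te1": np.arange(8.0)})
        (r,) = correlate_pairs(m, [("n1", "te1")])
        assert np.isnan(r.pearson_r)
        assert not r.significant

    def test_matches_bruteforce_covariance_and_ranks(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            m = self.expr({"a": x, "b": y})
            (r,) = correlate_pairs(m, [("a", "b")])
            xm, ym = x - x.mean(), y - y.mean()
            pear = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            rxm, rym = rx - rx.mean(), ry - ry.mean()
            spear = (rxm @ rym) / np.sqrt((rxm @ rxm) * (rym @ rym))
            assert r.pearson_r == pytest.approx(pear, abs=1e-10)
            assert r.spearman_rho == pytest.approx(spear, abs=1e-10)


class TestChisq:
    def test_identical_proportions_null(self):
        presence = [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5
        groups = ["a"] * 10 + ["b"] * 10
        stat, p, star = chisq_presence(presence, groups)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert star == "N.S."

    def test_complete_separation_three_stars(self):
        presence = [True] * 10 + [False] * 10
        groups = ["a"] * 10 + ["b"] * 10
        stat, p, star = chisq_presence(presence, groups)
        assert stat == pytest.approx(20.0)
        assert p < 0.001
        assert star == "***"

    def test_matches_textbook_formula(self, rng):
        for _ in range(100):
            groups = np.array(["a"] * 15 + ["b"] * 15 + ["c"] * 15)
            presence = rng.random(45) < 0.5
            if presence.all() or not presence.any():
                continue
            stat, _, _ = chisq_presence(presence, groups)
            labels = ["a", "b", "c"]
            table = [
                [presence[groups == g].sum(), (~presence[groups == g]).sum()]
                for g in labels
            ]
            assert stat == pytest.approx(chisq_formula(table), abs=1e-10)

    def test_star_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.5) == "N.S."
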