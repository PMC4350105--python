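"""Promoter mapping, five-pattern classification, TSS profiles, enrichment."""

import itertools
import math

import numpy as np
import pytest

from ncmeth.dmr import DMR
from ncmeth.genome import (
    GeneModel,
    GenomicInterval,
    PromoterRegion,
    build_promoter,
    build_shores,
)
from ncmeth.patterns import (
    classify_patterns,
    concordance_rate_lt50,
    host_concordance,
    map_dmrs_to_cgis,
    map_dmrs_to_promoters,
    region_set_enrichment,
    tss_profile,
)


def dmr(start, end, direction="hyper", chrom="chr1"):
    return DMR(GenomicInterval(chrom, start, end), direction, (end - start) // 100, 1e-4, 2.0)


def promoter(gene_id, tss, strand="+", flank=2000, chrom="chr1"):
    return PromoterRegion(
        gene_id, GenomicInterval(chrom, tss - flank, tss + flank, strand), tss, flank
    )


class TestMapDmrsToPromoters:
    P = {"g": promoter("g", 2100)}  # promoter [100, 4100)

    def test_exactly_half_is_called(self):
        calls = map_dmrs_to_promoters([dmr(0, 200)], self.P)  # 100/200 = 0.5
        assert len(calls) == 1 and calls[0].gene_id == "g"

    def test_three_quarters_called(self):
        calls = map_dmrs_to_promoters([dmr(0, 400)], self.P)  # 300/400
        assert len(calls) == 1

    def test_just_below_half_not_called(self):
        # DMR [3700,4700) vs promoter [100,4100): overlap 400/1000 = 0.4
        assert map_dmrs_to_promoters([dmr(3700, 4700)], self.P) == []

    def test_outside_not_called(self):
        assert map_dmrs_to_promoters([dmr(8000, 8400)], self.P) == []

    def test_both_directions_flagged_ambiguous(self):
        calls = map_dmrs_to_promoters([dmr(200, 400, "hyper"), dmr(600, 800, "hypo")], self.P)
        assert {c.direction for c in calls} == {"hyper", "hypo"}
        assert all(c.ambiguous for c in calls)

    def test_agrees_with_brute_force_scan(self):
        """Oracle: check every (DMR, promoter) pair directly."""
        rng = np.random.default_rng(12)
        dmrs = [
            dmr(int(s), int(s + rng.integers(1, 10) * 100),
                "hyper" if rng.random() < 0.5 else "hypo")
            for s in rng.integers(0, 200, size=120) * 100
        ]
        proms = {
            f"g{i}": promoter(f"g{i}", int(t))
            for i, t in enumerate(rng.integers(20, 180, size=40) * 100)
        }
        calls = map_dmrs_to_promoters(dmrs, proms)
        got = {(c.gene_id, c.direction): set(c.dmr_indices) for c in calls}
        expected: dict = {}
        for (gid, p), (i, d) in itertools.product(proms.items(), enumerate(dmrs)):
            ov = max(0, min(d.interval.end, p.interval.end) - max(d.interval.start, p.interval.start))
            if ov / d.interval.length >= 0.5:
                expected.setdefault((gid, d.direction), set()).add(i)
        assert got == expected


class TestMapDmrsToCgis:
    def test_body_and_shore_rules(self):
        cgi = build_shores(GenomicInterval("chr1", 10_000, 11_000))
        # half inside the body
        out = map_dmrs_to_cgis([dmr(9_900, 10_100)], [cgi])
        assert out.loc[0, "body"] == "hyper"
        # fully inside the genome-right shore only
        out = map_dmrs_to_cgis([dmr(11_200, 11_600, "hypo")], [cgi])
        assert out.loc[0, "three_prime_shore"] == "hypo"
        assert out.loc[0, "body"] == "" and out.loc[0, "five_prime_shore"] == ""

    def test_spanning_dmr_calls_majority_region(self):
        cgi = build_shores(GenomicInterval("chr1", 10_000, 11_000))
        # DMR spans left shore end + body start: 800 bp in shore, 200 in body
        out = map_dmrs_to_cgis([dmr(9_200, 10_200)], [cgi])
        assert out.loc[0, "five_prime_shore"] == "hyper"  # 800/1000 >= 0.5
        assert out.loc[0, "body"] == ""  # 200/1000 < 0.5


class PatternFixture:
    """Constructed promoters covering all five patterns on both strands,
    boundary fractions, and a multi-CGI promoter."""

    def __init__(self):
        self.genes = {}
        self.promoters = {}
        self.cgis = []
        self.dmrs = []
        self.expected = {}
        self._next = 0

    def add(self, strand, expected_pattern, dmr_rel, cgi_rels=((-400, 400),),
            direction="hyper", with_cgi=True, label=None):
        """dmr_rel / cgi_rels are stranded TSS-relative [a, b) offsets."""
        gid = label or f"G{self._next}"
        self._next += 1
        tss = 100_000 + 20_000 * self._next
        chrom = "chr1"

        def to_genome(rel):
            a, b = rel
            if strand == "-":
                return GenomicInterval(chrom, tss - b, tss - a)
            return GenomicInterval(chrom, tss + a, tss + b)

        gene_iv = (
            GenomicInterval(chrom, tss, tss + 1_000, "+")
            if strand == "+"
            else GenomicInterval(chrom, tss - 1_000, tss, "-")
        )
        gene = GeneModel(gid, gene_iv, "lncRNA")
        self.genes[gid] = gene
        self.promoters[gid] = build_promoter(gene)
        if with_cgi:
            for rel in cgi_rels:
                self.cgis.append(build_shores(to_genome(rel)))
        self.dmrs.append(
            DMR(to_genome(dmr_rel), direction,
                (dmr_rel[1] - dmr_rel[0]) // 100, 1e-5, 2.0)
        )
        self.expected[(gid, direction)] = expected_pattern
        return gid

    def classify(self):
        calls = map_dmrs_to_promoters(self.dmrs, self.promoters)
        pcs = classify_patterns(calls, self.promoters, self.cgis, self.dmrs)
        return {(p.gene_id, p.direction): p.pattern for p in pcs}


def build_truth_table_fixture():
    fx = PatternFixture()
    for strand in ("+", "-"):
        dir_ = "hyper" if strand == "+" else "hypo"
        # pattern 1: DMR == CGI (either-region overlap 1.0)
        fx.add(strand, 1, (-400, 400), direction=dir_)
        # pattern 1 boundary: overlap just above 0.5 of the CGI
        # DMR [-100, 600): CGI overlap 500/800 = 0.625 of CGI, 500/700 of DMR
        fx.add(strand, 1, (-100, 600), direction=dir_)
        # pattern 4 boundary: overlap exactly 0.5 of either region is NOT
        # "greater than 50%" -> falls through to partial overlap
        # DMR [0, 400): overlap 400; of CGI 400/800 = 0.5, of DMR 400/400 = 1.0
        # ... of the DMR it IS 1.0 > 0.5, so use a wider DMR:
        # DMR [0, 800): overlap [0,400)=400; of CGI 0.5, of DMR 0.5 -> pattern 4
        fx.add(strand, 4, (0, 800), direction=dir_)
        # pattern 2: strictly 5' of the CGI, inside the 5' shore
        fx.add(strand, 2, (-1600, -800), direction=dir_)
        # pattern 2 boundary: DMR abuts the CGI start (half-open adjacency)
        fx.add(strand, 2, (-1200, -400), direction=dir_)
        # pattern 3: strictly 3'
        fx.add(strand, 3, (800, 1600), direction=dir_)
        # pattern 4: straddles the CGI edge with sub-half overlap both ways
        fx.add(strand, 4, (100, 1900), direction=dir_)
        # pattern 5: promoter without any CGI
        fx.add(strand, 5, (-400, 400), with_cgi=False, direction=dir_)
        # multi-CGI promoter: DMR between two CGIs -> not strictly 5'/3' of
        # every CGI -> pattern 4
        fx.add(strand, 4, (-100, 300),
               cgi_rels=((-1500, -700), (700, 1500)), direction=dir_)
        # multi-CGI promoter: confined to the first of two CGIs -> pattern 1
        fx.add(strand, 1, (-1500, -700),
               cgi_rels=((-1500, -700), (700, 1500)), direction=dir_)
    return fx


class TestClassifyPattern:
    def test_truth_table(self):
        fx = build_truth_table_fixture()
        got = fx.classify()
        assert got == fx.expected

    def test_exhaustive_and_exclusive(self):
        fx = build_truth_table_fixture()
        calls = map_dmrs_to_promoters(fx.dmrs, fx.promoters)
        pcs = classify_patterns(calls, fx.promoters, fx.cgis, fx.dmrs)
        keys = [(p.gene_id, p.direction) for p in pcs]
        assert len(keys) == len(set(keys))  # exactly one pattern per call
        assert all(p.pattern in (1, 2, 3, 4, 5) for p in pcs)

    def test_largest_overlap_dmr_decides(self):
        fx = PatternFixture()
        gid = fx.add("+", 1, (-400, 400))  # big CGI-confined DMR
        # add a small 3'-shore DMR on the same promoter
        tss = fx.promoters[gid].tss
        fx.dmrs.append(dmr(tss + 800, tss + 1_000))
        got = fx.classify()
        assert got[(gid, "hyper")] == 1  # 800-bp DMR outweighs 200-bp DMR


class TestTssProfile:
    def test_full_coverage_half_of_rows(self):
        proms = {"a": promoter("a", 10_000), "b": promoter("b", 50_000)}
        prof = tss_profile(proms, [dmr(8_000, 12_000)], "hyper")
        np.testing.assert_allclose(prof.frequency, 0.5)

    def test_no_dmrs_zero_matrix(self):
        proms = {"a": promoter("a", 10_000)}
        prof = tss_profile(proms, [], "hyper")
        assert prof.matrix.sum() == 0
        assert prof.matrix.shape == (1, 400)

    def test_minus_strand_downstream_window(self):
        # '-' gene: genomic upstream-of-TSS (higher coords) is downstream cols
        proms = {"a": promoter("a", 10_000, strand="-")}
        prof = tss_profile(proms, [dmr(9_000, 9_500)], "hyper")
        cols = np.flatnonzero(prof.matrix[0])
        assert cols.min() >= 200  # all in the downstream (positive) half

    def test_strand_reflection_invariance(self):
        """Reflecting the genome and flipping strands preserves the matrix."""
        L = 1_000_000
        rng = np.random.default_rng(13)
        proms, proms_ref, dmrs, dmrs_ref = {}, {}, [], []
        for i in range(12):
            tss = int(rng.integers(10, 90) * 10_000)
            strand = "+" if rng.random() < 0.5 else "-"
            flip = {"+": "-", "-": "+"}[strand]
            proms[f"g{i}"] = promoter(f"g{i}", tss, strand=strand)
            proms_ref[f"g{i}"] = promoter(f"g{i}", L - tss, strand=flip)
        for _ in range(30):
            s = int(rng.integers(0, L // 100 - 20)) * 100
            e = s + int(rng.integers(1, 20)) * 100
            dmrs.append(dmr(s, e))
            dmrs_ref.append(dmr(L - e, L - s))
        a = tss_profile(proms, dmrs, "hyper")
        b = tss_profile(proms_ref, dmrs_ref, "hyper")
        np.testing.assert_array_equal(a.matrix, b.matrix)


class TestHostConcordance:
    def make_pair(self, nc_tss, host_tss, nc_dir=None, host_dir=None):
        host = GeneModel("host", GenomicInterval("chr1", host_tss, host_tss + 50_000, "+"), "coding")
        nc = GeneModel(
            "nc", GenomicInterval("chr1", nc_tss, nc_tss + 500, "+"), "lncRNA",
            biotype="intragenic", host_gene_id="host",
        )
        proms = {"nc": build_promoter(nc), "host": build_promoter(host)}
        dmrs, calls = [], []
        from ncmeth.patterns import PromoterCall

        if nc_dir:
            calls.append(PromoterCall("nc", nc_dir, (0,)))
        if host_dir:
            calls.append(PromoterCall("host", host_dir, (0,)))
        return host_concordance(calls, [nc, host], proms)

    def test_identical_promoters_ge50(self):
        out = self.make_pair(20_000, 20_000)
        assert out.loc[0, "overlap_class"] == "ge50"

    def test_disjoint_promoters_concordant(self):
        out = self.make_pair(40_000, 20_000, "hyper", "hyper")
        assert out.loc[0, "overlap_class"] == "lt50"
        assert out.loc[0, "concordant"]
        assert concordance_rate_lt50(out) == 1.0

    def test_one_called_discordant(self):
        out = self.make_pair(40_000, 20_000, "hyper", None)
        assert not out.loc[0, "concordant"]


class TestRegionSetEnrichment:
    def setup_method(self):
        # 20 genes: 10 with promoters inside the region set, 10 outside
        self.proms = {}
        for i in range(20):
            self.proms[f"g{i}"] = promoter(f"g{i}", 10_000 + 10_000 * i)
        self.region = [GenomicInterval("chr1", 0, 105_000)]  # first 10 promoters

    def test_perfect_association(self):
        called = {f"g{i}" for i in range(10)}
        odds, p = region_set_enrichment(called, list(self.proms), self.region, self.proms)
        assert odds == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))  # Haldane
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_independence(self):
        called = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10, 15)}
        odds, p = region_set_enrichment(called, list(self.proms), self.region, self.proms)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Oracle: two-sided p as the mass of all tables with probability
        <= the observed one, from math.comb."""
        rng = np.random.default_rng(14)
        from scipy.stats import fisher_exact

        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            n = a + b + c + d
            row1, col1 = a + b, a + c

            def table_p(k):
                return (
                    math.comb(col1, k) * math.comb(n - col1, row1 - k)
                    / math.comb(n, row1)
                )

            p_obs = table_p(a)
            lo, hi = max(0, row1 - (n - col1)), min(row1, col1)
            p_two = sum(table_p(k) for k in range(lo, hi + 1)
                        if table_p(k) <= p_obs * (1 + 1e-9))
            _, p_scipy = fisher_exact([[a, b], [c, d]])
            assert p_scipy == pytest.approx(p_two, abs=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            region_set_enrichment(set(), [], self.region, self.proms)
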