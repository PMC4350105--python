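"""Normalization, rank-sum testing, BH adjustment and DMR merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from ncmeth.dmr import (
    InsufficientDataError,
    adjust_bh,
    call_dmrs,
    merge_bins_to_dmrs,
    normalize_linear,
    wilcoxon_rank_sum,
)
from ncmeth.dmr import test_bins as bin_statistics  # alias: pytest must not collect it
from ncmeth.io import BinTrack


def make_track(values, sample_id="s", group="tumor", bin_width=100):
    return BinTrack(sample_id, bin_width, {"chr1": np.asarray(values, float)}, group)


def enumeration_p(x, y):
    """Independent oracle: build the exact null distribution of the rank sum
    by dynamic programming over item inclusion, then double the smaller tail
    (capped at 1), the usual two-sided convention for discrete statistics."""
    pooled = np.concatenate([x, y])
    ranks = sp_stats.rankdata(pooled)
    n = len(x)
    w_obs = round(ranks[:n].sum() * 2)  # doubled ranks are integers
    # dist[k][s] = number of k-subsets of the doubled ranks summing to s
    dist = [{0: 1}]
    for _ in range(n):
        dist.append({})
    for r in (ranks * 2).astype(int):
        for k in range(min(n, len(dist) - 1), 0, -1):
            for s, cnt in list(dist[k - 1].items()):
                dist[k][s + r] = dist[k].get(s + r, 0) + cnt
    total = sum(dist[n].values())
    lo = sum(c for s, c in dist[n].items() if s <= w_obs)
    hi = sum(c for s, c in dist[n].items() if s >= w_obs)
    return min(1.0, 2.0 * min(lo, hi) / total)


class TestNormalizeLinear:
    def test_scale_factors(self):
        a = make_track([10] * 10)  # total 100
        b = make_track([30] * 10)  # total 300
        out = normalize_linear([a, b])
        assert out[0].data["chr1"][0] == pytest.approx(20.0)  # factor 2
        assert out[1].data["chr1"][0] == pytest.approx(20.0)  # factor 2/3
        assert out[0].total() == pytest.approx(out[1].total())

    def test_single_sample_identity(self):
        a = make_track([1, 2, 3])
        out = normalize_linear([a])
        np.testing.assert_allclose(out[0].data["chr1"], [1, 2, 3])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_linear([make_track([0, 0], sample_id="bad")])


class TestWilcoxonRankSum:
    def test_fully_separated_small(self):
        # 2 * 1/C(6,3) = 0.1 by enumerating all 20 rank splits
        assert wilcoxon_rank_sum([10, 11, 12], [1, 2, 3]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.integers(0, 20, size=4).astype(float)
            y = rng.integers(0, 20, size=5).astype(float)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_rank_sum(y, x))

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_rank_sum([1.0], [2.0, 3.0])

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            n, m = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            x = rng.integers(0, 8, size=n).astype(float)  # ties likely
            y = rng.integers(0, 8, size=m).astype(float)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                enumeration_p(x, y), abs=1e-12
            )

    def test_exact_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            pool = rng.permutation(40)[:9].astype(float)
            x, y = pool[:4], pool[4:]
            ours = wilcoxon_rank_sum(x, y)
            ref = sp_stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours == pytest.approx(ref.pvalue, abs=1e-12)

    def test_asymptotic_matches_scipy_continuity_corrected(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(0, 1, size=15)
            y = rng.normal(0.5, 1, size=12)
            ours = wilcoxon_rank_sum(x, y)
            ref = sp_stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            assert ours == pytest.approx(ref.pvalue, rel=1e-9)


class TestAdjustBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_constant(self):
        assert adjust_bh([1.0])[0] == 1.0
        np.testing.assert_allclose(adjust_bh([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    def test_matches_hand_step_up_on_random_vectors(self):
        def hand_bh(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p, kind="stable")
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, m * p[i] / rank)
                q[i] = running
            return q

        rng = np.random.default_rng(8)
        for _ in range(25):
            p = rng.uniform(size=int(rng.integers(1, 60)))
            np.testing.assert_allclose(adjust_bh(p), hand_bh(p), atol=1e-12)

    def test_rank_monotonicity(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        q = adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestTestBins:
    def build_cohort(self, tumor_rows, normal_rows):
        tracks = [make_track(r, f"t{i}", "tumor") for i, r in enumerate(tumor_rows)]
        tracks += [make_track(r, f"n{i}", "normal") for i, r in enumerate(normal_rows)]
        return tracks

    def test_zero_coverage_bin_excluded(self):
        tracks = self.build_cohort(
            [[0, 50], [0, 60], [0, 55]], [[0, 10], [0, 12], [0, 9]]
        )
        stats = bin_statistics(tracks)
        assert not stats.loc[0, "tested"]
        assert stats.loc[0, "call"] == "none"
        assert stats.loc[1, "tested"]

    def test_fold_change_below_threshold_not_called(self):
        # strong separation but fold change 1.9 < 2 must stay uncalled
        tumor = [[190 + i] for i in range(6)]
        normal = [[100 + i] for i in range(6)]
        stats = bin_statistics(self.build_cohort(tumor, normal), pseudocount=0.0)
        assert 1.8 < stats.loc[0, "fold_change"] < 2.0
        assert stats.loc[0, "call"] == "none"

    def test_missing_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            bin_statistics([make_track([1, 2], group="tumor")] * 3)

    def test_bh_family_is_tested_bins_only(self):
        rng = np.random.default_rng(10)
        tumor = [rng.poisson(50, size=30).astype(float) for _ in range(5)]
        normal = [rng.poisson(50, size=30).astype(float) for _ in range(5)]
        for rows in (tumor, normal):  # make bins 0..9 empty everywhere
            for r in rows:
                r[:10] = 0.0
        stats = bin_statistics(self.build_cohort(tumor, normal))
        assert stats["tested"].sum() == 20
        assert stats.loc[~stats["tested"], "q_value"].isna().all()


class TestMergeBinsToDmrs:
    def frame(self, calls, chrom="chr1", start0=0):
        n = len(calls)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.arange(n) * 100 + start0,
                "end": np.arange(1, n + 1) * 100 + start0,
                "fold_change": [4.0 if c == "hyper" else 0.25 if c == "hypo" else 1.0
                                for c in calls],
                "q_value": [1e-3 if c != "none" else np.nan for c in calls],
                "call": calls,
            }
        )

    def test_gap_breaks_run(self):
        dmrs = merge_bins_to_dmrs(self.frame(["hyper", "hyper", "none", "hyper"]))
        spans = [(d.interval.start, d.interval.end, d.n_bins) for d in dmrs]
        assert spans == [(0, 200, 2), (300, 400, 1)]

    def test_direction_change_breaks_run(self):
        dmrs = merge_bins_to_dmrs(self.frame(["hyper", "hypo"]))
        assert [(d.direction, d.n_bins) for d in dmrs] == [("hyper", 1), ("hypo", 1)]

    def test_no_calls(self):
        assert merge_bins_to_dmrs(self.frame(["none"] * 4)) == []

    def test_chromosome_boundary_breaks_run(self):
        f = pd.concat(
            [self.frame(["hyper"]), self.frame(["hyper"], chrom="chr2")],
            ignore_index=True,
        )
        assert len(merge_bins_to_dmrs(f)) == 2

    def test_unsorted_rejected(self):
        f = self.frame(["hyper", "hyper"]).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            merge_bins_to_dmrs(f)

    def test_base_conservation_random(self):
        """Total DMR span equals called bins x bin width (connected components)."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            calls = rng.choice(["hyper", "hypo", "none"], size=60, p=[0.3, 0.3, 0.4])
            dmrs = merge_bins_to_dmrs(self.frame(list(calls)))
            n_called = int(np.sum(calls != "none"))
            assert sum(d.interval.length for d in dmrs) == n_called * 100
            assert sum(d.n_bins for d in dmrs) == n_called


def test_call_dmrs_end_to_end_smoke(default_cohort):
    config, annotation, tracks, truth = default_cohort
    dmrs, stats = call_dmrs(tracks)
    assert len(dmrs) > 0
    assert stats["tested"].all()  # baseline coverage everywhere
    for d in dmrs:
        assert d.min_q < 0.01 and d.interval.length == d.n_bins * 100
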