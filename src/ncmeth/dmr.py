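"""Differential methylation calling on fixed-width genomic bins.

The procedure: linear library-size normalization of the per-sample bin
tracks, a two-sided Wilcoxon rank-sum test per bin between the tumor and
normal groups, Benjamini-Hochberg adjustment across all tested bins
genome-wide, a dual call criterion (fold change of pseudocounted group
means >= ``fc_threshold`` or <= its reciprocal, and adjusted p <
``q_threshold``), and merging of gap-free runs of same-direction called
bins into differentially methylated regions (DMRs).

Bins whose group means both fall below a coverage floor are excluded from
testing and from the BH family: capture-based methylomes leave CpG-poor
bins systematically empty, and testing them only dilutes the adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomicInterval
from .io import BinTrack


class InsufficientDataError(ValueError):
    """Fewer than two observations in a group."""


@dataclass(frozen=True)
class DMR:
    """Maximal run of adjacent same-direction significant bins."""

    interval: GenomicInterval
    direction: str  # hyper | hypo, tumor relative to normal
    n_bins: int
    min_q: float
    max_abs_log2fc: float


def normalize_linear(tracks: list[BinTrack]) -> list[BinTrack]:
    """Scale every track so all totals equal the cohort mean total."""
    if not tracks:
        raise ValueError("no tracks to normalize")
    totals = [t.total() for t in tracks]
    for t, tot in zip(tracks, totals):
        if tot == 0:
            raise ValueError(f"sample {t.sample_id} has zero total count")
    target = float(np.mean(totals))
    return [t.scaled(target / tot) for t, tot in zip(tracks, totals)]


def _ranksum_p_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized two-sided normal-approximation rank-sum p-values.

    ``x``: (n, bins) tumor values, ``y``: (m, bins) normal values.  Uses
    midranks, the tie-corrected variance and a 0.5 continuity correction.
    Columns with zero rank variance (all values tied) get p = 1.
    """
    n, m = x.shape[0], y.shape[0]
    big_n = n + m
    pooled = np.vstack([x, y])
    ranks = stats.rankdata(pooled, axis=0)
    w = ranks[:n].sum(axis=0)
    mean_w = n * (big_n + 1) / 2.0
    # tie correction: sum over tie groups of (t^3 - t), per column
    sorted_r = np.sort(ranks, axis=0)
    new_group = np.ones_like(sorted_r, dtype=bool)
    new_group[1:] = sorted_r[1:] != sorted_r[:-1]
    group_id = np.cumsum(new_group, axis=0)
    tie_term = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        _, counts = np.unique(group_id[:, j], return_counts=True)
        tie_term[j] = float(np.sum(counts.astype(float) ** 3 - counts))
    var_w = (n * m / 12.0) * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    p = np.ones(x.shape[1])
    ok = var_w > 0
    diff = w - mean_w
    cc = np.sign(diff) * 0.5  # continuity correction toward the mean
    z = np.zeros_like(p)
    z[ok] = (diff[ok] - cc[ok]) / np.sqrt(var_w[ok])
    p[ok] = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z[ok])))
    return p


def wilcoxon_rank_sum(x, y, exact_limit: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two samples.

    Small samples (n + m <= ``exact_limit``) are handled by exact
    enumeration of all C(n+m, n) group assignments of the (mid)ranks, with
    the two-sided p as twice the smaller tail probability, capped at 1.
    Larger samples use the tie- and continuity-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise InsufficientDataError("need >= 2 observations per group")
    if n + m <= exact_limit:
        ranks = stats.rankdata(np.concatenate([x, y]))
        w_obs = ranks[:n].sum()
        lo = hi = total = 0
        for combo in itertools.combinations(range(n + m), n):
            w = ranks[list(combo)].sum()
            total += 1
            if w >= w_obs - 1e-9:
                hi += 1
            if w <= w_obs + 1e-9:
                lo += 1
        return min(1.0, 2.0 * min(lo, hi) / total)
    return float(_ranksum_p_matrix(x[:, None], y[:, None])[0])


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_bins(
    tracks: list[BinTrack],
    fc_threshold: float = 2.0,
    q_threshold: float = 0.01,
    pseudocount: float = 0.5,
    min_mean: float = 1.0,
    exact_limit: int = 12,
) -> pd.DataFrame:
    """Per-bin differential methylation statistics between groups.

    Expects normalized tracks.  Returns one row per genomic bin with columns
    chrom, start, end, tumor_mean, normal_mean, fold_change, p_value,
    q_value, call and tested.  Untested (low-coverage) bins carry NaN
    statistics and call ``none``; BH runs over tested bins only,
    genome-wide.
    """
    tumor = [t for t in tracks if t.group == "tumor"]
    normal = [t for t in tracks if t.group == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise InsufficientDataError("need >= 2 tumor and >= 2 normal tracks")
    bin_width = tracks[0].bin_width
    chroms = sorted(tracks[0].data)

    frames = []
    for chrom in chroms:
        xs = np.vstack([t.data[chrom] for t in tumor])
        ys = np.vstack([t.data[chrom] for t in normal])
        t_mean = xs.mean(axis=0)
        n_mean = ys.mean(axis=0)
        tested = (t_mean >= min_mean) | (n_mean >= min_mean)
        fc = (t_mean + pseudocount) / (n_mean + pseudocount)
        p = np.full(xs.shape[1], np.nan)
        if tested.any():
            if len(tumor) + len(normal) <= exact_limit:
                idx = np.flatnonzero(tested)
                p[idx] = [
                    wilcoxon_rank_sum(xs[:, j], ys[:, j], exact_limit) for j in idx
                ]
            else:
                p[tested] = _ranksum_p_matrix(xs[:, tested], ys[:, tested])
        starts = np.arange(xs.shape[1]) * bin_width
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + bin_width,
                    "tumor_mean": t_mean,
                    "normal_mean": n_mean,
                    "fold_change": fc,
                    "p_value": p,
                    "tested": tested,
                }
            )
        )
    stats_df = pd.concat(frames, ignore_index=True)
    q = np.full(len(stats_df), np.nan)
    tested_mask = stats_df["tested"].to_numpy()
    q[tested_mask] = adjust_bh(stats_df.loc[tested_mask, "p_value"])
    stats_df["q_value"] = q

    call = np.full(len(stats_df), "none", dtype=object)
    sig = tested_mask & (q < q_threshold)
    call[sig & (stats_df["fold_change"] >= fc_threshold)] = "hyper"
    call[sig & (stats_df["fold_change"] <= 1.0 / fc_threshold)] = "hypo"
    stats_df["call"] = call
    return stats_df


def merge_bins_to_dmrs(stats_df: pd.DataFrame, bin_width: int | None = None) -> list[DMR]:
    """Merge gap-free runs of adjacent same-direction called bins into DMRs.

    Any intervening bin on the grid — uncalled or opposite direction —
    terminates a run; singleton DMRs are allowed.
    """
    if len(stats_df) == 0:
        return []
    chrom = stats_df["chrom"].to_numpy()
    start = stats_df["start"].to_numpy()
    end = stats_df["end"].to_numpy()
    call = stats_df["call"].to_numpy()
    same_chrom = chrom[1:] == chrom[:-1]
    if np.any(same_chrom & (start[1:] < start[:-1])):
        raise ValueError("bin statistics must be coordinate sorted")

    called = call != "none"
    if not called.any():
        return []
    # a new run starts wherever adjacency to the previous called bin breaks
    new_run = np.ones(len(stats_df), dtype=bool)
    new_run[1:] = ~(
        same_chrom & (start[1:] == end[:-1]) & (call[1:] == call[:-1]) & called[:-1]
    )
    run_id = np.cumsum(new_run & called)
    run_id[~called] = 0

    q = stats_df["q_value"].to_numpy(dtype=float)
    abs_l2fc = np.abs(np.log2(stats_df["fold_change"].to_numpy(dtype=float)))
    dmrs: list[DMR] = []
    idx = np.flatnonzero(called)
    # runs are contiguous index stretches within `idx`
    split_points = np.flatnonzero(np.diff(run_id[idx]) != 0) + 1
    for seg in np.split(idx, split_points):
        first, last = seg[0], seg[-1]
        iv = GenomicInterval(str(chrom[first]), int(start[first]), int(end[last]))
        dmrs.append(
            DMR(
                iv,
                str(call[first]),
                len(seg),
                float(np.min(q[seg])),
                float(np.max(abs_l2fc[seg])),
            )
        )
    return dmrs


def call_dmrs(
    tracks: list[BinTrack],
    fc_threshold: float = 2.0,
    q_threshold: float = 0.01,
    pseudocount: float = 0.5,
    min_mean: float = 1.0,
) -> tuple[list[DMR], pd.DataFrame]:
    """Normalize, test and merge in one step; returns (DMRs, bin stats)."""
    normalized = normalize_linear(tracks)
    stats_df = test_bins(
        normalized,
        fc_threshold=fc_threshold,
        q_threshold=q_threshold,
        pseudocount=pseudocount,
        min_mean=min_mean,
    )
    return merge_bins_to_dmrs(stats_df, tracks[0].bin_width), stats_df
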