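"""Methylation-expression integration and biomarker panel evaluation.

Two regulatory scenarios are screened: *silencing* (promoter
hypermethylation with reduced expression in tumor) and *activating*
(hypomethylation with increased expression).  lncRNA expression comes from
a small cell-line FPKM table and uses a two-fold rule that must hold in
every tumor line; miRNA expression comes from a cohort RPM matrix and uses
a two-sample t-test on log2(RPM + 1) with BH adjustment.  Candidates are
the intersection with opposing methylation/expression directions.

Biomarker panels score each sample by the mean of per-feature Z-scores,
sign-flipped so that the cancer-associated direction of every feature
contributes positively, and are evaluated by ROC/AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .dmr import adjust_bh
from .genome import PromoterRegion
from .io import BinTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegulationCandidate:
    """A gene whose methylation and expression change in opposite senses."""

    gene_id: str
    scenario: str  # silencing | activating
    methylation_direction: str
    expression_direction: str


def lncrna_expression_change(
    fpkm: pd.DataFrame,
    control_cols: Sequence[str],
    tumor_cols: Sequence[str],
    fold: float = 2.0,
    min_fpkm: float = 0.1,
) -> pd.Series:
    """Per-gene expression change label from a cell-line FPKM table.

    Each tumor line is labeled up/down/none against the mean of the control
    lines by a pseudocounted ratio (> fold is up, < 1/fold is down); a gene
    is labeled only when every tumor line agrees.
    """
    missing = [c for c in list(control_cols) + list(tumor_cols) if c not in fpkm.columns]
    if missing or not control_cols:
        raise ValueError(f"missing expression columns: {missing or 'control'}")
    control = fpkm[list(control_cols)].mean(axis=1)
    labels = pd.DataFrame(index=fpkm.index)
    for col in tumor_cols:
        ratio = (fpkm[col] + min_fpkm) / (control + min_fpkm)
        lab = pd.Series("none", index=fpkm.index, dtype=object)
        lab[ratio > fold] = "up"
        lab[ratio < 1.0 / fold] = "down"
        labels[col] = lab
    agree = labels.apply(lambda row: row.iloc[0] if row.nunique() == 1 else "none", axis=1)
    return agree.astype(object)


def mirna_differential_expression(
    rpm: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided t-test per miRNA on log2(RPM + 1), BH-adjusted.

    ``groups`` maps sample (column) to tumor/normal.  Direction is the sign
    of the tumor-minus-normal mean on the log scale; genes with zero
    variance in both groups and equal means get p = 1.
    """
    tumor_cols = [c for c in rpm.columns if groups[c] == "tumor"]
    normal_cols = [c for c in rpm.columns if groups[c] == "normal"]
    if len(tumor_cols) < 2 or len(normal_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    x = np.log2(rpm[tumor_cols].to_numpy(dtype=float) + 1.0)
    y = np.log2(rpm[normal_cols].to_numpy(dtype=float) + 1.0)
    t, p = stats.ttest_ind(x, y, axis=1)
    flat = np.isnan(p)
    t = np.where(flat, 0.0, t)
    p = np.where(flat, 1.0, p)
    q = adjust_bh(p)
    diff = x.mean(axis=1) - y.mean(axis=1)
    direction = np.where(diff > 0, "up", np.where(diff < 0, "down", "none"))
    return pd.DataFrame(
        {
            "t": t,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "significant": q < alpha,
        },
        index=rpm.index,
    )


def call_candidates(
    methylation_calls: Mapping[str, str],
    expression_directions: Mapping[str, str],
) -> list[RegulationCandidate]:
    """Opposing-direction intersection of methylation and expression.

    hyper + down -> silencing; hypo + up -> activating.  Genes moving in
    the same direction are dropped (counted in the log).
    """
    candidates = []
    dropped = 0
    for gene_id, meth_dir in methylation_calls.items():
        expr_dir = expression_directions.get(gene_id)
        if expr_dir not in ("up", "down"):
            continue
        if meth_dir == "hyper" and expr_dir == "down":
            candidates.append(RegulationCandidate(gene_id, "silencing", meth_dir, expr_dir))
        elif meth_dir == "hypo" and expr_dir == "up":
            candidates.append(RegulationCandidate(gene_id, "activating", meth_dir, expr_dir))
        else:
            dropped += 1
    if dropped:
        logger.info("%d genes dropped for concordant methylation/expression", dropped)
    return candidates


def histone_concordance(
    promoters: dict[str, PromoterRegion],
    mark_tracks: Mapping[tuple[str, str], BinTrack],
    control_line: str,
    tumor_lines: Sequence[str],
    fold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Promoter histone-mark change labels per gene.

    For each mark, the summed promoter density in every tumor line is
    compared with the control line; the gene is labeled ``<mark>_up`` /
    ``<mark>_down`` when the pseudocounted ratio is >= fold (or <= 1/fold,
    boundary inclusive) in *all* tumor lines.
    """
    marks = sorted({m for m, _ in mark_tracks})
    for m in marks:
        if (m, control_line) not in mark_tracks:
            raise ValueError(f"missing control line track for mark {m}")

    def promoter_sum(track: BinTrack, prom: PromoterRegion) -> float:
        vec = track.data[prom.interval.chrom]
        bw = track.bin_width
        return float(vec[prom.interval.start // bw : -(-prom.interval.end // bw)].sum())

    rows = []
    for gene_id, prom in promoters.items():
        row: dict[str, object] = {"gene_id": gene_id}
        for m in marks:
            ctrl = promoter_sum(mark_tracks[(m, control_line)], prom)
            ratios = [
                (promoter_sum(mark_tracks[(m, line)], prom) + pseudocount)
                / (ctrl + pseudocount)
                for line in tumor_lines
            ]
            if all(r >= fold for r in ratios):
                row[m] = "up"
            elif all(r <= 1.0 / fold for r in ratios):
                row[m] = "down"
            else:
                row[m] = "none"
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def promoter_methylation_matrix(
    tracks: Sequence[BinTrack],
    promoters: dict[str, PromoterRegion],
    gene_ids: Sequence[str],
) -> pd.DataFrame:
    """Mean normalized methylation over each gene's promoter, per sample.

    Rows = genes, columns = samples; the panel feature matrix.
    """
    data = {}
    for t in tracks:
        col = []
        for g in gene_ids:
            prom = promoters[g].interval
            vec = t.data[prom.chrom]
            bw = t.bin_width
            col.append(float(vec[prom.start // bw : -(-prom.end // bw)].mean()))
        data[t.sample_id] = col
    return pd.DataFrame(data, index=pd.Index(list(gene_ids), name="gene_id"))


def zscore_panel(
    feature_matrix: pd.DataFrame,
    feature_directions: Mapping[str, int],
) -> pd.Series:
    """Per-sample panel score: mean of direction-signed feature Z-scores.

    Rows are features, columns samples.  Z uses the sample standard
    deviation (ddof 1) across samples; zero-variance features are dropped
    with a warning; directions are +1 (higher in cancer) or -1 (lower).
    """
    if feature_matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to Z-transform")
    signed = []
    for gene_id, values in feature_matrix.iterrows():
        sd = values.std(ddof=1)
        if sd == 0:
            logger.warning("feature %s has zero variance: dropped from panel", gene_id)
            continue
        z = (values - values.mean()) / sd
        signed.append(z * int(feature_directions[gene_id]))
    if not signed:
        raise ValueError("no usable features in panel")
    return pd.concat(signed, axis=1).mean(axis=1)


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points at every distinct threshold plus AUC.

    AUC equals the Mann-Whitney probability that a positive outscores a
    negative, with ties counted 1/2.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    points = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return points, float(roc_auc_score(labels, scores))
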