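"""Functional similarity between gene groups and term enrichment.

Supports guilt-by-association analysis of methylation-pattern gene groups:
pairwise gene similarity is the Jaccard index of annotation-term sets,
group-level similarity is the symmetric best-match average (each gene's
maximum similarity to the other group, averaged in both directions), and
the cross-group score is normalized against the two within-group scores as
``2*S(A,B) / (S(A,A) + S(B,B))``.  Term over-representation uses a
one-sided Fisher exact test with BH adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import adjust_bh

logger = logging.getLogger(__name__)

AnnotationMap = Mapping[str, frozenset]


def read_annotation_map(path: str) -> dict[str, frozenset]:
    """Two-column gene -> term TSV into a gene -> term-set map."""
    mapping: dict[str, set] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return {g: frozenset(t) for g, t in mapping.items()}


def gene_pair_similarity(g1: str, g2: str, annotation: AnnotationMap) -> float:
    """Jaccard index of the two genes' term sets."""
    for g in (g1, g2):
        if g not in annotation or not annotation[g]:
            raise KeyError(f"gene {g!r} has no annotation")
    t1, t2 = annotation[g1], annotation[g2]
    return len(t1 & t2) / len(t1 | t2)


def _annotated(group: Iterable[str], annotation: AnnotationMap) -> list[str]:
    genes = list(group)
    kept = [g for g in genes if g in annotation and annotation[g]]
    if len(kept) < len(genes):
        logger.info("%d unannotated genes excluded from similarity", len(genes) - len(kept))
    return kept


def set_similarity(
    group_a: Sequence[str], group_b: Sequence[str], annotation: AnnotationMap
) -> float:
    """Symmetric best-match-average similarity between two gene groups.

    For the self comparison of a multi-gene group, each gene's best match
    excludes itself; a singleton self-set scores 1.
    """
    a = _annotated(group_a, annotation)
    b = _annotated(group_b, annotation)
    if not a or not b:
        raise ValueError("each group needs >= 1 annotated gene")
    self_compare = sorted(a) == sorted(b)
    if self_compare and len(a) == 1:
        return 1.0

    def best_mean(src: list[str], dst: list[str]) -> float:
        best = []
        for g in src:
            cands = [h for h in dst if not (self_compare and h == g)]
            best.append(max(gene_pair_similarity(g, h, annotation) for h in cands))
        return float(np.mean(best))

    return 0.5 * (best_mean(a, b) + best_mean(b, a))


def normalized_similarity(
    group_a: Sequence[str], group_b: Sequence[str], annotation: AnnotationMap
) -> float:
    """Cross-group similarity normalized to the two within-group scores:
    ``2*S(A,B)/(S(A,A)+S(B,B))``."""
    saa = set_similarity(group_a, group_a, annotation)
    sbb = set_similarity(group_b, group_b, annotation)
    if saa + sbb == 0:
        raise ZeroDivisionError("both intra-class similarities are zero")
    return 2.0 * set_similarity(group_a, group_b, annotation) / (saa + sbb)


@dataclass(frozen=True)
class SimilarityResult:
    group_a: str
    group_b: str
    raw: float
    normalized: float
    n_a: int
    n_b: int


def group_similarity_matrix(
    groups: Mapping[str, Sequence[str]], annotation: AnnotationMap
) -> list[SimilarityResult]:
    """All pairwise (including self) group similarities."""
    names = sorted(groups)
    out = []
    for i, a in enumerate(names):
        for b in names[i:]:
            raw = set_similarity(groups[a], groups[b], annotation)
            norm = normalized_similarity(groups[a], groups[b], annotation)
            out.append(
                SimilarityResult(
                    a, b, raw, norm,
                    len(_annotated(groups[a], annotation)),
                    len(_annotated(groups[b], annotation)),
                )
            )
    return out


def term_enrichment(
    gene_set: Sequence[str],
    universe: Sequence[str],
    annotation: AnnotationMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term over-representation of ``gene_set`` within ``universe``.

    One-sided Fisher exact on the 2x2 membership table, BH across terms;
    terms annotating no universe gene are skipped.
    """
    gene_set = list(gene_set)
    universe = list(universe)
    if not gene_set:
        raise ValueError("empty gene set")
    if not set(gene_set) <= set(universe):
        raise ValueError("gene_set must be contained in universe")
    terms: dict[str, set] = {}
    for g in universe:
        for t in annotation.get(g, ()):  # unannotated genes contribute nothing
            terms.setdefault(t, set()).add(g)
    in_set = set(gene_set)
    rows = []
    for term, members in sorted(terms.items()):
        a = len(members & in_set)
        b = len(in_set - members)
        c = len(members - in_set)
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"term": term, "n_set": a, "n_universe": len(members),
                     "odds_ratio": odds, "p_value": p})
    df = pd.DataFrame(rows).set_index("term")
    df["q_value"] = adjust_bh(df["p_value"].to_numpy())
    df["significant"] = df["q_value"] < alpha
    return df.sort_values("p_value")
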