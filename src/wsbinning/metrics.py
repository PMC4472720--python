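"""Evaluation statistics: missing-branch (FN) rate, branch-length ratios,
per-triplet Jensen-Shannon divergence with its ECDF, and support-ordered
edge-quality curves.

JS divergence uses the natural logarithm by default (bound ln 2); the base is
exposed because the ECDF shape is invariant up to that scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .summarize import TripletDistribution
from .treeio import SupportTree, TreeError, bipartitions, splits

__all__ = [
    "fn_rate",
    "branch_length_ratios",
    "js_divergence",
    "triplet_js_divergence",
    "ecdf",
    "edge_quality_curve",
    "EdgeQualityCurve",
    "write_triplet_divergence_tsv",
    "write_branch_ratio_tsv",
    "MetricsReport",
    "metrics_report",
]


def fn_rate(true_tree: SupportTree, est_tree: SupportTree) -> float:
    """Fraction of the true tree's internal branches missing from the estimate."""
    if true_tree.leaf_labels != est_tree.leaf_labels:
        raise TreeError("trees must share a leaf set")
    true_splits = splits(true_tree)
    if not true_splits:
        raise TreeError("true tree has no internal branches")
    est_splits = splits(est_tree)
    return len(true_splits - est_splits) / len(true_splits)


def branch_length_ratios(
    true_tree: SupportTree, est_tree: SupportTree
) -> List[Tuple[object, float]]:
    """Estimated/true length ratio for every true branch present in the
    estimate (1.0 = perfect; < 1 means under-estimated lengths)."""
    if true_tree.leaf_labels != est_tree.leaf_labels:
        raise TreeError("trees must share a leaf set")
    true_map = {b: length for b, _, length in bipartitions(true_tree)}
    est_map = {b: length for b, _, length in bipartitions(est_tree)}
    out: List[Tuple[object, float]] = []
    for bip, t_len in true_map.items():
        if bip not in est_map:
            continue
        e_len = est_map[bip]
        if t_len is None or e_len is None:
            raise TreeError("both trees must carry branch lengths on shared splits")
        if t_len == 0:
            raise TreeError(f"zero true length on shared split {bip}")
        out.append((bip, e_len / t_len))
    return out


def js_divergence(p: Sequence[float], q: Sequence[float], base: Optional[float] = None) -> float:
    """Jensen-Shannon divergence JS(P,Q) = (KL(P,M) + KL(Q,M)) / 2, M=(P+Q)/2.

    Natural log by default (0 <= JS <= ln 2); ``base`` rescales.  The 0*log 0
    convention makes every term finite.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have identical shape")
    m = 0.5 * (p + q)

    def kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / m[mask])))

    js = 0.5 * kl(p) + 0.5 * kl(q)
    if base is not None:
        js /= math.log(base)
    return max(js, 0.0)


def triplet_js_divergence(
    true_dist: TripletDistribution,
    est_dist: TripletDistribution,
    base: Optional[float] = None,
) -> Dict[Tuple[str, str, str], float]:
    """Per-triplet JS divergence between two triplet distributions.

    Triplets with no resolved observation in either distribution are skipped.
    """
    if true_dist.taxa != est_dist.taxa:
        raise TreeError("triplet distributions are over different taxon sets")
    out: Dict[Tuple[str, str, str], float] = {}
    for tr in true_dist.triplets():
        p = true_dist.frequencies(tr)
        q = est_dist.frequencies(tr)
        if p is None or q is None:
            continue
        out[tr] = js_divergence(p, q, base=base)
    return out


def ecdf(values: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: returns (sorted values, fraction at or below each)."""
    v = np.sort(np.asarray(list(values), dtype=float))
    if v.size == 0:
        return v, v
    y = np.arange(1, v.size + 1) / v.size
    return v, y


@dataclass
class EdgeQualityCurve:
    """Edges ordered best-to-worst: TP by descending support, then FP by
    ascending support.  ``high_support_fp`` counts FP edges above the flag
    threshold (the troublesome region)."""

    entries: List[Tuple[str, float]]  # ("TP"|"FP", support)
    high_support_fp: int
    flag_threshold: float

    def cumulative_fractions(self) -> np.ndarray:
        n = len(self.entries)
        return np.arange(1, n + 1) / n if n else np.array([])


def edge_quality_curve(
    est_trees: Sequence[SupportTree],
    true_tree: SupportTree,
    flag_threshold: float = 75.0,
) -> EdgeQualityCurve:
    """Pool the supported internal edges of the estimates and order them by
    quality against the true tree."""
    true_splits = splits(true_tree)
    tp: List[float] = []
    fp: List[float] = []
    for est in est_trees:
        for bip, support, _ in bipartitions(est):
            if support is None:
                raise TreeError("edge-quality curve needs supports on all edges")
            (tp if bip in true_splits else fp).append(support)
    entries = [("TP", s) for s in sorted(tp, reverse=True)]
    entries += [("FP", s) for s in sorted(fp)]
    return EdgeQualityCurve(
        entries=entries,
        high_support_fp=sum(1 for s in fp if s > flag_threshold),
        flag_threshold=flag_threshold,
    )


def write_triplet_divergence_tsv(divergences: Dict[Tuple[str, str, str], float], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon1\ttaxon2\ttaxon3\tjs_divergence\n")
        for (a, b, c), v in sorted(divergences.items()):
            fh.write(f"{a}\t{b}\t{c}\t{v:.10g}\n")


def write_branch_ratio_tsv(ratios: List[Tuple[object, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("split_side\tratio\n")
        for bip, r in ratios:
            side = ",".join(sorted(bip.side))
            fh.write(f"{side}\t{r:.10g}\n")


@dataclass
class MetricsReport:
    fn_rate: float
    rf_count: int
    bl_ratios: List[Tuple[object, float]] = field(default_factory=list)
    js_divergences: List[float] = field(default_factory=list)
    edge_quality: Optional[EdgeQualityCurve] = None


def metrics_report(
    true_tree: SupportTree,
    est_tree: SupportTree,
    true_dist: Optional[TripletDistribution] = None,
    est_dist: Optional[TripletDistribution] = None,
) -> MetricsReport:
    from .treeio import rf_distance

    count, _ = rf_distance(true_tree, est_tree)
    report = MetricsReport(fn_rate=fn_rate(true_tree, est_tree), rf_count=count)
    try:
        report.bl_ratios = branch_length_ratios(true_tree, est_tree)
    except TreeError:
        report.bl_ratios = []
    if true_dist is not None and est_dist is not None:
        report.js_divergences = list(
            triplet_js_divergence(true_dist, est_dist).values()
        )
    return report
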