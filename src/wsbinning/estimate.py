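"""Lightweight in-house gene-tree estimation: JC distances, neighbor joining,
and nonparametric site bootstrapping with support annotation.

NJ on JC distances is statistically consistent for JC data, which is all the
end-to-end property suite needs; heavier ML estimation is delegated to the
external adapter in :mod:`wsbinning.supergene`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .treeio import Alignment, Node, SupportTree, TreeError, bipartitions, splits

__all__ = [
    "DistanceMatrix",
    "BootstrapResult",
    "jc_distance_matrix",
    "nj_tree",
    "bootstrap_gene_tree",
]

JC_DISTANCE_CAP = 5.0


@dataclass
class DistanceMatrix:
    taxa: List[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise TreeError("distance matrix shape does not match taxa")
        if not np.allclose(v, v.T, atol=1e-12):
            raise TreeError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise TreeError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise TreeError("distances must be non-negative")
        self.values = v


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(aln: Alignment, taxa: Sequence[str]) -> np.ndarray:
    mat = np.empty((len(taxa), aln.length), dtype=np.int8)
    for i, t in enumerate(taxa):
        mat[i] = [_CODE.get(ch, 4) for ch in aln.sequences[t]]
    return mat


def jc_distance_matrix(aln: Alignment, columns: np.ndarray | None = None) -> DistanceMatrix:
    """Jukes-Cantor distances, ignoring columns with a gap or N in either row.

    Saturated pairs (mismatch fraction >= 0.75) are capped at 5.0.
    ``columns`` optionally selects (with repetition) the columns to use — the
    hook the bootstrap resampler uses.
    """
    taxa = list(aln.taxa)
    if len(taxa) < 2:
        raise TreeError("need at least two taxa")
    mat = _encode(aln, taxa)
    if columns is not None:
        mat = mat[:, columns]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] < 4) & (mat[j] < 4)
            m = int(ok.sum())
            if m == 0:
                raise TreeError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}"
                )
            p_hat = float((mat[i, ok] != mat[j, ok]).mean())
            if p_hat >= 0.75:
                dist = JC_DISTANCE_CAP
            else:
                dist = -0.75 * math.log(1.0 - 4.0 * p_hat / 3.0)
                dist = min(dist, JC_DISTANCE_CAP)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=taxa, values=d)


def nj_tree(dm: DistanceMatrix) -> SupportTree:
    """Canonical neighbor joining (Saitou-Nei with the Studier-Keppler Q).

    Deterministic: the minimum-Q pair is chosen by scanning in taxon order;
    negative estimated branch lengths are clamped to zero.  Returns an
    unrooted tree (trifurcating root), without supports.
    """
    n = len(dm.taxa)
    if n < 3:
        raise TreeError("neighbor joining needs at least three taxa")
    nodes: List[Node] = [Node(label=t) for t in dm.taxa]
    d = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                qv = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or qv < best[0] - 1e-12:
                    best = (qv, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        merged = Node(children=[child_i, child_j])
        # distances from the new node
        d = np.pad(d, ((0, 1), (0, 1)))
        new_idx = d.shape[0] - 1
        for m in active:
            if m in (i, j):
                continue
            d[new_idx, m] = d[m, new_idx] = 0.5 * (d[i, m] + d[j, m] - d[i, j])
        nodes.append(merged)
        active = [m for m in active if m not in (i, j)] + [new_idx]

    # final three-way join
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
    root = Node(children=[nodes[i], nodes[j], nodes[k]])
    return SupportTree(root, rooted=False)


@dataclass
class BootstrapResult:
    point_tree: SupportTree  # supports attached
    replicate_trees: List[SupportTree]


def _attach_supports(point: SupportTree, replicates: Sequence[SupportTree]) -> SupportTree:
    out = point.copy()
    rep_splits = [splits(t) for t in replicates]
    full = out.leaf_labels
    from .treeio import Bipartition, _leafsets

    leafsets = _leafsets(out.root)
    n = len(full)
    for node in out.root.postorder():
        if node.is_leaf or node is out.root:
            continue
        under = leafsets[id(node)]
        if not (2 <= len(under) <= n - 2):
            continue
        bip = Bipartition(under, full)
        freq = sum(bip in s for s in rep_splits) / len(replicates)
        node.support = 100.0 * freq
    return out


def bootstrap_gene_tree(aln: Alignment, b: int, seed: int) -> BootstrapResult:
    """Point NJ tree plus ``b`` site-resampled replicates.

    Each internal edge of the point tree is annotated with 100 x (fraction of
    replicates containing its split).  One master seed spawns independent
    per-replicate column streams, so growing ``b`` never perturbs earlier
    replicates.
    """
    if b < 1:
        raise TreeError("need at least one bootstrap replicate")
    point = nj_tree(jc_distance_matrix(aln))
    streams = np.random.SeedSequence(seed).spawn(b)
    replicates: List[SupportTree] = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        cols = rng.integers(aln.length, size=aln.length)
        replicates.append(nj_tree(jc_distance_matrix(aln, columns=cols)))
    return BootstrapResult(
        point_tree=_attach_supports(point, replicates),
        replicate_trees=replicates,
    )
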