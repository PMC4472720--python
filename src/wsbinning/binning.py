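"""Threshold compatibility, the incompatibility graph, and balanced coloring.

Two genes conflict when their trees carry incompatible branches *both*
supported at or above the threshold B (equivalently: after contracting every
edge with support strictly below B, the two trees have no common refinement).
Since pairwise split compatibility implies setwise compatibility, the test
reduces to checking every cross pair of retained splits.

Bins are the color classes of a clique-seeded, balance-greedy variant of the
Brelaz (DSATUR) vertex-coloring heuristic.  The only randomized step is the
bin-size tie during placement; it is driven by a caller-supplied seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

from .treeio import (
    LeafSetMismatchError,
    SupportTree,
    collapse_low_support,
    splits,
)

__all__ = [
    "IncompatibilityGraph",
    "Binning",
    "thresholded_splits",
    "are_compatible",
    "build_incompatibility_graph",
    "seed_clique",
    "balanced_color",
    "weight_bins",
    "unweighted_output",
    "write_bin_table",
    "read_bin_table",
]


def thresholded_splits(tree: SupportTree, threshold: float) -> frozenset:
    """Splits surviving contraction of edges with support < threshold."""
    return splits(collapse_low_support(tree, threshold))


def _splits_compatible(s1: frozenset, s2: frozenset) -> bool:
    for a in s1:
        for b in s2:
            if not a.is_compatible_with(b):
                return False
    return True


def are_compatible(t1: SupportTree, t2: SupportTree, threshold: float) -> bool:
    """True iff the two trees, after collapsing low-support edges, share a
    common refinement."""
    if t1.leaf_labels != t2.leaf_labels:
        raise LeafSetMismatchError(
            f"cannot compare trees on different leaf sets: "
            f"{sorted(t1.leaf_labels ^ t2.leaf_labels)} not shared"
        )
    return _splits_compatible(
        thresholded_splits(t1, threshold), thresholded_splits(t2, threshold)
    )


class IncompatibilityGraph:
    """Undirected graph over gene indices 0..p-1; edge = significant conflict.

    Vertex order is the input gene order, which anchors every downstream
    tie-breaking rule.
    """

    def __init__(self, n_vertices: int):
        self.n = n_vertices
        self.adj: List[set] = [set() for _ in range(n_vertices)]

    def add_edge(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("self-loop in incompatibility graph")
        self.adj[i].add(j)
        self.adj[j].add(i)

    def has_edge(self, i: int, j: int) -> bool:
        return j in self.adj[i]

    def degree(self, i: int) -> int:
        return len(self.adj[i])

    def edges(self) -> List[tuple]:
        return [(i, j) for i in range(self.n) for j in sorted(self.adj[i]) if i < j]

    @property
    def vertices(self) -> range:
        return range(self.n)

    def to_dot(self, names: Sequence[str] | None = None) -> str:
        names = list(names) if names is not None else [f"g{i}" for i in range(self.n)]
        lines = ["graph incompatibility {"]
        for i in range(self.n):
            lines.append(f'  "{names[i]}";')
        for i, j in self.edges():
            lines.append(f'  "{names[i]}" -- "{names[j]}";')
        lines.append("}")
        return "\n".join(lines)


def build_incompatibility_graph(
    trees: Sequence[SupportTree], threshold: float
) -> IncompatibilityGraph:
    """One vertex per gene; an edge joins genes whose trees conflict at B.

    Collapsed split sets are computed once per tree, so the pairwise stage
    costs O(p^2) split-set comparisons.
    """
    graph = IncompatibilityGraph(len(trees))
    leafset = None
    cached: List[frozenset] = []
    for idx, tree in enumerate(trees):
        if leafset is None:
            leafset = tree.leaf_labels
        elif tree.leaf_labels != leafset:
            raise LeafSetMismatchError(
                f"gene {idx} is on a different leaf set than gene 0"
            )
        try:
            cached.append(thresholded_splits(tree, threshold))
        except Exception as exc:
            raise type(exc)(f"gene {idx}: {exc}") from exc
    for i in range(len(trees)):
        for j in range(i + 1, len(trees)):
            if not _splits_compatible(cached[i], cached[j]):
                graph.add_edge(i, j)
    return graph


def seed_clique(graph: IncompatibilityGraph) -> List[int]:
    """Greedy clique: repeatedly add the highest-degree vertex adjacent to all
    current members (ties -> lowest input index)."""
    if graph.n == 0:
        return []
    candidates = set(graph.vertices)
    clique: List[int] = []
    while candidates:
        best = min(candidates, key=lambda v: (-graph.degree(v), v))
        clique.append(best)
        candidates = candidates & graph.adj[best]
    return clique


@dataclass
class Binning:
    """Disjoint gene-index bins covering all vertices (a proper coloring)."""

    bins: List[List[int]]
    threshold: float

    @property
    def n_genes(self) -> int:
        return sum(len(b) for b in self.bins)

    @property
    def sizes(self) -> List[int]:
        return [len(b) for b in self.bins]

    def bin_of(self) -> Dict[int, int]:
        return {g: b for b, members in enumerate(self.bins) for g in members}


def balanced_color(graph: IncompatibilityGraph, threshold: float = 0.0,
                   seed: int = 42) -> Binning:
    """Clique-seeded balanced greedy coloring.

    Stage 1 assigns each seed-clique member its own bin (in input-index
    order).  Stage 2 repeatedly takes the unplaced gene in conflict with the
    most existing bins (ties -> lowest index) and drops it into the smallest
    conflict-free bin; bin-size ties are broken uniformly at random from the
    seeded RNG, and a new bin is opened only when no existing bin admits it.
    """
    rng = random.Random(seed)
    bins: List[List[int]] = [[g] for g in sorted(seed_clique(graph))]
    placed = {g for b in bins for g in b}
    unplaced = [v for v in graph.vertices if v not in placed]

    def conflicts_with_bin(gene: int, members: List[int]) -> bool:
        return any(graph.has_edge(gene, m) for m in members)

    while unplaced:
        scored = [
            (sum(conflicts_with_bin(g, b) for b in bins), g) for g in unplaced
        ]
        n_conf, gene = max(scored, key=lambda t: (t[0], -t[1]))
        unplaced.remove(gene)
        eligible = [i for i, b in enumerate(bins) if not conflicts_with_bin(gene, b)]
        if not eligible:
            bins.append([gene])
            continue
        smallest = min(len(bins[i]) for i in eligible)
        tied = [i for i in eligible if len(bins[i]) == smallest]
        choice = tied[0] if len(tied) == 1 else rng.choice(tied)
        bins[choice].append(gene)

    for b in bins:
        b.sort()
    return Binning(bins=bins, threshold=threshold)


def _check_supergene_trees(binning: Binning, supergene_trees: Mapping[int, SupportTree]):
    for b, members in enumerate(binning.bins):
        if members and b not in supergene_trees:
            raise ValueError(f"no supergene tree supplied for non-empty bin {b}")


def weight_bins(
    binning: Binning, supergene_trees: Mapping[int, SupportTree]
) -> List[SupportTree]:
    """Weighted output: the tree of bin b appears |b| times, bins in order."""
    _check_supergene_trees(binning, supergene_trees)
    out: List[SupportTree] = []
    for b, members in enumerate(binning.bins):
        out.extend([supergene_trees[b]] * len(members))
    return out


def unweighted_output(
    binning: Binning, supergene_trees: Mapping[int, SupportTree]
) -> List[SupportTree]:
    """Unweighted output: one tree per non-empty bin, in bin order."""
    _check_supergene_trees(binning, supergene_trees)
    return [supergene_trees[b] for b, members in enumerate(binning.bins) if members]


def write_bin_table(binning: Binning, path, gene_names: Sequence[str] | None = None) -> None:
    mapping = binning.bin_of()
    with open(path, "w") as fh:
        fh.write("gene_id\tbin_id\n")
        for g in sorted(mapping):
            name = gene_names[g] if gene_names is not None else f"g{g}"
            fh.write(f"{name}\t{mapping[g]}\n")


def read_bin_table(path) -> Dict[str, int]:
    out: Dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if line.strip():
                name, b = line.split("\t")
                out[name] = int(b)
    return out
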