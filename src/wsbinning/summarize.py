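"""Summary methods over tree collections: greedy consensus, rooted-triplet
distributions, the R* plurality-triplet supertree (via the Aho BUILD
algorithm), and site-only multi-locus bootstrap orchestration.

R* stands in for external coalescent-based summary tools: it selects, for
every taxon triplet, the plurality rooted topology across the input trees and
assembles the selected triplets into a supertree.  It is statistically
consistent given gene trees sampled under the multispecies coalescent.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .binning import Binning
from .treeio import (
    Bipartition,
    Node,
    SupportTree,
    TreeError,
    _leafsets,
    splits,
)

__all__ = [
    "TripletDistribution",
    "ReplicateSet",
    "greedy_consensus",
    "triplet_counts",
    "rstar_species_tree",
    "mlbs",
    "assemble_replicates",
]


# ---------------------------------------------------------------------------
# greedy consensus
# ---------------------------------------------------------------------------

def greedy_consensus(trees: Sequence[SupportTree]) -> SupportTree:
    """Greedy (extended majority-rule) consensus with frequency supports.

    Splits are sorted by frequency (most frequent first; ties broken by a
    deterministic lexicographic split order) and added when compatible with
    everything already kept.  Retained splits carry support = 100 x frequency.
    """
    if not trees:
        raise TreeError("greedy consensus of an empty tree list")
    full = trees[0].leaf_labels
    for i, t in enumerate(trees[1:], start=1):
        if t.leaf_labels != full:
            raise TreeError(f"tree {i} has a different leaf set than tree 0")
    counts: Counter = Counter()
    for t in trees:
        counts.update(splits(t))

    def sort_key(item: Tuple[Bipartition, int]):
        bip, c = item
        return (-c, tuple(sorted(bip.side)))

    kept: List[Tuple[Bipartition, float]] = []
    for bip, c in sorted(counts.items(), key=sort_key):
        if all(bip.is_compatible_with(k) for k, _ in kept):
            kept.append((bip, 100.0 * c / len(trees)))
    return _tree_from_splits(kept, full)


def _tree_from_splits(
    weighted_splits: Sequence[Tuple[Bipartition, float]], full: frozenset
) -> SupportTree:
    """Build the (unrooted) tree displaying a pairwise-compatible split set.

    Canonical sides all exclude the lexicographically smallest taxon r, so
    compatibility makes them a laminar family; the tree is the containment
    hierarchy hung next to r.
    """
    r = min(full)
    clusters = sorted(weighted_splits, key=lambda kv: -len(kv[0].side))
    nodes: List[Tuple[frozenset, Node]] = []
    root = Node()

    def parent_node(side: frozenset) -> Node:
        best = None
        for cl_side, cl_node in nodes:
            if side < cl_side and (best is None or len(cl_side) < len(best[0])):
                best = (cl_side, cl_node)
        return best[1] if best else root

    for bip, support in clusters:
        node = Node(support=support)
        parent_node(bip.side).children.append(node)
        nodes.append((bip.side, node))
    for leaf in sorted(full):
        if leaf == r:
            root.children.insert(0, Node(label=leaf))
        else:
            parent_node(frozenset([leaf])).children.append(Node(label=leaf))
    return SupportTree(root, rooted=False)


# ---------------------------------------------------------------------------
# triplet distributions
# ---------------------------------------------------------------------------

@dataclass
class TripletDistribution:
    """Counts of the three rooted resolutions per taxon triplet.

    For the sorted triplet (a, b, c), topology index 0 is ab|c (cherry a,b),
    1 is ac|b, and 2 is bc|a.  Unresolved observations are tracked separately.
    """

    taxa: Tuple[str, ...]
    counts: Dict[Tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    unresolved: Dict[Tuple[str, str, str], int] = field(default_factory=dict)
    n_trees: int = 0

    def frequencies(self, triplet: Tuple[str, str, str]) -> Optional[np.ndarray]:
        c = self.counts[triplet]
        total = c.sum()
        if total == 0:
            return None
        return c / total

    def triplets(self) -> List[Tuple[str, str, str]]:
        return sorted(self.counts)


def _pair_mrca_depths(tree: SupportTree) -> Dict[frozenset, int]:
    """Depth (root=0) of the MRCA of every leaf pair."""
    depths: Dict[frozenset, int] = {}
    node_depth: Dict[int, int] = {id(tree.root): 0}
    for node in tree.root.preorder():
        for child in node.children:
            node_depth[id(child)] = node_depth[id(node)] + 1
    leafsets = _leafsets(tree.root)
    for node in tree.root.preorder():
        if node.is_leaf:
            continue
        d = node_depth[id(node)]
        kids = [leafsets[id(c)] for c in node.children]
        for s1, s2 in itertools.combinations(kids, 2):
            for x in s1:
                for y in s2:
                    depths[frozenset((x, y))] = d
    return depths


def triplet_counts(trees: Sequence[SupportTree]) -> TripletDistribution:
    """Tally the rooted triplet resolutions induced by each input tree."""
    if not trees:
        raise TreeError("no trees given")
    full = trees[0].leaf_labels
    taxa = tuple(sorted(full))
    dist = TripletDistribution(taxa=taxa, n_trees=len(trees))
    triplets = list(itertools.combinations(taxa, 3))
    for tr in triplets:
        dist.counts[tr] = np.zeros(3)
        dist.unresolved[tr] = 0
    for tree in trees:
        if not tree.rooted:
            raise TreeError("triplet extraction requires rooted trees")
        if tree.leaf_labels != full:
            raise TreeError("trees must share one leaf set")
        depths = _pair_mrca_depths(tree)
        for a, b, c in triplets:
            d_ab = depths[frozenset((a, b))]
            d_ac = depths[frozenset((a, c))]
            d_bc = depths[frozenset((b, c))]
            top = max(d_ab, d_ac, d_bc)
            if d_ab == d_ac == d_bc:
                dist.unresolved[(a, b, c)] += 1
            elif d_ab == top:
                dist.counts[(a, b, c)][0] += 1
            elif d_ac == top:
                dist.counts[(a, b, c)][1] += 1
            else:
                dist.counts[(a, b, c)][2] += 1
    return dist


# ---------------------------------------------------------------------------
# R* supertree via BUILD
# ---------------------------------------------------------------------------

def _plurality_triplets(dist: TripletDistribution) -> List[Tuple[str, str, str]]:
    """Strict-plurality rooted triplets as (in1, in2, out); ties are omitted."""
    selected = []
    for tr in dist.triplets():
        c = dist.counts[tr]
        if c.sum() == 0:
            continue
        order = np.argsort(-c)
        if c[order[0]] - c[order[1]] <= 0:
            continue  # tie -> conservative omission
        a, b, cc = tr
        winner = int(order[0])
        if winner == 0:
            selected.append((a, b, cc))
        elif winner == 1:
            selected.append((a, cc, b))
        else:
            selected.append((b, cc, a))
    return selected


def rstar_species_tree(dist: TripletDistribution) -> SupportTree:
    """Aho BUILD supertree of the strict-plurality triplets.

    Components that cannot be separated yield polytomies rather than failure.
    """
    taxa = list(dist.taxa)
    if len(taxa) < 3:
        raise TreeError("need at least three taxa")
    constraints = _plurality_triplets(dist)

    def build(subset: List[str]) -> Node:
        if len(subset) == 1:
            return Node(label=subset[0])
        if len(subset) == 2:
            return Node(children=[Node(label=subset[0]), Node(label=subset[1])])
        inset = set(subset)
        parent = {t: t for t in subset}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x, y):
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[rx] = ry

        for a, b, out in constraints:
            if a in inset and b in inset and out in inset:
                union(a, b)
        comps: Dict[str, List[str]] = {}
        for t in subset:
            comps.setdefault(find(t), []).append(t)
        components = sorted(comps.values(), key=lambda c: sorted(c)[0])
        if len(components) == 1:
            return Node(children=[Node(label=t) for t in sorted(subset)])  # polytomy
        return Node(children=[build(sorted(c)) for c in components])

    return SupportTree(build(sorted(taxa)), rooted=True)


# ---------------------------------------------------------------------------
# multi-locus bootstrapping
# ---------------------------------------------------------------------------

@dataclass
class ReplicateSet:
    """b replicates, each containing exactly one tree per gene/supergene."""

    replicates: List[List[SupportTree]]

    def __post_init__(self):
        if not self.replicates:
            raise TreeError("empty replicate set")
        length = len(self.replicates[0])
        if any(len(r) != length for r in self.replicates):
            raise TreeError("ragged replicate lists")

    @property
    def b(self) -> int:
        return len(self.replicates)


def assemble_replicates(
    per_unit_bootstrap: Mapping[object, Sequence[SupportTree]],
    weighting: Optional[Binning] = None,
) -> ReplicateSet:
    """Assemble index-wise MLBS replicates.

    Without ``weighting``, keys are genes (or supergenes) and replicate i
    collects each unit's i-th bootstrap tree.  With a :class:`Binning`, keys
    must be bin indices and each supergene's tree is replicated bin-size
    times within every replicate.
    """
    if not per_unit_bootstrap:
        raise TreeError("no bootstrap trees supplied")
    lengths = {len(v) for v in per_unit_bootstrap.values()}
    if len(lengths) != 1:
        raise TreeError(f"unequal bootstrap counts across units: {sorted(lengths)}")
    (b,) = lengths
    if weighting is not None:
        order: List[object] = []
        for bin_idx, members in enumerate(weighting.bins):
            if not members:
                continue
            if bin_idx not in per_unit_bootstrap:
                raise TreeError(f"no bootstrap trees for bin {bin_idx}")
            order.extend([bin_idx] * len(members))
    else:
        order = list(per_unit_bootstrap)
    replicates = [[per_unit_bootstrap[u][i] for u in order] for i in range(b)]
    return ReplicateSet(replicates=replicates)


def mlbs(
    replicates: ReplicateSet,
    summary: Callable[[List[SupportTree]], SupportTree],
) -> SupportTree:
    """Site-only MLBS: summarise each replicate, then take the greedy
    consensus of the per-replicate species trees (supports = frequencies)."""
    species_trees = [summary(r) for r in replicates.replicates]
    return greedy_consensus(species_trees)


def rstar_summary(trees: List[SupportTree]) -> SupportTree:
    """Convenience summary callable: triplet tally + R* supertree."""
    return rstar_species_tree(triplet_counts(trees))
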