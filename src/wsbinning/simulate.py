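"""Synthetic data: coalescent gene trees inside a species tree, and
GTR+Gamma sequence evolution down gene trees.

Species-tree branch lengths are read directly in coalescent units: within a
branch, k lineages coalesce at rate k(k-1)/2 per unit.  Simulated gene trees
are ultrametric in coalescent time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .treeio import (
    Alignment,
    Node,
    SupportTree,
    TreeError,
    rf_distance,
    rooted_clade_distance,
)

__all__ = [
    "SpeciesTreeModel",
    "GTRSimParams",
    "JC_PARAMS",
    "make_caterpillar_species_tree",
    "fifteen_taxon_model",
    "FIFTEEN_TAXON_RATE_SCALE",
    "simulate_gene_trees",
    "simulate_sequences",
    "discordance",
    "random_binary_topology",
    "set_all_supports",
]


# ---------------------------------------------------------------------------
# species-tree model
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTreeModel:
    """A rooted, ultrametric species tree with coalescent-unit branch lengths."""

    tree: SupportTree
    theta: Optional[float] = None
    _heights: Dict[int, float] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.tree.rooted:
            raise TreeError("species-tree model requires a rooted tree")
        for node in self.tree.root.postorder():
            if node is self.tree.root:
                continue
            if node.length is None or (not node.is_leaf and node.length <= 0):
                raise TreeError("species tree needs positive internal branch lengths")
        self._heights = self._compute_heights()

    def _compute_heights(self) -> Dict[int, float]:
        heights: Dict[int, float] = {}
        for node in self.tree.root.postorder():
            if node.is_leaf:
                heights[id(node)] = 0.0
            else:
                hs = [heights[id(c)] + (c.length or 0.0) for c in node.children]
                if max(hs) - min(hs) > 1e-9:
                    raise TreeError("species tree must be ultrametric in coalescent units")
                heights[id(node)] = hs[0]
        return heights

    def height_of(self, node: Node) -> float:
        return self._heights[id(node)]


def make_caterpillar_species_tree(
    n: int = 15, internal_len: float = 0.1
) -> SpeciesTreeModel:
    """Rooted ultrametric caterpillar on ``s01..sNN`` with n-3 successive
    internal branches of ``internal_len`` coalescent units.

    The cherry (x, y) at the tip of the ladder sits at height ``internal_len``
    so its two pendant branches also have that length, matching the
    "all short branches in succession" construction.
    """
    if n < 4:
        raise TreeError("a caterpillar species tree needs at least 4 taxa")
    labels = [f"s{i:02d}" for i in range(1, n + 1)]
    h = internal_len
    node = Node(children=[Node(label=labels[0], length=h), Node(label=labels[1], length=h)])
    height = h
    for lab in labels[2:]:
        height += internal_len
        node = Node(children=[node, Node(label=lab, length=height)])
        node.children[0].length = internal_len
    return SpeciesTreeModel(tree=SupportTree(node, rooted=True))


# ---------------------------------------------------------------------------
# multispecies coalescent
# ---------------------------------------------------------------------------

def _coalesce_in_interval(
    lineages: List[Tuple[Node, float]],
    t_start: float,
    t_end: float,
    rng: np.random.Generator,
) -> List[Tuple[Node, float]]:
    """Run the coalescent among ``lineages`` from t_start up to t_end
    (coalescent units; math.inf above the root)."""
    t = t_start
    lineages = list(lineages)
    while len(lineages) > 1:
        k = len(lineages)
        wait = rng.exponential(2.0 / (k * (k - 1)))
        if t + wait > t_end:
            break
        t += wait
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (node_i, h_i) = lineages[i]
        (node_j, h_j) = lineages[j]
        node_i.length = t - h_i
        node_j.length = t - h_j
        merged = Node(children=[node_i, node_j])
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append((merged, t))
    return lineages


def simulate_gene_trees(
    model: SpeciesTreeModel, p: int, seed: int
) -> List[SupportTree]:
    """Sample ``p`` rooted gene trees under the MSC (one lineage per species).

    Fully reproducible: the same (model, p, seed) gives identical trees.
    """
    if p < 1:
        raise TreeError("need at least one gene tree")
    rng = np.random.default_rng(seed)
    out: List[SupportTree] = []
    sp_root = model.tree.root
    for _ in range(p):
        surviving: Dict[int, List[Tuple[Node, float]]] = {}
        for node in sp_root.postorder():
            if node.is_leaf:
                pool = [(Node(label=node.label), 0.0)]
            else:
                pool = []
                for c in node.children:
                    pool.extend(surviving[id(c)])
            t_start = model.height_of(node)
            if node is sp_root:
                pool = _coalesce_in_interval(pool, t_start, math.inf, rng)
            else:
                t_end = t_start + (node.length or 0.0)
                pool = _coalesce_in_interval(pool, t_start, t_end, rng)
            surviving[id(node)] = pool
        ((root, _),) = surviving[id(sp_root)]
        out.append(SupportTree(root, rooted=True))
    return out


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class GTRSimParams:
    """GTR+Gamma parameters; the generator is normalised to mean rate 1 at
    stationarity, so branch lengths are expected substitutions per site."""

    exchangeabilities: Sequence[float] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)  # AC AG AT CG CT GT
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: Optional[float] = None
    n_categories: int = 4
    rate_scale: float = 1.0  # substitutions per coalescent unit

    def __post_init__(self):
        if abs(sum(self.base_freqs) - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        if any(r < 0 for r in self.exchangeabilities):
            raise ValueError("exchangeabilities must be non-negative")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")

    def rate_matrix(self) -> np.ndarray:
        pi = np.asarray(self.base_freqs, dtype=float)
        r = self.exchangeabilities
        q = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for rate, (i, j) in zip(r, pairs):
            q[i, j] = rate * pi[j]
            q[j, i] = rate * pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(pi @ np.diag(q))
        return q / mu

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.array([1.0])
        a = self.gamma_shape
        m = self.n_categories
        quantiles = (2 * np.arange(m) + 1) / (2 * m)
        rates = gamma_dist.ppf(quantiles, a, scale=1.0 / a)
        return rates / rates.mean()


JC_PARAMS = GTRSimParams()

FIFTEEN_TAXON_RATE_SCALE = 0.025
"""Substitutions per (2N-generation) coalescent unit for the 15-taxon preset:
theta = 4*N*mu = 0.05 makes one coalescent unit theta/2 = 0.025 expected
substitutions per site."""


def fifteen_taxon_model() -> SpeciesTreeModel:
    """The 15-taxon high-ILS preset: a caterpillar whose 12 successive internal
    branches are 0.005 expected substitutions per site under theta = 0.05.

    In the simulator's standard coalescent units (2N generations; k lineages
    coalesce at rate k(k-1)/2 per unit) that is 0.005 / (theta/2) = 0.2 per
    branch.  Protocols that quote these branches as "0.1" are using the
    theta-scaled (4N-generation) unit convention; the underlying model tree
    is the same.
    """
    return make_caterpillar_species_tree(15, internal_len=0.2)


def simulate_sequences(
    gene_tree: SupportTree, params: GTRSimParams, k: int, seed: int
) -> Alignment:
    """Evolve ``k`` i.i.d. sites down ``gene_tree`` under GTR(+Gamma).

    Gene-tree branch lengths are multiplied by ``params.rate_scale`` to
    convert coalescent units into expected substitutions per site.
    """
    if k < 1:
        raise TreeError("alignment length must be >= 1")
    rng = np.random.default_rng(seed)
    q = params.rate_matrix()
    cat_rates = params.category_rates()
    pi = np.asarray(params.base_freqs, dtype=float)

    site_cat = rng.integers(len(cat_rates), size=k)
    root_states = rng.choice(4, size=k, p=pi)
    rows: Dict[str, str] = {}

    def transition(parent_states: np.ndarray, branch_subs: float) -> np.ndarray:
        child = np.empty_like(parent_states)
        for c, rate in enumerate(cat_rates):
            mask = site_cat == c
            if not mask.any():
                continue
            p = expm(q * branch_subs * rate)
            cum = np.cumsum(p, axis=1)
            u = rng.random(mask.sum())
            rowcum = cum[parent_states[mask]]
            child[mask] = (u[:, None] > rowcum).sum(axis=1)
        return child

    def descend(node: Node, node_states: np.ndarray) -> None:
        if node.is_leaf:
            rows[node.label] = "".join(_BASES[node_states])
            return
        for child in node.children:
            subs = (child.length or 0.0) * params.rate_scale
            descend(child, transition(node_states, subs))

    descend(gene_tree.root, root_states)
    return Alignment(rows)


# ---------------------------------------------------------------------------
# discordance and random-topology helpers
# ---------------------------------------------------------------------------

def discordance(model: SpeciesTreeModel, gene_trees: Sequence[SupportTree]) -> float:
    """Mean normalized topological distance (percent) between the gene trees
    and the species tree.

    Uses unrooted split distance; for 3-taxon trees (whose unrooted view is
    split-free) the rooted-clade distance is used instead.
    """
    if not gene_trees:
        raise TreeError("no gene trees supplied")
    sp = model.tree
    total = 0.0
    for gt in gene_trees:
        if sp.n_leaves == 3:
            _, norm = rooted_clade_distance(sp, gt)
        else:
            _, norm = rf_distance(sp, gt)
        total += norm
    return 100.0 * total / len(gene_trees)


def random_binary_topology(
    labels: Sequence[str], rng: np.random.Generator, rooted: bool = True
) -> SupportTree:
    """A uniform-ish random binary topology built by random sequential joins."""
    if len(labels) < 2:
        raise TreeError("need at least two labels")
    nodes = [Node(label=l) for l in labels]
    while len(nodes) > (2 if rooted else 3):
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = Node(children=[nodes[i], nodes[j]])
        nodes = [nodes[m] for m in range(len(nodes)) if m not in (i, j)] + [merged]
    root = Node(children=nodes)
    return SupportTree(root, rooted=rooted)


def set_all_supports(tree: SupportTree, value: float) -> SupportTree:
    """Copy of ``tree`` with every internal edge's support set to ``value``."""
    out = tree.copy()
    for node in out.root.postorder():
        if not node.is_leaf and node is not out.root:
            node.support = value
    return out
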