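"""Supergene alignments, partition files, and a small exact partitioned ML solver.

The in-house solver is restricted to JC69 and exhaustive topology
enumeration (n <= 8).  It exists so that the decomposition

    fully-partitioned log L(topology) = sum over partitions of the
    per-partition optimised log-likelihood on that topology

is checkable exactly at desk scale; heavier models go through the external
command-line adapter.
"""

from __future__ import annotations

import math
import re
import subprocess
from dataclasses import dataclass
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .treeio import Alignment, Node, SupportTree, TreeError, parse_newick, write_alignment

__all__ = [
    "SupergeneAlignment",
    "PartitionedMLResult",
    "concatenate_bin",
    "write_partition_file",
    "parse_partition_file",
    "enumerate_unrooted_topologies",
    "fully_partitioned_ml_exhaustive",
    "unpartitioned_ml_exhaustive",
    "external_raxml_adapter",
]

MAX_EXHAUSTIVE_TAXA = 8
BRANCH_BOUNDS = (1e-8, 10.0)
LOGLIK_TOL = 1e-6
INIT_BRANCH = 0.1


# ---------------------------------------------------------------------------
# supergene assembly
# ---------------------------------------------------------------------------

@dataclass
class SupergeneAlignment:
    """Concatenated per-bin alignment plus 1-based inclusive gene coordinates."""

    alignment: Alignment
    partitions: Dict[str, Tuple[int, int]]  # gene_id -> (start, end)

    def __post_init__(self):
        expected = 1
        for gene, (start, end) in self.partitions.items():
            if start != expected or end < start:
                raise TreeError(
                    f"partition map not contiguous at {gene!r}: ({start},{end})"
                )
            expected = end + 1
        if expected - 1 != self.alignment.length:
            raise TreeError("partition map does not cover the alignment")


def concatenate_bin(
    alignments: Mapping[str, Alignment], bin_genes: Sequence[str]
) -> SupergeneAlignment:
    """Concatenate the alignments of a bin, in bin gene order.

    Taxa missing from a gene are filled with '-' across that gene's range;
    the union of taxa is taken across the bin.
    """
    if not bin_genes:
        raise TreeError("cannot concatenate an empty bin")
    if len(set(bin_genes)) != len(bin_genes):
        raise TreeError("duplicate gene in bin")
    taxa: List[str] = []
    for g in bin_genes:
        if g not in alignments:
            raise TreeError(f"no alignment for gene {g!r}")
        for t in alignments[g].taxa:
            if t not in taxa:
                taxa.append(t)
    taxa.sort()
    rows = {t: [] for t in taxa}
    partitions: Dict[str, Tuple[int, int]] = {}
    pos = 1
    for g in bin_genes:
        aln = alignments[g]
        for t in taxa:
            rows[t].append(aln.sequences.get(t, "-" * aln.length))
        partitions[g] = (pos, pos + aln.length - 1)
        pos += aln.length
    return SupergeneAlignment(
        alignment=Alignment({t: "".join(parts) for t, parts in rows.items()}),
        partitions=partitions,
    )


def write_partition_file(sa: SupergeneAlignment) -> str:
    """RAxML-style partition file text: one ``DNA, name = a-b`` line per gene."""
    return "".join(
        f"DNA, {gene} = {start}-{end}\n" for gene, (start, end) in sa.partitions.items()
    )


_PARTITION_LINE = re.compile(r"^DNA,\s*(\S+)\s*=\s*(\d+)-(\d+)\s*$")


def parse_partition_file(text: str) -> Dict[str, Tuple[int, int]]:
    out: Dict[str, Tuple[int, int]] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        m = _PARTITION_LINE.match(line.strip())
        if not m:
            raise TreeError(f"unparseable partition line: {line!r}")
        out[m.group(1)] = (int(m.group(2)), int(m.group(3)))
    return out


# ---------------------------------------------------------------------------
# topology enumeration
# ---------------------------------------------------------------------------

def enumerate_unrooted_topologies(taxa: Sequence[str]) -> Iterator[SupportTree]:
    """All unrooted binary topologies on the taxa (1, 3, 15, 105, ... trees).

    Trees are yielded with a trifurcating root (the unrooted convention) and
    no branch lengths or supports.
    """
    taxa = sorted(taxa)
    if len(taxa) < 3:
        raise TreeError("need at least 3 taxa to enumerate unrooted topologies")

    def build(current: Node, remaining: List[str]) -> Iterator[Node]:
        if not remaining:
            yield current.copy()
            return
        new_taxon, rest = remaining[0], remaining[1:]
        # insert the new leaf on every edge of the current tree
        parents = []
        for node in current.preorder():
            for child in node.children:
                parents.append((node, child))
        for parent, child in parents:
            idx = parent.children.index(child)
            joint = Node(children=[child, Node(label=new_taxon)])
            parent.children[idx] = joint
            yield from build(current, rest)
            parent.children[idx] = child  # undo

    base = Node(children=[Node(label=t) for t in taxa[:3]])
    for root in build(base, list(taxa[3:])):
        yield SupportTree(root, rooted=False)


# ---------------------------------------------------------------------------
# JC69 likelihood machinery
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _pattern_compress(aln: Alignment, taxa: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    """Column patterns (rows = taxa, codes 0-3, 4 = missing) and their counts."""
    mat = np.empty((len(taxa), aln.length), dtype=np.int8)
    for i, t in enumerate(taxa):
        row = aln.sequences[t]
        mat[i] = [_BASE_INDEX.get(c, 4) for c in row]
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def _jc_p_matrix(t: float) -> np.ndarray:
    e = math.exp(-4.0 * t / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


class _TopologyLik:
    """Pruning-algorithm JC69 log-likelihood for one topology and one
    pattern-compressed alignment, with per-edge branch lengths."""

    def __init__(self, tree: SupportTree, patterns: np.ndarray, counts: np.ndarray,
                 taxa: Sequence[str]):
        self.counts = counts
        # flatten the tree into postorder arrays
        nodes = list(tree.root.postorder())
        self.n_nodes = len(nodes)
        index = {id(n): i for i, n in enumerate(nodes)}
        self.root_idx = index[id(tree.root)]
        self.children: List[List[int]] = [[] for _ in nodes]
        self.leaf_row: List[Optional[int]] = [None] * len(nodes)
        self.edge_key: List[Optional[frozenset]] = [None] * len(nodes)
        taxon_row = {t: i for i, t in enumerate(taxa)}
        leafset: Dict[int, frozenset] = {}
        for i, n in enumerate(nodes):
            if n.is_leaf:
                self.leaf_row[i] = taxon_row[n.label]
                leafset[i] = frozenset([n.label])
            else:
                self.children[i] = [index[id(c)] for c in n.children]
                leafset[i] = frozenset().union(*(leafset[c] for c in self.children[i]))
            if n is not tree.root:
                self.edge_key[i] = leafset[i]
        self.edges = [i for i in range(len(nodes)) if i != self.root_idx]
        npat = patterns.shape[1]
        # leaf conditional likelihoods: one-hot, or all-ones for missing
        self.leaf_cl: Dict[int, np.ndarray] = {}
        for i in range(len(nodes)):
            row = self.leaf_row[i]
            if row is None:
                continue
            cl = np.zeros((npat, 4))
            codes = patterns[row]
            known = codes < 4
            cl[known, codes[known]] = 1.0
            cl[~known] = 1.0
            self.leaf_cl[i] = cl

    def _downs(self, lengths: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Postorder conditional likelihoods and per-edge messages to parents."""
        npat = self.counts.shape[0]
        down = np.empty((self.n_nodes, npat, 4))
        msg = np.empty_like(down)
        for i in range(self.n_nodes):
            if self.leaf_row[i] is not None:
                down[i] = self.leaf_cl[i]
            else:
                acc = np.ones((npat, 4))
                for c in self.children[i]:
                    acc = acc * msg[c]
                down[i] = acc
            if i != self.root_idx:
                msg[i] = down[i] @ _jc_p_matrix(lengths[i]).T
        return down, msg

    def _ups(self, msg: np.ndarray) -> np.ndarray:
        """Preorder 'rest of tree' partials; the 1/4 root prior is folded in,
        so the likelihood through any edge c is sum_x up[c] * msg[c]."""
        npat = self.counts.shape[0]
        up = np.empty((self.n_nodes, npat, 4))
        up[self.root_idx] = 0.25
        order = [self.root_idx]
        while order:
            v = order.pop()
            kids = self.children[v]
            for c in kids:
                acc = up[v].copy()
                for s in kids:
                    if s is not c:
                        acc *= msg[s]
                up[c] = acc
                if self.children[c]:
                    order.append(c)
        return up

    def loglik(self, lengths: np.ndarray) -> float:
        down, msg = self._downs(lengths)
        site = down[self.root_idx].sum(axis=1) * 0.25
        return float(self.counts @ np.log(site))

    def optimize(self) -> Tuple[float, np.ndarray]:
        """Coordinate ascent: each branch in turn, exploiting that the JC
        site likelihood is affine in exp(-4t/3) for cheap 1-D optimisation."""
        lengths = np.full(self.n_nodes, INIT_BRANCH)
        e_lo = math.exp(-4.0 * BRANCH_BOUNDS[1] / 3.0)
        e_hi = math.exp(-4.0 * BRANCH_BOUNDS[0] / 3.0)
        current = self.loglik(lengths)
        calm_sweeps = 0
        for _ in range(100):
            for edge in self.edges:
                down, msg = self._downs(lengths)
                up = self._ups(msg)
                d, u = down[edge], up[edge]
                big_d = d.sum(axis=1)
                alpha = 0.25 * big_d * u.sum(axis=1)
                beta = (d * u).sum(axis=1) - alpha

                def neg(ev):
                    return -float(self.counts @ np.log(alpha + beta * ev))

                res = minimize_scalar(
                    neg, bounds=(e_lo, e_hi), method="bounded",
                    options={"xatol": 1e-12},
                )
                lengths[edge] = -0.75 * math.log(float(res.x))
            new = self.loglik(lengths)
            if new - current < LOGLIK_TOL:
                calm_sweeps += 1
                if calm_sweeps >= 2:
                    break
            else:
                calm_sweeps = 0
            current = new
        return current, lengths


@dataclass
class PartitionedMLResult:
    """Best topology, per-partition optimised branch lengths, summed log-likelihood.

    Branch-length maps are keyed by the frozenset of leaves below each edge
    (pendant edges by the singleton leaf set).
    """

    topology: SupportTree
    per_partition_branch_lengths: Dict[str, Dict[frozenset, float]]
    log_likelihood: float
    per_topology_scores: Optional[Dict[str, float]] = None


def _partition_alignments(sa: SupergeneAlignment) -> Dict[str, Alignment]:
    out = {}
    for gene, (start, end) in sa.partitions.items():
        out[gene] = Alignment(
            {t: row[start - 1:end] for t, row in sa.alignment.sequences.items()}
        )
    return out


def _check_size(taxa: Sequence[str]) -> None:
    if len(taxa) > MAX_EXHAUSTIVE_TAXA:
        raise TreeError(
            f"exhaustive ML is limited to {MAX_EXHAUSTIVE_TAXA} taxa "
            f"(got {len(taxa)}); use the external adapter for larger problems"
        )


def fully_partitioned_ml_exhaustive(
    sa: SupergeneAlignment, model: str = "JC69"
) -> PartitionedMLResult:
    """Exhaustive search for the topology maximising the summed per-partition
    optimised JC69 log-likelihood (branch lengths free per partition)."""
    if model != "JC69":
        raise ValueError("the in-house solver supports JC69 only")
    if not sa.partitions:
        raise TreeError("need at least one partition")
    taxa = sorted(sa.alignment.taxa)
    _check_size(taxa)
    parts = _partition_alignments(sa)
    compressed = {g: _pattern_compress(a, taxa) for g, a in parts.items()}

    best = None
    for topo in enumerate_unrooted_topologies(taxa):
        total = 0.0
        lengths_by_gene: Dict[str, Dict[frozenset, float]] = {}
        machines = {}
        for gene, (patterns, counts) in compressed.items():
            machine = _TopologyLik(topo, patterns, counts, taxa)
            ll, lengths = machine.optimize()
            total += ll
            lengths_by_gene[gene] = {
                machine.edge_key[e]: float(lengths[e]) for e in machine.edges
            }
            machines[gene] = machine
        if best is None or total > best[0] + 1e-12:
            best = (total, topo, lengths_by_gene)
    total, topo, lengths_by_gene = best
    return PartitionedMLResult(
        topology=topo, per_partition_branch_lengths=lengths_by_gene,
        log_likelihood=total,
    )


def unpartitioned_ml_exhaustive(
    alignment: Alignment, model: str = "JC69"
) -> PartitionedMLResult:
    """Exhaustive JC69 ML with a single branch-length set shared by all sites."""
    if model != "JC69":
        raise ValueError("the in-house solver supports JC69 only")
    taxa = sorted(alignment.taxa)
    _check_size(taxa)
    patterns, counts = _pattern_compress(alignment, taxa)
    best = None
    for topo in enumerate_unrooted_topologies(taxa):
        machine = _TopologyLik(topo, patterns, counts, taxa)
        ll, lengths = machine.optimize()
        if best is None or ll > best[0] + 1e-12:
            best = (ll, topo, {machine.edge_key[e]: float(lengths[e]) for e in machine.edges})
    ll, topo, lengths = best
    return PartitionedMLResult(
        topology=topo,
        per_partition_branch_lengths={"all": lengths},
        log_likelihood=ll,
    )


def per_topology_partition_scores(
    sa: SupergeneAlignment,
) -> Dict[str, Dict[str, float]]:
    """For every topology (keyed by its Newick) the optimised log-likelihood of
    each partition — the raw table behind the summed-score decomposition."""
    from .treeio import write_newick

    taxa = sorted(sa.alignment.taxa)
    _check_size(taxa)
    parts = _partition_alignments(sa)
    compressed = {g: _pattern_compress(a, taxa) for g, a in parts.items()}
    table: Dict[str, Dict[str, float]] = {}
    for topo in enumerate_unrooted_topologies(taxa):
        key = write_newick(topo)
        table[key] = {}
        for gene, (patterns, counts) in compressed.items():
            machine = _TopologyLik(topo, patterns, counts, taxa)
            ll, _ = machine.optimize()
            table[key][gene] = ll
    return table


# ---------------------------------------------------------------------------
# external adapter
# ---------------------------------------------------------------------------

@dataclass
class RaxmlConfig:
    command_template: str = (
        "raxmlHPC-SSE3 -m GTRGAMMA -s {alignment} -n {name} -N 20 -M "
        "-q {partition_file} -p {seed}"
    )
    workdir: str = "."
    name: str = "supergene"
    seed: int = 42
    dry_run: bool = False


def external_raxml_adapter(sa: SupergeneAlignment, config: RaxmlConfig) -> Optional[SupportTree]:
    """Write the supergene inputs, render the configured command, run it and
    parse the resulting Newick.  ``dry_run`` stops after writing inputs."""
    import os
    import shutil

    aln_path = os.path.join(config.workdir, f"{config.name}.phylip")
    part_path = os.path.join(config.workdir, f"{config.name}.partitions")
    write_alignment(sa.alignment, aln_path, fmt="phylip")
    with open(part_path, "w") as fh:
        fh.write(write_partition_file(sa))
    command = config.command_template.format(
        alignment=aln_path, partition_file=part_path,
        name=config.name, seed=config.seed,
    )
    if config.dry_run:
        return None
    binary = command.split()[0]
    if shutil.which(binary) is None:
        raise RuntimeError(
            f"external tool {binary!r} not found on PATH; install it or use dry_run"
        )
    proc = subprocess.run(
        command.split(), cwd=config.workdir, capture_output=True, text=True
    )
    if proc.returncode != 0:
        raise RuntimeError(f"{binary} failed (exit {proc.returncode}): {proc.stderr}")
    result = os.path.join(config.workdir, f"RAxML_bestTree.{config.name}")
    with open(result) as fh:
        return parse_newick(fh.read())
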