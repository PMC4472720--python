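"""Support-annotated trees, alignments, and the split primitives shared by all modules.

Trees are stored rooted-as-read.  All bipartition/RF operations act on the
unrooted view of a tree; rooted operations (triplet extraction, coalescent
simulation) require ``rooted=True`` and raise otherwise.

Bootstrap supports live on internal edges, on a 0-100 scale, and are carried
on the child node of each edge.  An absent support is ``None`` — never 0.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import dendropy

__all__ = [
    "TreeError",
    "LeafSetMismatchError",
    "Node",
    "SupportTree",
    "Bipartition",
    "Alignment",
    "parse_newick",
    "write_newick",
    "read_tree_list",
    "write_tree_list",
    "bipartitions",
    "splits",
    "clades",
    "collapse_low_support",
    "rf_distance",
    "root_at_outgroup",
    "read_alignment",
    "write_alignment",
]

DNA_ALPHABET = frozenset("ACGT-N")


class TreeError(ValueError):
    """Validation failure on a tree or alignment."""


class LeafSetMismatchError(TreeError):
    """Two trees were compared that do not share a leaf set."""


# ---------------------------------------------------------------------------
# core tree structure
# ---------------------------------------------------------------------------

@dataclass
class Node:
    label: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: List["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaf_labels(self) -> List[str]:
        return [n.label for n in self.postorder() if n.is_leaf]

    def copy(self) -> "Node":
        return Node(
            label=self.label,
            length=self.length,
            support=self.support,
            children=[c.copy() for c in self.children],
        )


class SupportTree:
    """A (gene or species) tree with optional per-internal-edge bootstrap support."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        self._validate()

    def _validate(self) -> None:
        labels = self.root.leaf_labels()
        if any(lab is None or lab == "" for lab in labels):
            raise TreeError("every leaf must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate taxon labels: {dupes}")
        for node in self.root.postorder():
            if node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length {node.length}")
            if node.is_leaf and node.support is not None:
                raise TreeError("support on a leaf (pendant) edge")

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(self.root.leaf_labels())

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaf_labels())

    def copy(self) -> "SupportTree":
        return SupportTree(self.root.copy(), rooted=self.rooted)

    def internal_edges(self) -> List[Node]:
        """Child nodes of internal edges (every non-leaf node except the root)."""
        return [n for n in self.root.postorder() if not n.is_leaf and n is not self.root]

    def __repr__(self) -> str:  # pragma: no cover
        return f"SupportTree({write_newick(self)!r}, rooted={self.rooted})"


# ---------------------------------------------------------------------------
# bipartitions
# ---------------------------------------------------------------------------

class Bipartition:
    """A non-trivial unrooted split, canonicalised deterministically.

    The stored ``side`` is the half *not* containing the lexicographically
    smallest taxon, so two encodings of the same split compare (and hash) equal.
    """

    __slots__ = ("side", "full_set")

    def __init__(self, side: Iterable[str], full_set: Iterable[str]):
        full = frozenset(full_set)
        s = frozenset(side)
        if not s <= full:
            raise TreeError("bipartition side is not a subset of the leaf set")
        if min(full) in s:
            s = full - s
        if not (2 <= len(s) <= len(full) - 2):
            raise TreeError(f"trivial bipartition: |side|={len(s)} of n={len(full)}")
        self.side = s
        self.full_set = full

    def is_compatible_with(self, other: "Bipartition") -> bool:
        """Split compatibility: some quadrant A∩C, A∩D, B∩C, B∩D is empty."""
        a, b = self.side, self.full_set - self.side
        c, d = other.side, other.full_set - other.side
        return not (a & c) or not (a & d) or not (b & c) or not (b & d)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Bipartition)
            and self.side == other.side
            and self.full_set == other.full_set
        )

    def __hash__(self) -> int:
        return hash((self.side, self.full_set))

    def __repr__(self) -> str:  # pragma: no cover
        rest = ",".join(sorted(self.full_set - self.side))
        return f"Bipartition({'|'.join(sorted(self.side))} vs {rest})"


def _leafsets(root: Node) -> Dict[int, frozenset]:
    out: Dict[int, frozenset] = {}
    for node in root.postorder():
        if node.is_leaf:
            out[id(node)] = frozenset([node.label])
        else:
            out[id(node)] = frozenset().union(*(out[id(c)] for c in node.children))
    return out


def bipartitions(tree: SupportTree) -> List[Tuple[Bipartition, Optional[float], Optional[float]]]:
    """Non-trivial splits of the unrooted view, with the support and length
    carried by their edges.

    A degree-2 root contributes a single unrooted edge: the two root-child
    edges are merged (lengths summed, first available support kept).  Trees on
    fewer than four leaves have no non-trivial splits.
    """
    full = tree.leaf_labels
    if len(full) < 4:
        return []
    leafsets = _leafsets(tree.root)
    seen: Dict[Bipartition, Tuple[Optional[float], Optional[float]]] = {}
    order: List[Bipartition] = []
    for node in tree.root.postorder():
        if node is tree.root:
            continue
        under = leafsets[id(node)]
        if len(under) < 2 or len(full) - len(under) < 2:
            continue
        bip = Bipartition(under, full)
        if bip in seen:
            sup, length = seen[bip]
            if sup is None:
                sup = node.support
            if length is not None and node.length is not None:
                length = length + node.length
            elif length is None:
                length = node.length
            seen[bip] = (sup, length)
        else:
            seen[bip] = (node.support, node.length)
            order.append(bip)
    return [(b, *seen[b]) for b in order]


def splits(tree: SupportTree) -> frozenset:
    """Just the set of non-trivial splits (topology only)."""
    return frozenset(b for b, _, _ in bipartitions(tree))


def clades(tree: SupportTree) -> frozenset:
    """Non-trivial rooted clades (2 <= |clade| <= n-1); requires a rooted tree."""
    if not tree.rooted:
        raise TreeError("clades are defined for rooted trees only")
    full = tree.leaf_labels
    leafsets = _leafsets(tree.root)
    out = set()
    for node in tree.root.postorder():
        if node is tree.root or node.is_leaf:
            continue
        under = leafsets[id(node)]
        if 2 <= len(under) <= len(full) - 1:
            out.add(under)
    return frozenset(out)


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

_COMMENT_SUPPORT = re.compile(r"\)\s*:\s*([0-9.eE+\-]+)\s*\[([0-9.]+)\]")


def parse_newick(
    text: str,
    support_convention: str = "internal_label",
    rooted: Optional[bool] = None,
) -> SupportTree:
    """Parse one Newick tree.

    ``support_convention`` is ``"internal_label"`` (RAxML bipartition style,
    the default: ``(a,b)95:1.0``) or ``"branch_comment"`` (``(a,b):1.0[95]``).
    ``rooted=None`` infers rootedness from the root degree (2 => rooted).
    """
    if support_convention not in ("internal_label", "branch_comment"):
        raise ValueError(f"unknown support convention {support_convention!r}")
    if support_convention == "branch_comment":
        text = _COMMENT_SUPPORT.sub(r")\2:\1", text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy reports line/column in its message
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        node = Node()
        if dnode.is_leaf():
            node.label = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            node.children = [convert(c) for c in dnode.child_nodes()]
            if dnode.label not in (None, ""):
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    raise TreeError(f"non-numeric internal node label {dnode.label!r}")
        node.length = dnode.edge.length
        return node

    root = convert(dtree.seed_node)
    root.support = None  # a root "edge" has no support
    if rooted is None:
        rooted = len(root.children) == 2
    return SupportTree(root, rooted=rooted)


def _fmt_num(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def _write_node(node: Node, buf: io.StringIO) -> None:
    if node.is_leaf:
        buf.write(node.label)
    else:
        buf.write("(")
        for i, child in enumerate(node.children):
            if i:
                buf.write(",")
            _write_node(child, buf)
        buf.write(")")
        if node.support is not None:
            buf.write(_fmt_num(node.support))
    if node.length is not None:
        buf.write(":" + _fmt_num(node.length))


def write_newick(tree: SupportTree) -> str:
    buf = io.StringIO()
    _write_node(tree.root, buf)
    buf.write(";")
    return buf.getvalue()


def read_tree_list(path_or_text, support_convention: str = "internal_label",
                   rooted: Optional[bool] = None) -> List[SupportTree]:
    """Read a multi-Newick file (one tree per line)."""
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    trees = []
    for line in text.splitlines():
        line = line.strip()
        if line:
            trees.append(parse_newick(line, support_convention, rooted=rooted))
    return trees


def write_tree_list(trees: Sequence[SupportTree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# collapsing and distances
# ---------------------------------------------------------------------------

def collapse_low_support(tree: SupportTree, threshold: float) -> SupportTree:
    """Contract every internal edge whose support is strictly below ``threshold``.

    Every internal edge must carry a support value; a missing value is a
    validation error (the caller decides the default, we do not guess).
    """
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in out.root.preorder():
            if node.is_leaf:
                continue
            kept: List[Node] = []
            for child in node.children:
                if child.is_leaf:
                    kept.append(child)
                    continue
                if child.support is None:
                    raise TreeError(
                        "internal edge without support encountered during collapse; "
                        "assign supports (or a default) before collapsing"
                    )
                if child.support < threshold:
                    kept.extend(child.children)  # contract the edge
                    changed = True
                else:
                    kept.append(child)
            node.children = kept
            if changed:
                break
    return out


def _check_same_leaves(t1: SupportTree, t2: SupportTree) -> None:
    if t1.leaf_labels != t2.leaf_labels:
        only1 = sorted(t1.leaf_labels - t2.leaf_labels)
        only2 = sorted(t2.leaf_labels - t1.leaf_labels)
        raise LeafSetMismatchError(
            f"leaf sets differ (only in first: {only1}; only in second: {only2})"
        )


def rf_distance(t1: SupportTree, t2: SupportTree) -> Tuple[int, float]:
    """Robinson-Foulds distance on unrooted splits.

    Returns ``(count, normalized)`` with ``count`` the size of the symmetric
    difference of the two split sets and ``normalized = count / (|S1| + |S2|)``
    (0.0 when both trees are split-free).
    """
    _check_same_leaves(t1, t2)
    s1, s2 = splits(t1), splits(t2)
    count = len(s1 ^ s2)
    denom = len(s1) + len(s2)
    return count, (count / denom if denom else 0.0)


def rooted_clade_distance(t1: SupportTree, t2: SupportTree) -> Tuple[int, float]:
    """Symmetric-difference distance on rooted clades (used for n=3 trees,
    where the unrooted view is split-free)."""
    _check_same_leaves(t1, t2)
    c1, c2 = clades(t1), clades(t2)
    count = len(c1 ^ c2)
    denom = len(c1) + len(c2)
    return count, (count / denom if denom else 0.0)


# ---------------------------------------------------------------------------
# rerooting
# ---------------------------------------------------------------------------

def root_at_outgroup(tree: SupportTree, outgroup: str) -> SupportTree:
    """Return a rooted copy with the root placed on the outgroup's pendant edge.

    Edge supports travel with their edges.  The outgroup pendant length is
    split evenly across the two root edges when present.
    """
    if outgroup not in tree.leaf_labels:
        raise TreeError(f"outgroup {outgroup!r} not in the leaf set")
    work = tree.copy()

    parent: Dict[int, Optional[Node]] = {id(work.root): None}
    for node in work.root.preorder():
        for child in node.children:
            parent[id(child)] = node
    og = next(n for n in work.root.postorder() if n.is_leaf and n.label == outgroup)
    og_parent = parent[id(og)]
    if og_parent is None:
        raise TreeError("cannot root a single-leaf tree")

    def hang(node: Node, came_from: Optional[Node],
             edge_len: Optional[float], edge_sup: Optional[float]) -> Node:
        """Rebuild the subtree seen from ``node`` walking away from ``came_from``,
        reached over an edge with the given attributes."""
        new = Node(label=node.label, length=edge_len, support=edge_sup)
        for child in node.children:
            if child is not came_from:
                new.children.append(hang(child, node, child.length, child.support))
        up = parent[id(node)]
        if up is not None and up is not came_from:
            new.children.append(hang(up, node, node.length, node.support))
        if new.label is None and len(new.children) == 1:
            # degree-2 pass-through (the old root seen from below): splice out,
            # merging the two half-edges into one
            only = new.children[0]
            if new.length is not None and only.length is not None:
                only.length = only.length + new.length
            elif only.length is None:
                only.length = new.length
            if only.support is None and not only.is_leaf:
                only.support = new.support
            return only
        return new

    half = og.length / 2.0 if og.length is not None else None
    og_node = Node(label=outgroup, length=half)
    rest = hang(og_parent, og, half, None)
    root = Node(children=[og_node, rest])
    return SupportTree(root, rooted=True)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

class Alignment:
    """A gap-aware DNA alignment: taxon -> row over {A,C,G,T,-,N}."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise TreeError("alignment has no sequences")
        seqs = {str(k): str(v).upper() for k, v in sequences.items()}
        lengths = {len(v) for v in seqs.values()}
        if len(lengths) != 1:
            raise TreeError(f"ragged alignment: row lengths {sorted(lengths)}")
        (k,) = lengths
        if k < 1:
            raise TreeError("alignment must have at least one column")
        for name, row in seqs.items():
            bad = set(row) - DNA_ALPHABET
            if bad:
                raise TreeError(f"illegal characters {sorted(bad)} in row {name!r}")
        self.sequences: Dict[str, str] = seqs
        self.length = k

    @property
    def taxa(self) -> List[str]:
        return list(self.sequences)

    def __eq__(self, other) -> bool:
        return isinstance(other, Alignment) and self.sequences == other.sequences

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({len(self.sequences)} taxa x {self.length} cols)"


def read_alignment(path, fmt: str = "fasta") -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment via Biopython."""
    from Bio import SeqIO

    schema = {"fasta": "fasta", "phylip": "phylip-relaxed"}[fmt]
    records = list(SeqIO.parse(str(path), schema))
    if not records:
        raise TreeError(f"no sequences found in {path}")
    return Alignment({r.id: str(r.seq) for r in records})


def write_alignment(aln: Alignment, path, fmt: str = "fasta") -> None:
    if fmt == "fasta":
        with open(path, "w") as fh:
            for name, row in aln.sequences.items():
                fh.write(f">{name}\n{row}\n")
    elif fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f" {len(aln.sequences)} {aln.length}\n")
            for name, row in aln.sequences.items():
                fh.write(f"{name}  {row}\n")
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
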