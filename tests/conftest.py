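import itertools

import numpy as np
import pytest

from wsbinning.treeio import Node, SupportTree, parse_newick


@pytest.fixture
def quartet_ab_cd():
    return parse_newick("((a:1,b:1)100:1,(c:1,d:1)100:1);")


@pytest.fixture
def quartet_ac_bd():
    return parse_newick("((a:1,c:1)100:1,(b:1,d:1)100:1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def enumerate_binary_unrooted(taxa):
    """Independent brute-force enumerator of unrooted binary topologies,
    used as the oracle for compatibility and ML tests.

    Represents trees as nested frozensets and only converts to SupportTree
    at the end, so it shares no code with the package's enumerator.
    """
    taxa = sorted(taxa)

    def grow(structures, remaining):
        if not remaining:
            return structures
        t, rest = remaining[0], remaining[1:]
        grown = []
        for s in structures:
            for edited in _insert_everywhere(s, t):
                grown.append(edited)
        return grow(grown, rest)

    def _insert_everywhere(structure, taxon):
        # structure: tuple of three subtrees (unrooted center)
        out = []
        for i, sub in enumerate(structure):
            for new_sub in _insert_in_subtree(sub, taxon):
                lst = list(structure)
                lst[i] = new_sub
                out.append(tuple(lst))
        return out

    def _insert_in_subtree(sub, taxon):
        yield (sub, taxon)  # attach on the edge above `sub`
        if isinstance(sub, tuple):
            left, right = sub
            for new_left in _insert_in_subtree(left, taxon):
                yield (new_left, right)
            for new_right in _insert_in_subtree(right, taxon):
                yield (left, new_right)

    def to_tree(structure):
        def node(sub):
            if isinstance(sub, tuple):
                return Node(children=[node(s) for s in sub])
            return Node(label=sub)

        return SupportTree(Node(children=[node(s) for s in structure]), rooted=False)

    start = [tuple(taxa[:3])]
    return [to_tree(s) for s in grow(start, taxa[3:])]
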