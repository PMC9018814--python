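"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (enumeration or alternative
formulations) and shares no code with the implementations under test.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import networkx as nx
import numpy as np

from v2rscan._seq import AA_INDEX, BLOSUM62

# ---------------------------------------------------------------------------
# pairwise alignment


def affine_align_score_enum(a: str, b: str, gap_open=11.0, gap_ext=1.0) -> float:
    """True enumeration of all global alignments (tiny inputs only).

    Alignments are column sequences; gap runs in each row are charged
    open + (len-1) * ext.
    """

    best = [-np.inf]

    def rec(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = BLOSUM62[AA_INDEX[a[i]], AA_INDEX[b[j]]]
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            pen = gap_ext if state == "X" else gap_open
            rec(i + 1, j, score - pen, "X")
        if j < len(b):
            pen = gap_ext if state == "Y" else gap_open
            rec(i, j + 1, score - pen, "Y")

    rec(0, 0, 0.0, "M")
    return best[0]


def affine_align_score_memo(a: str, b: str, gap_open=11.0, gap_ext=1.0) -> float:
    """Independent memoized formulation (top-down, state = last column)."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int, state: str) -> float:
        if i == 0 and j == 0:
            # "M" doubles as the start state; a gap run cannot pre-exist
            return 0.0 if state == "M" else -np.inf
        cands = []
        if i > 0 and j > 0:
            s = BLOSUM62[AA_INDEX[a[i - 1]], AA_INDEX[b[j - 1]]]
            if state == "M":
                cands.extend(f(i - 1, j - 1, st) for st in "MXY")
                cands = [c + s for c in cands]
        if state == "X" and i > 0:
            cands.append(f(i - 1, j, "X") - gap_ext)
            cands.append(f(i - 1, j, "M") - gap_open)
            cands.append(f(i - 1, j, "Y") - gap_open)
        if state == "Y" and j > 0:
            cands.append(f(i, j - 1, "Y") - gap_ext)
            cands.append(f(i, j - 1, "M") - gap_open)
            cands.append(f(i, j - 1, "X") - gap_open)
        return max(cands) if cands else -np.inf

    return max(f(len(a), len(b), st) for st in "MXY")


# ---------------------------------------------------------------------------
# trees: enumeration, additive matrices, RF


def all_unrooted_topologies(labels: list[str]) -> list[nx.Graph]:
    """Every unrooted binary topology on the given leaves (n <= 6)."""
    assert len(labels) >= 3
    base = nx.Graph()
    center = ("int", 0)
    base.add_edges_from((center, (l,)) for l in labels[:3])
    trees = [base]
    next_int = 1
    for label in labels[3:]:
        new_trees = []
        for t in trees:
            for u, v in list(t.edges()):
                t2 = t.copy()
                mid = ("int", next_int, label, (u, v))
                t2.remove_edge(u, v)
                t2.add_edge(u, mid)
                t2.add_edge(mid, v)
                t2.add_edge(mid, (label,))
                new_trees.append(t2)
        trees = new_trees
        next_int += 1
    return trees


def random_additive_matrix(topology: nx.Graph, labels: list[str], rng):
    """Assign random positive branch lengths; return path-length matrix."""
    g = topology.copy()
    for u, v in g.edges():
        g[u][v]["weight"] = float(rng.uniform(0.3, 2.0))
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = nx.shortest_path_length(
                g, (labels[i],), (labels[j],), weight="weight"
            )
            D[i, j] = D[j, i] = d
    return D, g


def graph_bipartitions(g: nx.Graph, leaves: set) -> set[frozenset]:
    """Non-trivial bipartitions by edge removal on the tree graph."""
    out = set()
    ref = min(leaves)
    for u, v in list(g.edges()):
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = {n[0] for n in comp if len(n) == 1 and n[0] in leaves}
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(frozenset(side))
    return out


def dendropy_to_graph(tree) -> tuple[nx.Graph, set]:
    g = nx.Graph()
    leaves = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            key_c = (node.taxon.label,) if node.is_leaf() else ("int", id(node))
            key_p = (
                (node.parent_node.taxon.label,)
                if node.parent_node.is_leaf()
                else ("int", id(node.parent_node))
            )
            g.add_edge(key_p, key_c,
                       weight=float(node.edge.length or 0.0))
            if node.is_leaf():
                leaves.add(node.taxon.label)
    return g, leaves


def rf_oracle(t1, t2) -> int:
    g1, l1 = dendropy_to_graph(t1)
    g2, l2 = dendropy_to_graph(t2)
    assert l1 == l2
    return len(graph_bipartitions(g1, l1) ^ graph_bipartitions(g2, l2))


def tree_path_matrix(tree, labels: list[str]) -> np.ndarray:
    g, leaves = dendropy_to_graph(tree)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = nx.shortest_path_length(
                g, (labels[i],), (labels[j],), weight="weight"
            )
    return D


# ---------------------------------------------------------------------------
# parsimony


def dollo_min_events(tree, present: set[str]) -> int:
    """Minimum events over all single-gain scenarios, by enumeration.

    For every candidate gain node and every subset of branches below it
    as losses, check whether the implied leaf states match.
    """
    nodes = list(tree.preorder_node_iter())
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not present:
        return 0
    best = np.inf
    for gain in nodes:
        below = [n for n in nodes if _is_descendant_or_self(n, gain)]
        gain_leaves = {lf.taxon.label for lf in gain.leaf_iter()}
        if not present <= gain_leaves:
            continue
        edges = [n for n in below if n is not gain]
        for r in range(0, len(edges) + 1):
            if 1 + r >= best:
                break
            for cut in itertools.combinations(edges, r):
                lost = set()
                for c in cut:
                    lost |= {lf.taxon.label for lf in c.leaf_iter()}
                state_p = gain_leaves - lost
                if state_p == present:
                    best = min(best, 1 + r)
                    break
    return int(best)


def _is_descendant_or_self(node, anc) -> bool:
    n = node
    while n is not None:
        if n is anc:
            return True
        n = n.parent_node
    return False


def linear_parsimony_min_cost(tree, totals: dict[str, int]) -> int:
    """Exhaustive enumeration of ancestral integer states in [0, max]."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    M = max(totals.values())
    best = np.inf
    for assign in itertools.product(range(M + 1), repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, assign)}
        for lf in tree.leaf_node_iter():
            state[id(lf)] = totals[lf.taxon.label]
        cost = 0
        for n in tree.preorder_node_iter():
            if n.parent_node is not None:
                cost += abs(state[id(n)] - state[id(n.parent_node)])
        best = min(best, cost)
    return int(best)
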