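"""Alignment and distance-based tree inference.

The tree-building path is deliberately simple and fully deterministic:
a k-mer-guided progressive aligner with affine gaps, low-coverage column
filtering, Poisson-corrected distances, canonical neighbor joining with
explicit tie-breaking, and nonparametric bootstrap supports.  Externally
computed trees can be imported through :func:`read_tree` and used by every
downstream step in place of the built-in inference.

Trees are :class:`dendropy.Tree` objects throughout; bootstrap supports
are stored on internal nodes both as ``node.support`` (float, 0-100) and
as the node label, so they survive newick round-trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage

from ._dp import nw_affine
from ._seq import AA_ALPHABET, AA_INDEX, BLOSUM62

GAP = -1

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXT = 1.0

_W = BLOSUM62[:22, :22].astype(np.float64)


@dataclass
class MSA:
    """A multiple protein alignment: rows are aa-index arrays, gap = -1."""

    ids: list[str]
    matrix: np.ndarray  # (n_seqs, n_cols) int8

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def coverage(self) -> np.ndarray:
        """Per-column fraction of non-gap symbols."""
        return (self.matrix != GAP).mean(axis=0)

    def row(self, i: int) -> str:
        return "".join("-" if c == GAP else AA_ALPHABET[c] for c in self.matrix[i])

    def rows(self) -> dict[str, str]:
        return {sid: self.row(i) for i, sid in enumerate(self.ids)}


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("nonzero diagonal")


def _encode_rows(seqs: list[str]) -> np.ndarray:
    n = len(seqs)
    L = len(seqs[0])
    out = np.full((n, L), GAP, dtype=np.int8)
    for i, s in enumerate(seqs):
        for j, c in enumerate(s):
            if c != "-":
                out[i, j] = AA_INDEX[c]
    return out


def msa_from_strings(rows: dict[str, str]) -> MSA:
    ids = list(rows)
    lens = {len(v) for v in rows.values()}
    if len(lens) > 1:
        raise ValueError("unequal alignment row lengths")
    return MSA(ids, _encode_rows([rows[i] for i in ids]))


# ---------------------------------------------------------------------------
# progressive alignment


def _kmer_sets(seq: str, k: int = 3) -> set[str]:
    return {seq[i : i + k] for i in range(max(len(seq) - k + 1, 1))}


def _profile(matrix: np.ndarray) -> np.ndarray:
    """Residue frequency profile; gaps dilute (counts / n_rows)."""
    n, L = matrix.shape
    prof = np.zeros((L, 22))
    for a in range(22):
        prof[:, a] = (matrix == a).sum(axis=0)
    return prof / n


def _align_groups(m1: np.ndarray, m2: np.ndarray, gap_open: float, gap_ext: float):
    S = _profile(m1) @ _W @ _profile(m2).T
    _, pa, pb, L = nw_affine(S, gap_open, gap_ext)
    out = np.full((m1.shape[0] + m2.shape[0], L), GAP, dtype=np.int8)
    for k in range(L):
        if pa[k] >= 0:
            out[: m1.shape[0], k] = m1[:, pa[k]]
        if pb[k] >= 0:
            out[m1.shape[0] :, k] = m2[:, pb[k]]
    return out


def pairwise_align(a: str, b: str, gap_open: float = DEFAULT_GAP_OPEN,
                   gap_ext: float = DEFAULT_GAP_EXT) -> tuple[float, str, str]:
    """Global affine pairwise alignment; returns (score, row_a, row_b)."""
    m1 = _encode_rows([a])
    m2 = _encode_rows([b])
    S = (_W[m1[0]][:, m2[0]]).astype(np.float64)
    score, pa, pb, L = nw_affine(S, gap_open, gap_ext)
    ra = "".join(a[pa[k]] if pa[k] >= 0 else "-" for k in range(L))
    rb = "".join(b[pb[k]] if pb[k] >= 0 else "-" for k in range(L))
    return score, ra, rb


def progressive_align(seqs: dict[str, str], gap_open: float = DEFAULT_GAP_OPEN,
                      gap_ext: float = DEFAULT_GAP_EXT) -> MSA:
    """k-mer/UPGMA-guided progressive alignment with affine gaps."""
    ids = list(seqs)
    if not ids:
        raise ValueError("no sequences to align")
    if any(len(seqs[i]) == 0 for i in ids):
        raise ValueError("empty sequence in alignment input")
    if len(ids) == 1:
        return MSA(ids, _encode_rows([seqs[ids[0]]]))
    n = len(ids)
    ksets = [_kmer_sets(seqs[i]) for i in ids]
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(ksets[i] & ksets[j])
            cond.append(1.0 - 2.0 * inter / (len(ksets[i]) + len(ksets[j])))
    Z = linkage(np.asarray(cond), method="average")
    groups: dict[int, tuple[list[int], np.ndarray]] = {
        i: ([i], _encode_rows([seqs[ids[i]]])) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ga, gb = groups.pop(int(a)), groups.pop(int(b))
        merged = _align_groups(ga[1], gb[1], gap_open, gap_ext)
        groups[n + step] = (ga[0] + gb[0], merged)
    order, matrix = groups.popitem()[1]
    # restore input row order
    perm = np.argsort(np.asarray(order))
    return MSA([ids[order[p]] for p in perm], matrix[perm])


def filter_columns(msa: MSA, min_cov: float = 0.5) -> MSA:
    """Drop columns whose non-gap coverage is strictly below ``min_cov``."""
    keep = msa.coverage() >= min_cov
    if not keep.any():
        raise ValueError("all alignment columns removed by coverage filter")
    return MSA(list(msa.ids), msa.matrix[:, keep])


# ---------------------------------------------------------------------------
# distances

SATURATION_P = 0.95


def distances(msa: MSA, model: str = "poisson") -> DistanceMatrix:
    """Poisson-corrected pairwise distances d = -ln(1 - p).

    p is the mismatch fraction over mutually non-gap columns; pairs at or
    beyond p = 0.95, and pairs sharing no columns, get an infinite
    (saturated) sentinel.
    """
    if model not in ("poisson", "p"):
        raise ValueError(f"unknown distance model {model!r}")
    X = msa.matrix
    n = len(msa.ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (X[i] != GAP) & (X[j] != GAP)
            m = int(both.sum())
            if m == 0:
                warnings.warn(
                    f"no shared columns between {msa.ids[i]} and {msa.ids[j]};"
                    " distance saturated"
                )
                d = np.inf
            else:
                p = float((X[i, both] != X[j, both]).mean())
                if model == "p":
                    d = p
                elif p >= SATURATION_P:
                    d = np.inf
                else:
                    d = -np.log(1.0 - p)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(msa.ids), D)


# ---------------------------------------------------------------------------
# neighbor joining


def _new_tree(tns: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    return dendropy.Tree(taxon_namespace=tns or dendropy.TaxonNamespace())


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical NJ (Q-criterion).

    Ties on Q are broken toward the lexicographically smallest pair of
    cluster keys (a cluster's key is its smallest leaf label).  Negative
    branch lengths are clamped to zero with the deficit moved to the
    sister edge.
    """
    ids = dm.ids
    if not np.all(np.isfinite(dm.matrix)):
        raise ValueError("distance matrix contains saturated (infinite) entries")
    tree = _new_tree()
    tns = tree.taxon_namespace
    nodes = []
    for label in ids:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label)
        nodes.append(node)
    n = len(ids)
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        tree.seed_node.add_child(nodes[0])
        nodes[0].edge.length = 0.0
        tree.is_rooted = False
        return tree
    if n == 2:
        d = float(dm.matrix[0, 1])
        for node in nodes:
            tree.seed_node.add_child(node)
            node.edge.length = d / 2.0
        tree.is_rooted = False
        return tree

    D = dm.matrix.astype(np.float64).copy()
    active = list(range(n))
    keys = {i: ids[i] for i in range(n)}
    clusters = {i: nodes[i] for i in range(n)}
    next_idx = n
    Dmap = {(i, j): D[i, j] for i in range(n) for j in range(n) if i != j}

    def dist(a, b):
        return Dmap[(a, b)] if a != b else 0.0

    while len(active) > 3:
        r = len(active)
        R = {a: sum(dist(a, b) for b in active) for a in active}
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1 :]:
                q = (r - 2) * dist(a, b) - R[a] - R[b]
                pair_key = tuple(sorted((keys[a], keys[b])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and pair_key < best[1]
                ):
                    best = (q, pair_key, a, b)
        _, _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (R[a] - R[b]) / (2.0 * (r - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
            la = max(la, 0.0)
        parent = dendropy.Node()
        parent.add_child(clusters[a])
        clusters[a].edge.length = la
        parent.add_child(clusters[b])
        clusters[b].edge.length = lb
        u = next_idx
        next_idx += 1
        clusters[u] = parent
        keys[u] = min(keys[a], keys[b])
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            Dmap[(u, c)] = Dmap[(c, u)] = duc
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = sorted(active, key=lambda x: keys[x])
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    la = max((dab + dac - dbc) / 2.0, 0.0)
    lb = max((dab + dbc - dac) / 2.0, 0.0)
    lc = max((dac + dbc - dab) / 2.0, 0.0)
    for x, lx in ((a, la), (b, lb), (c, lc)):
        tree.seed_node.add_child(clusters[x])
        clusters[x].edge.length = lx
    tree.is_rooted = False
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, rooting, comparison


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def _node_leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each named by the side that does
    not contain the lexicographically smallest leaf."""
    all_leaves = frozenset(leaf_labels(tree))
    ref = min(all_leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _node_leafset(node)
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric-difference (RF) distance over shared leaves."""
    shared = leaf_labels(t1) & leaf_labels(t2)
    if len(shared) < 4:
        warnings.warn("fewer than 4 shared leaves; RF distance reported as 0")
        return 0
    p1 = prune_to_taxa(t1, shared)
    p2 = prune_to_taxa(t2, shared)
    return len(bipartitions(p1) ^ bipartitions(p2))


def prune_to_taxa(tree: dendropy.Tree, labels: set[str]) -> dendropy.Tree:
    """Copy of ``tree`` restricted to ``labels`` (unary nodes collapsed)."""
    sub = tree.extract_tree_with_taxa_labels(labels)
    sub.purge_taxon_namespace()
    return sub


def default_builder(msa: MSA) -> dendropy.Tree:
    return neighbor_joining(distances(msa))


def bootstrap(msa: MSA, builder=None, n: int = 100, seed: int = 0) -> dendropy.Tree:
    """Point-estimate tree with column-resampling bootstrap supports.

    Supports are the percentage of replicate trees containing each
    non-trivial bipartition of the point tree, stored on internal nodes.
    """
    if n < 1:
        raise ValueError("need at least one bootstrap replicate")
    builder = builder or default_builder
    point = builder(msa)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(point)}
    L = msa.n_cols
    for _ in range(n):
        cols = rng.integers(0, L, size=L)
        rep = MSA(list(msa.ids), msa.matrix[:, cols])
        try:
            rep_bps = bipartitions(builder(rep))
        except ValueError:
            continue  # saturated replicate contributes to no bipartition
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_leaves = frozenset(leaf_labels(point))
    ref = min(all_leaves)
    for node in point.preorder_node_iter():
        if node is point.seed_node or node.is_leaf():
            continue
        side = _node_leafset(node)
        if ref in side:
            side = all_leaves - side
        if side in counts:
            sup = 100.0 * counts[side] / n
            node.support = sup
            node.label = str(int(round(sup)))
    return point


def root_with_outgroup(tree: dendropy.Tree, outgroup_ids) -> dendropy.Tree:
    """Root on the edge separating a monophyletic outgroup from the rest."""
    og = frozenset(outgroup_ids)
    leaves = frozenset(leaf_labels(tree))
    if not og:
        raise ValueError("empty outgroup")
    if not og <= leaves:
        raise ValueError(f"outgroup ids missing from tree: {sorted(og - leaves)}")
    if og == leaves:
        raise ValueError("outgroup cannot contain every leaf")
    work = tree.clone(depth=1)
    target = None
    for node in work.preorder_node_iter():
        if node is work.seed_node:
            continue
        side = _node_leafset(node)
        if side == og or side == leaves - og:
            target = node
            break
    if target is None:
        smallest = min(
            (
                _node_leafset(nd)
                for nd in work.preorder_node_iter()
                if og <= _node_leafset(nd)
            ),
            key=len,
        )
        raise ValueError(
            "outgroup is not monophyletic; smallest containing clade is "
            f"{sorted(smallest)}"
        )
    edge = target.edge
    L = edge.length if edge.length is not None else 0.0
    work.reroot_at_edge(edge, update_bipartitions=False)
    for child in work.seed_node.child_nodes():
        child.edge.length = L / 2.0
    work.is_rooted = True
    return work


# ---------------------------------------------------------------------------
# newick I/O


def canonicalize(tree: dendropy.Tree) -> dendropy.Tree:
    """Sort children everywhere by smallest descendant leaf label."""

    def key(node):
        return min(lf.taxon.label for lf in node.leaf_iter())

    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if children:
            for ch in children:
                node.remove_child(ch)
            for ch in sorted(children, key=key):
                node.add_child(ch)
    return tree


def read_tree(newick: str) -> dendropy.Tree:
    """Parse a newick string; internal numeric labels become supports."""
    if not newick.strip():
        raise ValueError("empty newick string")
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from exc
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree


def write_tree(tree: dendropy.Tree) -> str:
    canonicalize(tree)
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return s.strip() + "\n"
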