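"""Clade and subfamily assignment from a rooted gene tree.

The receptor family is delimited by the calcium-sensing receptor (CaSR)
rule: every gene in the sister clade of the smallest clade containing
the CaSR anchors is a V2R homolog; everything else (e.g. genes drawn
toward Tas1r/GRM/GABA-B outgroups) is non-V2R.  Within the homologs,
each gene is assigned to the smallest sufficiently supported clade that
contains anchors of exactly one major clade (V2R2, ancV2R, fV2R, tV2R),
and f-V2R genes are further placed into marker-defined subfamilies, with
marker-free supported clades of two or more genes reported as novel
subfamilies ("a1", "a2", ...).

Species are parsed from gene ids as the prefix before the first ``|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .phylogeny import leaf_labels, prune_to_taxa, robinson_foulds

MAJOR_CLADES = ("V2R2", "ancV2R", "fV2R", "tV2R")


def species_of(gene_id: str) -> str:
    if "|" not in gene_id:
        raise ValueError(f"gene id {gene_id!r} carries no species|name token")
    return gene_id.split("|", 1)[0]


@dataclass
class ReferencePanel:
    """Outgroup, clade-anchor and subfamily-marker id sets."""

    outgroups: dict[str, list[str]]  # family name (CaSR, Tas1r, ...) -> ids
    clade_anchors: dict[str, list[str]]  # major clade -> ids
    subfamily_markers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in (self.outgroups, self.clade_anchors, self.subfamily_markers):
            for ids in group.values():
                if not ids:
                    raise ValueError("panel group declared without any id")
                overlap = seen & set(ids)
                if overlap:
                    raise ValueError(f"panel id sets overlap: {sorted(overlap)}")
                seen |= set(ids)

    @property
    def casr_ids(self) -> list[str]:
        for name, ids in self.outgroups.items():
            if name.lower() == "casr":
                return ids
        raise ValueError("panel declares no CaSR outgroup")

    def all_ids(self) -> set[str]:
        out: set[str] = set()
        for group in (self.outgroups, self.clade_anchors, self.subfamily_markers):
            for ids in group.values():
                out |= set(ids)
        return out

    def anchor_clade(self) -> dict[str, str]:
        return {i: c for c, ids in self.clade_anchors.items() for i in ids}

    def marker_subfamily(self) -> dict[str, str]:
        return {i: s for s, ids in self.subfamily_markers.items() for i in ids}


@dataclass
class CladeAssignment:
    gene_id: str
    clade: str  # non-V2R | V2R2 | ancV2R | fV2R | tV2R
    subfamily: str = ""  # fV2R only
    support: float = 100.0
    fallback: bool = False


def _support(node: dendropy.Node) -> float:
    s = getattr(node, "support", None)
    return 100.0 if s is None else float(s)


def _leafsets(tree: dendropy.Tree) -> dict[int, frozenset[str]]:
    out: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[id(node)] = frozenset([node.taxon.label])
        else:
            s: set[str] = set()
            for ch in node.child_nodes():
                s |= out[id(ch)]
            out[id(node)] = frozenset(s)
    return out


def _depths(tree: dendropy.Tree) -> dict[int, float]:
    d: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        d[id(node)] = d[id(node.parent_node)] + (node.edge.length or 0.0)
    return d


def _patristic(tree: dendropy.Tree) -> callable:
    depths = _depths(tree)
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    ancestors: dict[str, list[dendropy.Node]] = {}
    for label, lf in leaves.items():
        chain = []
        n = lf
        while n is not None:
            chain.append(n)
            n = n.parent_node
        ancestors[label] = chain

    def dist(a: str, b: str) -> float:
        seen = {id(n) for n in ancestors[a]}
        mrca = next(n for n in ancestors[b] if id(n) in seen)
        return depths[id(leaves[a])] + depths[id(leaves[b])] - 2 * depths[id(mrca)]

    return dist


def define_v2r_homologs(tree: dendropy.Tree, panel: ReferencePanel) -> set[str]:
    """Leaves of the sister clade of the smallest clade containing CaSR."""
    casr = set(panel.casr_ids)
    leaves = leaf_labels(tree)
    missing = casr - leaves
    if missing:
        raise ValueError(f"CaSR anchors absent from tree: {sorted(missing)}")
    leafsets = _leafsets(tree)
    mrca = None
    for node in tree.postorder_node_iter():
        if casr <= leafsets[id(node)]:
            mrca = node
            break
    if mrca is tree.seed_node or mrca.parent_node is None:
        raise ValueError("CaSR clade has no sister (it spans the root)")
    sister: set[str] = set()
    for sib in mrca.parent_node.child_nodes():
        if sib is not mrca:
            sister |= leafsets[id(sib)]
    return sister


def _assign_by_anchor_ascent(
    tree: dendropy.Tree,
    gene_ids: set[str],
    anchor_of: dict[str, str],
    support_min: float,
    leafsets: dict[int, frozenset[str]],
) -> dict[str, tuple[str, float] | None]:
    """Smallest supported node containing the gene and anchors of exactly
    one label; None when no such node exists."""
    leaf_nodes = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    anchors = set(anchor_of)
    out: dict[str, tuple[str, float] | None] = {}
    for gid in sorted(gene_ids):
        node = leaf_nodes[gid].parent_node
        result = None
        while node is not None:
            inside = leafsets[id(node)] & anchors
            if inside:
                labels = {anchor_of[a] for a in inside}
                if len(labels) == 1 and _support(node) >= support_min:
                    result = (labels.pop(), _support(node))
                    break
            node = node.parent_node
        out[gid] = result
    return out


def assign_major_clade(
    tree: dendropy.Tree,
    panel: ReferencePanel,
    support_min: float = 50.0,
) -> list[CladeAssignment]:
    """Per-gene major-clade labels for every non-panel leaf of the tree.

    Genes outside the CaSR-sister clade are non-V2R.  Genes with no
    supported anchor-pure containing clade fall back to the nearest
    anchor by patristic distance (flagged; clade-name ties break
    lexicographically).
    """
    anchor_of = panel.anchor_clade()
    if not anchor_of:
        raise ValueError("panel declares no clade anchors")
    homologs = define_v2r_homologs(tree, panel)
    panel_ids = panel.all_ids()
    genes = {lf.taxon.label for lf in tree.leaf_node_iter()} - panel_ids
    leafsets = _leafsets(tree)
    inside = {g for g in genes if g in homologs}
    hits = _assign_by_anchor_ascent(tree, inside, anchor_of, support_min, leafsets)
    dist = _patristic(tree)
    out: list[CladeAssignment] = []
    for gid in sorted(genes):
        if gid not in homologs:
            out.append(CladeAssignment(gid, "non-V2R", support=100.0))
            continue
        hit = hits[gid]
        if hit is not None:
            out.append(CladeAssignment(gid, hit[0], support=hit[1]))
            continue
        dists = {aid: dist(gid, aid) for aid in anchor_of}
        dmin = min(dists.values())
        clade = min(
            anchor_of[aid] for aid, d in dists.items() if d <= dmin + 1e-9
        )
        out.append(CladeAssignment(gid, clade, support=0.0, fallback=True))
    return out


def assign_subfamily(
    tree: dendropy.Tree,
    panel: ReferencePanel,
    assignments: list[CladeAssignment],
    support_min: float = 50.0,
    novel_min_size: int = 2,
) -> list[CladeAssignment]:
    """Fill subfamily labels for f-V2R genes (in place, also returned).

    Marker-free supported clades consisting only of unassigned f-V2R
    genes become novel subfamilies labelled "a1", "a2", ... in
    decreasing clade-size order; leftovers are "unplaced".
    """
    marker_of = panel.marker_subfamily()
    fv2r = {a.gene_id for a in assignments if a.clade == "fV2R"}
    by_id = {a.gene_id: a for a in assignments}
    leafsets = _leafsets(tree)
    hits = (
        _assign_by_anchor_ascent(tree, fv2r, marker_of, support_min, leafsets)
        if marker_of
        else {g: None for g in fv2r}
    )
    unresolved = set()
    for gid in fv2r:
        hit = hits[gid]
        if hit is not None:
            by_id[gid].subfamily = hit[0]
        else:
            unresolved.add(gid)
    # novel subfamilies: maximal supported clades of only-unresolved genes
    candidates = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        ls = leafsets[id(node)]
        if ls <= unresolved and len(ls) >= novel_min_size and _support(node) >= support_min:
            candidates.append(ls)
    maximal = [
        ls for ls in candidates if not any(ls < other for other in candidates)
    ]
    maximal.sort(key=lambda ls: (-len(ls), min(ls)))
    for i, ls in enumerate(maximal, start=1):
        for gid in ls:
            by_id[gid].subfamily = f"a{i}"
            unresolved.discard(gid)
    for gid in unresolved:
        by_id[gid].subfamily = "unplaced"
    return assignments


@dataclass
class OrthologClade:
    gene_ids: list[str]
    species: list[str]
    support: float


def detect_single_copy_orthologs(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    support_min: float = 50.0,
    min_species: int = 3,
) -> list[OrthologClade]:
    """Maximal clades with one gene per species (>= 3 species) whose
    topology matches the species tree (RF = 0 after pruning)."""
    leafsets = _leafsets(gene_tree)
    qualifying: dict[int, tuple[dendropy.Node, frozenset[str]]] = {}
    for node in gene_tree.preorder_node_iter():
        if node.is_leaf() or node is gene_tree.seed_node:
            continue
        ls = leafsets[id(node)]
        sp = [species_of(g) for g in ls]
        if len(sp) != len(set(sp)) or len(sp) < min_species:
            continue
        if _support(node) < support_min:
            continue
        sub = _clade_as_species_tree(node)
        if robinson_foulds(sub, species_tree) != 0:
            continue
        qualifying[id(node)] = (node, ls)
    out = []
    for nid, (node, ls) in qualifying.items():
        anc = node.parent_node
        shadowed = False
        while anc is not None:
            if id(anc) in qualifying:
                shadowed = True
                break
            anc = anc.parent_node
        if not shadowed:
            out.append(
                OrthologClade(
                    gene_ids=sorted(ls),
                    species=sorted({species_of(g) for g in ls}),
                    support=_support(node),
                )
            )
    out.sort(key=lambda c: c.gene_ids)
    return out


def _clade_as_species_tree(node: dendropy.Node) -> dendropy.Tree:
    """Copy the clade below ``node`` with leaves relabelled by species."""
    tree = dendropy.Tree(taxon_namespace=dendropy.TaxonNamespace())

    def copy(src: dendropy.Node, dst: dendropy.Node) -> None:
        for ch in src.child_nodes():
            nn = dendropy.Node()
            nn.edge.length = ch.edge.length
            dst.add_child(nn)
            if ch.is_leaf():
                nn.taxon = tree.taxon_namespace.new_taxon(
                    species_of(ch.taxon.label)
                )
            else:
                copy(ch, nn)

    copy(node, tree.seed_node)
    tree.is_rooted = True
    return tree


def test_wgd_ratio(
    tree: dendropy.Tree, focal_species: str, reference_species: str
) -> tuple[float, dict[int, int]]:
    """Fraction of reference-species genes with exactly two focal-species
    co-orthologs, plus the full count histogram.

    For each reference gene the counting clade is the smallest containing
    clade that holds at least one focal-species gene; a clade polluted by
    a third species at that point marks a non-orthologous grouping and is
    counted as-is.
    """
    present = {species_of(lf.taxon.label) for lf in tree.leaf_node_iter()}
    for sp in (focal_species, reference_species):
        if sp not in present:
            raise ValueError(f"species {sp!r} absent from tree")
    leafsets = _leafsets(tree)
    hist: dict[int, int] = {}
    n_ref = 0
    for lf in tree.leaf_node_iter():
        gid = lf.taxon.label
        if species_of(gid) != reference_species:
            continue
        n_ref += 1
        node = lf
        count = 0
        while node.parent_node is not None:
            node = node.parent_node
            count = sum(
                1 for g in leafsets[id(node)]
                if species_of(g) == focal_species
            )
            if count:
                break
        hist[count] = hist.get(count, 0) + 1
    frac = hist.get(2, 0) / n_ref if n_ref else 0.0
    return frac, hist


def copy_number_table(
    assignments: list[CladeAssignment],
    statuses: dict[str, str],
) -> pd.DataFrame:
    """Species x clade/subfamily table of intact gene counts.

    Columns: V2R2, ancV2R, tV2R, one column per observed f-V2R subfamily
    (``fV2R_<label>``), unplaced f-V2Rs, and the row total.
    """
    intact = [a for a in assignments if statuses.get(a.gene_id) == "intact"
              and a.clade in MAJOR_CLADES]
    species = sorted({species_of(a.gene_id) for a in intact})
    subfams = sorted(
        {a.subfamily for a in intact if a.clade == "fV2R" and a.subfamily
         and a.subfamily != "unplaced"},
        key=lambda s: (len(s), s),
    )
    cols = ["V2R2", "ancV2R", "tV2R"] + [f"fV2R_{s}" for s in subfams] + [
        "fV2R_unplaced", "total"]
    df = pd.DataFrame(0, index=species, columns=cols)
    for a in intact:
        sp = species_of(a.gene_id)
        if a.clade == "fV2R":
            col = (
                f"fV2R_{a.subfamily}"
                if a.subfamily and a.subfamily != "unplaced"
                else "fV2R_unplaced"
            )
        else:
            col = a.clade
        df.loc[sp, col] += 1
        df.loc[sp, "total"] += 1
    df.index.name = "species"
    return df
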