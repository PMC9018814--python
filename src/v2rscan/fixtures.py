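"""Standard synthetic study fixtures.

Builds the full simulated analysis world used by the tests, examples and
acceptance checks: a gene-family tree with reference-panel leaves
(outgroups, clade anchors, subfamily markers), evolved protein
sequences, planted genomes for each species, and ground truth for every
gene.  The default fixture is two species with ~1 Mb of genome each,
15 receptor genes per species (one V2R2, one ancV2R, three t-V2Rs and
ten f-V2Rs in four subfamilies of which one is novel/marker-free) and a
20% pseudogene fraction split across the three pseudogenization
mechanisms.

All randomness flows from one seed through named ``SeedSequence``
spawns, so fixtures are byte-stable across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import simulate as sim
from .classification import ReferencePanel
from .mining import TMQuery
from .phylogeny import read_tree

#: synthetic 7-TM annotation of the 340-aa family root protein
TM_INTERVALS = [
    (55, 76), (85, 106), (115, 136), (145, 166), (175, 196), (205, 226),
    (269, 290),
]
ROOT_PROTEIN_LEN = 340
TM_FLANK = 50

#: branch lengths (aa substitutions/site) of the family backbone
DEPTHS = {
    "outgroup_far": 0.7,
    "casr_stem": 0.45,
    "v2r_stem": 0.15,
    "clade_internode": 0.08,
    "clade_stem": 0.15,
    "anchor": 0.02,
    "subfamily_stem": 0.10,
    "marker": 0.02,
    "species_scale": 1.0,  # species-tree lengths are already subs/site
    "expansion": 0.06,
}


@dataclass
class FixtureConfig:
    species_newick: str = "(spA:0.12,spB:0.12);"
    n_v2r2: int = 1
    n_ancv2r: int = 1
    n_tv2r: int = 3
    fv2r_subfamilies: tuple[int, ...] = (3, 3, 2)  # marker-bearing subfamilies
    n_novel: int = 2  # genes in the marker-free (novel) subfamily
    pseudo_rate: float = 0.2
    genome: sim.GenomeParams = field(default_factory=sim.GenomeParams)
    introns: sim.IntronParams = field(default_factory=sim.IntronParams)


@dataclass
class FamilyFixture:
    species_tree: dendropy.Tree
    family_tree: dendropy.Tree  # rooted, includes panel leaves
    panel: ReferencePanel
    truth_labels: dict[str, tuple[str, str]]  # gene_id -> (clade, subfamily)
    proteins: dict[str, str]  # every leaf incl panel ids
    genomes: dict[str, sim.SyntheticGenome]
    truth_records: list[sim.TruthRecord]
    queries: list[TMQuery]

    def gene_ids(self) -> list[str]:
        return sorted(self.truth_labels)


def _leaf(tns, label: str, length: float) -> dendropy.Node:
    node = dendropy.Node()
    node.taxon = tns.new_taxon(label)
    node.edge.length = length
    return node


def _join(children: list[dendropy.Node], stem: float, rng) -> dendropy.Node:
    """Random binary join of subtrees under one node with edge ``stem``."""
    nodes = list(children)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.01, DEPTHS["expansion"]))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    nodes[0].edge.length = stem
    return nodes[0]


def _species_backbone(species_tree, tns, rng, per_species_leaves):
    """Copy the species-tree topology; each species leaf becomes either a
    single gene leaf or a random expansion subtree of its genes."""

    def copy(node):
        if node.is_leaf():
            sp = node.taxon.label
            labels = per_species_leaves[sp]
            if not labels:
                return None
            leaves = [_leaf(tns, lab, float(rng.uniform(0.02, DEPTHS["expansion"])))
                      for lab in labels]
            if len(leaves) == 1:
                leaves[0].edge.length = node.edge.length or 0.0
                return leaves[0]
            sub = _join(leaves, node.edge.length or 0.0, rng)
            return sub
        kids = [copy(ch) for ch in node.child_nodes()]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].edge.length = (kids[0].edge.length or 0.0) + (
                node.edge.length or 0.0
            )
            return kids[0]
        parent = dendropy.Node()
        parent.edge.length = node.edge.length or 0.0
        for k in kids:
            parent.add_child(k)
        return parent

    return copy(species_tree.seed_node)


def build_family(config: FixtureConfig, seed: int) -> FamilyFixture:
    """Assemble the family tree + panel + sequences + planted genomes."""
    ss = np.random.SeedSequence(seed)
    s_topo, s_seq, s_plant = ss.spawn(3)
    rng = np.random.default_rng(s_topo)

    species_tree = read_tree(config.species_newick)
    species_tree.is_rooted = True
    species = sorted(lf.taxon.label for lf in species_tree.leaf_node_iter())

    tree = dendropy.Tree(taxon_namespace=dendropy.TaxonNamespace())
    tns = tree.taxon_namespace
    truth: dict[str, tuple[str, str]] = {}
    counter = {c: 0 for c in sim.CLADES}

    def gene_labels(clade, sp, n, subfamily=""):
        out = []
        for _ in range(n):
            counter[clade] += 1
            gid = f"{sp}|{clade}{counter[clade]:03d}"
            truth[gid] = (clade, subfamily)
            out.append(gid)
        return out

    def clade_subtree(clade, n_per_species, subfamily=""):
        per_sp = {sp: gene_labels(clade, sp, n_per_species, subfamily)
                  for sp in species}
        return _species_backbone(species_tree, tns, rng, per_sp)

    def with_anchor(subtree, anchor_id, stem):
        node = dendropy.Node()
        node.edge.length = stem
        node.add_child(_leaf(tns, anchor_id, DEPTHS["anchor"]))
        subtree.edge.length = 0.03
        node.add_child(subtree)
        return node

    v2r2 = with_anchor(clade_subtree("V2R2", config.n_v2r2),
                       "REF|V2R2_anchor", DEPTHS["clade_stem"])
    ancv2r = with_anchor(clade_subtree("ancV2R", config.n_ancv2r),
                         "REF|ancV2R_anchor", DEPTHS["clade_stem"])
    tv2r = with_anchor(clade_subtree("tV2R", config.n_tv2r),
                       "REF|tV2R_anchor", DEPTHS["clade_stem"])

    # f-V2R: marker-bearing subfamilies plus one marker-free (novel) one
    sub_nodes = []
    markers = {}
    for k, n in enumerate(config.fv2r_subfamilies, start=1):
        sub = clade_subtree("fV2R", n, subfamily=str(k))
        node = dendropy.Node()
        node.edge.length = DEPTHS["subfamily_stem"]
        node.add_child(_leaf(tns, f"REF|fsub{k}_marker", DEPTHS["marker"]))
        sub.edge.length = 0.03
        node.add_child(sub)
        markers[str(k)] = [f"REF|fsub{k}_marker"]
        sub_nodes.append(node)
    if config.n_novel:
        # marker-free subfamily: detected as a novel "a1"-style clade
        novel = clade_subtree("fV2R", config.n_novel, subfamily="novel")
        novel.edge.length = DEPTHS["subfamily_stem"]
        sub_nodes.append(novel)
    fv2r_core = sub_nodes[0]
    for nxt in sub_nodes[1:]:
        parent = dendropy.Node()
        parent.edge.length = 0.04
        parent.add_child(fv2r_core)
        parent.add_child(nxt)
        fv2r_core = parent
    fv2r = dendropy.Node()
    fv2r.edge.length = DEPTHS["clade_stem"]
    fv2r.add_child(_leaf(tns, "REF|fV2R_anchor", DEPTHS["anchor"]))
    fv2r_core.edge.length = 0.03
    fv2r.add_child(fv2r_core)

    ft = dendropy.Node()
    ft.edge.length = DEPTHS["clade_internode"]
    ft.add_child(fv2r)
    ft.add_child(tv2r)
    anc_ft = dendropy.Node()
    anc_ft.edge.length = DEPTHS["clade_internode"]
    anc_ft.add_child(ancv2r)
    anc_ft.add_child(ft)
    v2r_root = dendropy.Node()
    v2r_root.edge.length = DEPTHS["v2r_stem"]
    v2r_root.add_child(v2r2)
    v2r_root.add_child(anc_ft)

    casr_node = dendropy.Node()
    casr_node.edge.length = 0.05
    casr_node.add_child(_leaf(tns, "OUT|CaSR1", DEPTHS["casr_stem"]))
    casr_node.add_child(v2r_root)

    other_names = ["Tas1r1", "Tas1r2", "GRM1", "GABAB1", "GPCR6"]
    other_leaves = [_leaf(tns, f"OUT|{n}", DEPTHS["outgroup_far"])
                    for n in other_names]
    others = _join(other_leaves, 0.05, rng)

    tree.seed_node.add_child(others)
    tree.seed_node.add_child(casr_node)
    tree.is_rooted = True

    panel = ReferencePanel(
        outgroups={
            "CaSR": ["OUT|CaSR1"],
            "Tas1r": ["OUT|Tas1r1", "OUT|Tas1r2"],
            "GRM": ["OUT|GRM1"],
            "GABAB": ["OUT|GABAB1"],
            "GPCR6": ["OUT|GPCR6"],
        },
        clade_anchors={c: [f"REF|{c}_anchor"] for c in sim.CLADES},
        subfamily_markers=markers,
    )

    seq_rng = np.random.default_rng(s_seq)
    root_protein = "".join(seq_rng.choice(list(sim.AA20), size=ROOT_PROTEIN_LEN))
    proteins = sim.evolve_sequences(
        tree, root_protein, subst_rate=1.0,
        seed=int(s_seq.generate_state(1)[0] % (2**31)),
    )

    genomes: dict[str, sim.SyntheticGenome] = {}
    records: list[sim.TruthRecord] = []
    plant_seeds = s_plant.spawn(len(species))
    for sp, ps in zip(species, plant_seeds):
        specs = [
            sim.PlantSpec(gid, sp, truth[gid][0], truth[gid][1], proteins[gid])
            for gid in sorted(truth)
            if gid.startswith(sp + "|")
        ]
        genome, recs = sim.plant_genes(
            specs, config.genome, config.pseudo_rate, config.introns,
            seed=int(ps.generate_state(1)[0] % (2**31)),
            pseudo_eligible_clades=("fV2R", "tV2R"),
        )
        genomes[sp] = genome
        records.extend(recs)

    queries = extract_fixture_queries(proteins, panel)
    return FamilyFixture(
        species_tree=species_tree,
        family_tree=tree,
        panel=panel,
        truth_labels=truth,
        proteins=proteins,
        genomes=genomes,
        truth_records=records,
        queries=queries,
    )


def extract_fixture_queries(
    proteins: dict[str, str], panel: ReferencePanel
) -> list[TMQuery]:
    """TM-region queries from the clade anchors.

    The anchors are near-ancestral sequences; the query spans 50 aa
    upstream of TM1 to 50 aa downstream of TM7 (clamped), mirroring how
    search queries are carved out of a seed alignment.
    """
    start = max(TM_INTERVALS[0][0] - TM_FLANK, 0)
    end = min(TM_INTERVALS[-1][1] + TM_FLANK, ROOT_PROTEIN_LEN)
    out = []
    for clade, ids in sorted(panel.clade_anchors.items()):
        for aid in ids:
            out.append(
                TMQuery(
                    query_id=f"TMq_{clade}",
                    sequence=proteins[aid][start:end],
                    provenance=f"anchor {aid}, TM1-{TM_FLANK}aa..TM7+{TM_FLANK}aa",
                )
            )
    return out


def default_fixture(seed: int = 20) -> FamilyFixture:
    """The standard two-species, 30-gene, 20%-pseudogene fixture."""
    return build_family(FixtureConfig(), seed)


# ---------------------------------------------------------------------------
# evaluation against truth


def _cds_overlap(exons_a, exons_b) -> int:
    total = 0
    for s1, e1 in exons_a:
        for s2, e2 in exons_b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


TRUTH_TO_MODEL_STATUS = {
    "stop": "pseudo_stop",
    "frameshift": "pseudo_frameshift",
    "truncated": "too_short",
}


def evaluate_mining(models, truth_records) -> dict:
    """Recall/precision for intact genes and pseudogene-reason fidelity.

    A planted intact gene is recovered when an intact model's CDS covers
    >= 90% of its planted CDS; an intact model is a true positive when
    >= 90% of its own CDS lies on a planted intact gene.
    """
    truth_genes = [r for r in truth_records if r.status != "landmark"]
    intact_truth = [r for r in truth_genes if r.status == "intact"]
    pseudo_truth = [r for r in truth_genes if r.status in TRUTH_TO_MODEL_STATUS]
    intact_models = [m for m in models if m.status == "intact"]

    def cds_len(exons):
        return sum(e - s for s, e in exons)

    recovered = 0
    for rec in intact_truth:
        for m in intact_models:
            if m.scaffold != rec.scaffold:
                continue
            if _cds_overlap(m.exons, rec.exons) >= 0.9 * cds_len(rec.exons):
                recovered += 1
                break
    tp = 0
    for m in intact_models:
        for rec in intact_truth:
            if m.scaffold != rec.scaffold:
                continue
            if _cds_overlap(m.exons, rec.exons) >= 0.9 * m.cds_len:
                tp += 1
                break
    reason_ok = 0
    for rec in pseudo_truth:
        want = TRUTH_TO_MODEL_STATUS[rec.status]
        for m in models:
            if m.scaffold != rec.scaffold:
                continue
            if _cds_overlap(m.exons, rec.exons) > 0 and m.status == want:
                reason_ok += 1
                break
    return {
        "n_truth_intact": len(intact_truth),
        "n_truth_pseudo": len(pseudo_truth),
        "n_models_intact": len(intact_models),
        "recall": recovered / len(intact_truth) if intact_truth else 1.0,
        "precision": tp / len(intact_models) if intact_models else 1.0,
        "pseudo_reason_accuracy": (
            reason_ok / len(pseudo_truth) if pseudo_truth else 1.0
        ),
    }


def evaluate_assignments(assignments, truth_labels) -> dict:
    """Clade / subfamily accuracy of tree-based assignment vs truth."""
    n = n_clade = n_sub = n_sub_ok = 0
    for a in assignments:
        if a.gene_id not in truth_labels:
            continue
        clade, sub = truth_labels[a.gene_id]
        n += 1
        if a.clade == clade:
            n_clade += 1
        if clade == "fV2R" and sub and sub != "novel":
            n_sub += 1
            if a.subfamily == sub:
                n_sub_ok += 1
    return {
        "n_genes": n,
        "clade_accuracy": n_clade / n if n else 1.0,
        "subfamily_accuracy": n_sub_ok / n_sub if n_sub else 1.0,
    }
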