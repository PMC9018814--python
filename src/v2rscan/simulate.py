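"""Synthetic genomes and receptor gene families with known truth.

The generator emulates the genomic architecture of a vomeronasal
type-2-receptor (V2R) repertoire so the whole mining/classification
pipeline can be exercised offline:

* per-clade gene histories from a linear birth-death process along a
  species tree (lineage-specific expansions, forced clade losses);
* protein evolution by i.i.d. per-site Poisson substitutions with
  uniform replacement (closed-form expectations, easy to test);
* multi-exon genes (GT..AG introns, phase 0) back-translated with a
  fixed codon per amino acid and embedded in random background DNA;
* the fish-type (f-V2R) genes inside a cluster flanked by two landmark
  genes (PLC eta1, neprilysin) with the single-copy V2R2/ancV2R genes
  in tandem next to the left landmark, and tetrapod-type (t-V2R) genes
  dispersed on a separate scaffold;
* planted pseudogenes: an in-frame stop, a 1-2 nt frameshift indel, or
  truncation below 600 coding nucleotides.

Every function is deterministic given its seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from ._seq import AA20, backtranslate, revcomp

CLADES = ("V2R2", "ancV2R", "fV2R", "tV2R")

LANDMARK_PLC = "landmark_PLC"
LANDMARK_NEP = "landmark_neprilysin"


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scenario types


@dataclass
class CladeParams:
    """Birth-death parameters for one receptor clade.

    ``origin`` names the species-tree node (edge above it) on which the
    clade originates; ``forced_loss`` lists nodes whose subtrees lose the
    clade entirely.
    """

    birth: float = 0.0
    death: float = 0.0
    origin: str | None = None  # None = species-tree root
    root_copies: int = 1
    forced_loss: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.birth < 0 or self.death < 0:
            raise ConfigurationError("birth/death rates must be >= 0")
        if self.root_copies < 0:
            raise ConfigurationError("root copy number must be >= 0")


@dataclass
class CladeScenario:
    clades: dict[str, CladeParams]

    def validate(self, species_tree: dendropy.Tree) -> None:
        labels = {_node_name(n) for n in species_tree.preorder_node_iter()}
        for clade, p in self.clades.items():
            p.validate()
            if p.origin is not None and p.origin not in labels:
                raise ConfigurationError(
                    f"origin branch {p.origin!r} for clade {clade} not in tree"
                )
            for fl in p.forced_loss:
                if fl not in labels:
                    raise ConfigurationError(
                        f"forced-loss branch {fl!r} for clade {clade} not in tree"
                    )


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or ""


# ---------------------------------------------------------------------------
# birth-death simulation of one clade


def _sim_branch(rng, node, t, birth, death):
    """Evolve one gene lineage along a species-tree branch of length t.

    ``node`` is the gene-tree node entering the branch; returns surviving
    gene-tree nodes at the bottom (edge lengths accumulated in time units).
    """
    if node.edge.length is None:
        node.edge.length = 0.0
    rate = birth + death
    if rate == 0.0:
        node.edge.length += t
        return [node]
    wait = rng.exponential(1.0 / rate)
    if wait >= t:
        node.edge.length += t
        return [node]
    node.edge.length += wait
    if rng.random() < birth / rate:
        out = []
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            node.add_child(child)
            out.extend(_sim_branch(rng, child, t - wait, birth, death))
        return out
    return []  # death


def simulate_family(
    species_tree: dendropy.Tree,
    scenario: CladeScenario,
    seed: int,
) -> tuple[dict[str, dendropy.Tree], dict[str, dict[str, int]]]:
    """Simulate per-clade gene trees along ``species_tree``.

    Returns ``(gene_trees, counts)``: one gene tree per clade (leaves
    labelled ``species|cladeNNN``; clades that die out completely map to
    ``None``) and per-species per-clade gene counts.
    """
    scenario.validate(species_tree)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(scenario.clades))
    gene_trees: dict[str, dendropy.Tree | None] = {}
    counts: dict[str, dict[str, int]] = {
        lf.taxon.label: {c: 0 for c in scenario.clades}
        for lf in species_tree.leaf_node_iter()
    }

    for (clade, params), cs in zip(sorted(scenario.clades.items()), child_seeds):
        rng = np.random.default_rng(cs)
        origin = species_tree.seed_node
        if params.origin is not None:
            for n in species_tree.preorder_node_iter():
                if _node_name(n) == params.origin:
                    origin = n
                    break
        tree = dendropy.Tree(taxon_namespace=dendropy.TaxonNamespace())
        root = tree.seed_node
        starters = []
        if params.root_copies == 1:
            starters = [root]
        else:
            for _ in range(params.root_copies):
                ch = dendropy.Node()
                ch.edge.length = 0.0
                root.add_child(ch)
                starters.append(ch)
        idx = {"n": 0}

        def descend(sp_node, lineages):
            if not lineages:
                return
            if sp_node.is_leaf():
                sp = sp_node.taxon.label
                for g in lineages:
                    idx["n"] += 1
                    g.taxon = tree.taxon_namespace.new_taxon(
                        f"{sp}|{clade}{idx['n']:03d}"
                    )
                    counts[sp][clade] += 1
                return
            for child in sp_node.child_nodes():
                if _node_name(child) in params.forced_loss:
                    continue
                entries = []
                for g in lineages:
                    gc = dendropy.Node()
                    gc.edge.length = 0.0
                    g.add_child(gc)
                    entries.append(gc)
                survivors = []
                t = child.edge.length or 0.0
                for e in entries:
                    survivors.extend(
                        _sim_branch(rng, e, t, params.birth, params.death)
                    )
                descend(child, survivors)

        # evolve along the origin branch itself, then downward
        t0 = origin.edge.length or 0.0
        survivors = []
        for s in starters:
            survivors.extend(_sim_branch(rng, s, t0, params.birth, params.death))
        if _node_name(origin) in params.forced_loss:
            survivors = []
        descend(origin, survivors)

        _prune_dead(tree)
        gene_trees[clade] = tree if any(tree.leaf_node_iter()) else None
    return gene_trees, counts


def _prune_dead(tree: dendropy.Tree) -> None:
    """Remove lineages with no named descendants; collapse unary nodes."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder_node_iter()):
            if node is tree.seed_node:
                continue
            if node.is_leaf() and node.taxon is None:
                node.parent_node.remove_child(node)
                changed = True
    tree.suppress_unifurcations()


# ---------------------------------------------------------------------------
# sequence evolution


def evolve_sequences(
    gene_tree: dendropy.Tree,
    root_protein: str,
    subst_rate: float,
    seed: int,
) -> dict[str, str]:
    """Evolve ``root_protein`` down ``gene_tree``.

    Per-site substitution events are Poisson with rate ``subst_rate`` per
    site per time unit; each event draws uniformly from the 20 amino
    acids (so back-substitution is possible and the expected fraction of
    changed sites on a branch of length t is (19/20)(1 - exp(-r t))).
    """
    if not root_protein:
        raise ValueError("root protein must be non-empty")
    if subst_rate < 0:
        raise ValueError("substitution rate must be >= 0")
    bad = set(root_protein) - set(AA20)
    if bad:
        raise ValueError(f"non-amino-acid symbols in root protein: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AA20.encode(), dtype=np.uint8)
    idx = {c: i for i, c in enumerate(AA20)}
    root = np.array([idx[c] for c in root_protein], dtype=np.int8)
    seqs: dict[int, np.ndarray] = {id(gene_tree.seed_node): root}
    out: dict[str, str] = {}
    for node in gene_tree.preorder_node_iter():
        if node is gene_tree.seed_node:
            cur = root
        else:
            parent = seqs[id(node.parent_node)]
            t = node.edge.length or 0.0
            p = 1.0 - np.exp(-subst_rate * t)
            cur = parent.copy()
            hit = rng.random(len(cur)) < p
            n_hit = int(hit.sum())
            if n_hit:
                cur[hit] = rng.integers(0, 20, size=n_hit)
        seqs[id(node)] = cur
        if node.is_leaf() and node.taxon is not None:
            out[node.taxon.label] = aa[cur.astype(np.intp)].tobytes().decode()
    return out


# ---------------------------------------------------------------------------
# gene planting


@dataclass
class IntronParams:
    min_count: int = 1
    max_count: int = 3
    min_length: int = 200
    max_length: int = 1500
    min_exon: int = 150

    def validate(self) -> None:
        if self.min_count < 0 or self.max_count < self.min_count:
            raise ConfigurationError("bad intron count range")
        if self.min_length < 4 or self.max_length < self.min_length:
            raise ConfigurationError("bad intron length range")


@dataclass
class GenomeParams:
    cluster_scaffold_length: int = 600_000
    dispersed_scaffold_length: int = 400_000
    min_gap: int = 5_000
    max_gap: int = 15_000
    landmark_protein_length: int = 250


@dataclass
class PlantSpec:
    gene_id: str
    species: str
    clade: str  # V2R2 | ancV2R | fV2R | tV2R
    subfamily: str  # "" unless fV2R
    protein: str


@dataclass
class TruthRecord:
    gene_id: str
    species: str
    clade: str
    subfamily: str
    status: str  # intact | stop | frameshift | truncated | landmark
    scaffold: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    protein: str = ""


@dataclass
class SyntheticGenome:
    species: str
    scaffolds: dict[str, str]


def _random_dna(rng, n: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n).tobytes().decode()


def _pseudogenize(cds: str, reason: str, rng) -> str:
    n_codons = len(cds) // 3
    if reason == "stop":
        pos = int(rng.integers(int(0.2 * n_codons), int(0.8 * n_codons)))
        return cds[: pos * 3] + "TAA" + cds[pos * 3 + 3 :]
    if reason == "frameshift":
        pos = int(rng.integers(int(0.2 * len(cds)), int(0.8 * len(cds))))
        size = int(rng.integers(1, 3))
        if rng.random() < 0.5:
            return cds[:pos] + cds[pos + size :]
        return cds[:pos] + _random_dna(rng, size) + cds[pos:]
    if reason == "truncated":
        return cds[: int(rng.integers(450, 600))]
    raise ConfigurationError(f"unknown pseudogenization reason {reason!r}")


def _split_exons(cds: str, ip: IntronParams, rng) -> list[str]:
    """Split a CDS into exon pieces at codon boundaries (phase-0 introns)."""
    n = len(cds)
    n_codons = n // 3
    m = -(-ip.min_exon // 3)  # min exon size in codons
    n_introns = int(rng.integers(ip.min_count, ip.max_count + 1))
    while n_introns > 0 and n_codons < (n_introns + 1) * m:
        n_introns -= 1
    if n_introns == 0:
        return [cds]
    # stars-and-bars: cut positions with >= m codons between consecutive cuts
    slack = n_codons - (n_introns + 1) * m
    draws = np.sort(rng.integers(0, slack + 1, size=n_introns))
    cuts = [3 * (m * (i + 1) + int(d)) for i, d in enumerate(draws)]
    bounds = [0] + cuts + [n]
    return [cds[a:b] for a, b in zip(bounds, bounds[1:])]


def _build_gene(spec: PlantSpec, status: str, ip: IntronParams, rng):
    """Returns (gene_dna_sense, exon_rel_intervals, cds)."""
    cds = backtranslate(spec.protein)
    if status != "intact":
        cds = _pseudogenize(cds, status, rng)
    pieces = _split_exons(cds, ip, rng)
    seq_parts = []
    exons = []
    pos = 0
    for i, piece in enumerate(pieces):
        exons.append((pos, pos + len(piece)))
        seq_parts.append(piece)
        pos += len(piece)
        if i < len(pieces) - 1:
            ilen = int(rng.integers(ip.min_length, ip.max_length + 1))
            intron = "GT" + _random_dna(rng, ilen - 4) + "AG"
            seq_parts.append(intron)
            pos += ilen
    return "".join(seq_parts), exons, cds


def plant_genes(
    genes: list[PlantSpec],
    genome_params: GenomeParams | None = None,
    pseudo_rate: float = 0.0,
    intron_params: IntronParams | None = None,
    seed: int = 0,
    pseudo_eligible_clades: tuple[str, ...] | None = None,
) -> tuple[SyntheticGenome, list[TruthRecord]]:
    """Embed one species' receptor genes in a synthetic genome.

    f-V2R genes go inside the landmark-flanked cluster scaffold with the
    V2R2 and ancV2R genes in tandem next to the PLC-eta1 landmark; t-V2R
    genes go on a separate scaffold.  ``pseudo_rate`` of the genes (the
    exact rounded count) are pseudogenized with reasons cycled through
    stop / frameshift / truncated; ``pseudo_eligible_clades`` restricts
    which clades may decay (default: all — pass the expanded clades to
    keep the ancient single-copy genes intact, as observed in real
    repertoires).
    """
    if not 0.0 <= pseudo_rate <= 1.0:
        raise ConfigurationError("pseudo_rate must be in [0, 1]")
    gp = genome_params or GenomeParams()
    ip = intron_params or IntronParams()
    ip.validate()
    species = {g.species for g in genes}
    if len(species) != 1:
        raise ConfigurationError("plant_genes expects genes of a single species")
    sp = species.pop()
    rng = np.random.default_rng(seed)

    n_pseudo = int(round(pseudo_rate * len(genes)))
    eligible = [
        i for i, g in enumerate(genes)
        if pseudo_eligible_clades is None or g.clade in pseudo_eligible_clades
    ]
    order = rng.permutation(len(eligible))
    reasons = ["stop", "frameshift", "truncated"]
    statuses = {g.gene_id: "intact" for g in genes}
    for k in range(min(n_pseudo, len(eligible))):
        statuses[genes[eligible[order[k]]].gene_id] = reasons[k % 3]

    cluster_name = f"{sp}_cluster_scaf"
    dispersed_name = f"{sp}_scaf2"
    landmark_prot_plc = "".join(
        rng.choice(list(AA20), size=gp.landmark_protein_length)
    )
    landmark_prot_nep = "".join(
        rng.choice(list(AA20), size=gp.landmark_protein_length)
    )

    by_clade = {c: [g for g in genes if g.clade == c] for c in CLADES}
    unknown = [g for g in genes if g.clade not in CLADES]
    if unknown:
        raise ConfigurationError(
            f"unknown clade labels: {sorted({g.clade for g in unknown})}"
        )

    truth: list[TruthRecord] = []
    scaffolds: dict[str, str] = {}

    def place(scaf_name, scaf_len, items):
        """items: list of (kind, spec_or_protein, status)."""
        background = np.frombuffer(
            _random_dna(rng, scaf_len).encode(), dtype=np.uint8
        ).copy()
        pos = int(rng.integers(gp.min_gap, gp.max_gap))
        for kind, payload, status in items:
            if kind == "landmark":
                name, prot = payload
                dna = backtranslate(prot)
                exons_rel = [(0, len(dna))]
                strand = "+"
            else:
                spec = payload
                dna, exons_rel, _cds = _build_gene(spec, status, ip, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    L = len(dna)
                    dna = revcomp(dna)
                    exons_rel = sorted((L - e, L - s) for s, e in exons_rel)
            end = pos + len(dna)
            if end + gp.min_gap > scaf_len:
                raise ConfigurationError(
                    f"scaffold {scaf_name} too small for requested layout"
                )
            background[pos:end] = np.frombuffer(dna.encode(), dtype=np.uint8)
            exons_abs = [(pos + s, pos + e) for s, e in exons_rel]
            if kind == "landmark":
                truth.append(
                    TruthRecord(
                        gene_id=f"{sp}|{payload[0]}",
                        species=sp,
                        clade=payload[0],
                        subfamily="",
                        status="landmark",
                        scaffold=scaf_name,
                        start=pos,
                        end=end,
                        strand="+",
                        exons=exons_abs,
                        protein=payload[1],
                    )
                )
            else:
                truth.append(
                    TruthRecord(
                        gene_id=spec.gene_id,
                        species=sp,
                        clade=spec.clade,
                        subfamily=spec.subfamily,
                        status=status,
                        scaffold=scaf_name,
                        start=pos,
                        end=end,
                        strand=strand,
                        exons=exons_abs,
                        protein=spec.protein,
                    )
                )
            pos = end + int(rng.integers(gp.min_gap, gp.max_gap))
        scaffolds[scaf_name] = background.tobytes().decode()

    cluster_items = [("landmark", (LANDMARK_PLC, landmark_prot_plc), "landmark")]
    for g in by_clade["V2R2"] + by_clade["ancV2R"] + by_clade["fV2R"]:
        cluster_items.append(("gene", g, statuses[g.gene_id]))
    cluster_items.append(("landmark", (LANDMARK_NEP, landmark_prot_nep), "landmark"))
    place(cluster_name, gp.cluster_scaffold_length, cluster_items)

    dispersed_items = [("gene", g, statuses[g.gene_id]) for g in by_clade["tV2R"]]
    place(dispersed_name, gp.dispersed_scaffold_length, dispersed_items)

    return SyntheticGenome(species=sp, scaffolds=scaffolds), truth


# ---------------------------------------------------------------------------
# fixture I/O


def write_fasta(path: str, records: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fixture(
    genomes: list[SyntheticGenome],
    truth: list[TruthRecord],
    species_tree: dendropy.Tree,
    outdir: str,
) -> dict[str, str]:
    """Write FASTA / GFF3 / newick / TSV artefacts; returns path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for genome in genomes:
        p = os.path.join(outdir, f"genome_{genome.species}.fa")
        write_fasta(p, genome.scaffolds)
        paths[f"genome_{genome.species}"] = p

    gff = os.path.join(outdir, "truth.gff3")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in truth:
            attrs = (
                f"ID={rec.gene_id};clade={rec.clade};subfamily={rec.subfamily};"
                f"status={rec.status};species={rec.species}"
            )
            fh.write(
                "\t".join(
                    [
                        rec.scaffold,
                        "v2rscan_sim",
                        "gene",
                        str(rec.start + 1),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for k, (s, e) in enumerate(rec.exons):
                for ftype in ("exon", "CDS"):
                    fh.write(
                        "\t".join(
                            [
                                rec.scaffold,
                                "v2rscan_sim",
                                ftype,
                                str(s + 1),
                                str(e),
                                ".",
                                rec.strand,
                                "0" if ftype == "CDS" else ".",
                                f"ID={rec.gene_id}.{ftype}{k};Parent={rec.gene_id}",
                            ]
                        )
                        + "\n"
                    )
    paths["gff3"] = gff

    from .phylogeny import write_tree

    nwk = os.path.join(outdir, "species_tree.nwk")
    with open(nwk, "w") as fh:
        fh.write(write_tree(species_tree))
    paths["species_tree"] = nwk

    tsv = os.path.join(outdir, "truth.tsv")
    with open(tsv, "w") as fh:
        fh.write(
            "gene_id\tspecies\tclade\tsubfamily\tstatus\tscaffold\tstart\tend\tstrand\n"
        )
        for rec in truth:
            fh.write(
                f"{rec.gene_id}\t{rec.species}\t{rec.clade}\t{rec.subfamily}\t"
                f"{rec.status}\t{rec.scaffold}\t{rec.start}\t{rec.end}\t{rec.strand}\n"
            )
    paths["truth"] = tsv
    return paths


def read_truth_gff3(path: str) -> list[TruthRecord]:
    """Round-trip reader for the fixture GFF3 (gene features only)."""
    genes: dict[str, TruthRecord] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            if f[2] == "gene":
                genes[attrs["ID"]] = TruthRecord(
                    gene_id=attrs["ID"],
                    species=attrs.get("species", ""),
                    clade=attrs.get("clade", ""),
                    subfamily=attrs.get("subfamily", ""),
                    status=attrs.get("status", ""),
                    scaffold=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6],
                )
            elif f[2] == "exon":
                parent = attrs["Parent"]
                genes[parent].exons.append((int(f[3]) - 1, int(f[4])))
    for rec in genes.values():
        rec.exons.sort()
    return list(genes.values())


# ---------------------------------------------------------------------------
# convenience: whole-genome-duplication style gene trees


def simulate_wgd_family(
    n_families: int,
    focal: str = "teleost",
    reference: str = "gar",
    duplicated: bool = True,
    seed: int = 0,
) -> dendropy.Tree:
    """Gene tree for a 2:1 co-ortholog test.

    With ``duplicated`` every reference gene has exactly two focal
    co-orthologs (the post-duplication pattern); without, exactly one.
    """
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree(taxon_namespace=dendropy.TaxonNamespace())
    tns = tree.taxon_namespace
    backbone = tree.seed_node
    for i in range(n_families):
        fam = dendropy.Node()
        fam.edge.length = float(rng.uniform(0.05, 0.2))
        ref = dendropy.Node()
        ref.edge.length = 0.3
        ref.taxon = tns.new_taxon(f"{reference}|g{i:03d}")
        fam.add_child(ref)
        if duplicated:
            dup = dendropy.Node()
            dup.edge.length = 0.15
            for j in range(2):
                leaf = dendropy.Node()
                leaf.edge.length = 0.15
                leaf.taxon = tns.new_taxon(f"{focal}|g{i:03d}_{'ab'[j]}")
                dup.add_child(leaf)
            fam.add_child(dup)
        else:
            leaf = dendropy.Node()
            leaf.edge.length = 0.3
            leaf.taxon = tns.new_taxon(f"{focal}|g{i:03d}")
            fam.add_child(leaf)
        # caterpillar backbone keeps the tree binary
        if i < n_families - 1:
            nxt = dendropy.Node()
            nxt.edge.length = 0.05
            backbone.add_child(fam)
            backbone.add_child(nxt)
            backbone = nxt
        else:
            backbone.add_child(fam)
    tree.suppress_unifurcations()
    tree.is_rooted = True
    return tree
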