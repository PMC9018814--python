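"""Configuration and end-to-end orchestration.

``run_pipeline`` executes the whole analysis on a synthetic study:
simulate -> mine -> (cluster) -> align/tree -> classify -> synteny ->
copy-number evolution, writing every intermediate artefact plus a
provenance record (config hash, seed, per-stage counts).  Reruns with
the same config are byte-identical.

A single global seed is fanned out to the stages by fixed offsets so
stages stay independently reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import yaml

from . import curation, evo_dynamics, mining, phylogeny, synteny
from .classification import (
    assign_major_clade,
    assign_subfamily,
    copy_number_table,
    species_of,
)
from .fixtures import FixtureConfig, build_family
from .mining import SearchParams, TMQuery
from .phylogeny import MSA
from .simulate import write_fasta, write_fixture

log = logging.getLogger("v2rscan")

SEED_OFFSETS = {"simulate": 0, "bootstrap": 1}

DEFAULT_CONFIG: dict = {
    "seed": 20,
    "outdir": "v2r_out",
    "fixture": {
        "species_newick": "(spA:0.12,spB:0.12);",
        "pseudo_rate": 0.2,
    },
    "mining": {
        "k": 3,
        "T": 11,
        "xdrop": 20.0,
        "evalue_cutoff": 1e-5,
        "min_cds_len": 600,
        "min_intron": 40,
        "frameshift_penalty": 15.0,
    },
    "curation": {"threshold": 0.8, "species": []},
    "phylogeny": {"min_cov": 0.5, "bootstrap": 100, "outgroup": ["OUT|CaSR1"]},
    "classification": {"support_min": 50.0},
    "evo": {"fold_min": 2.0, "abs_min": 40},
}


def load_config(source: str | dict | None = None) -> dict:
    """Merge a YAML file / dict over the defaults; unknown keys error."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if source is None:
        return cfg
    user = source
    if isinstance(source, str):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}

    def merge(base: dict, over: dict, path: str) -> None:
        for key, val in over.items():
            if key not in base:
                raise ValueError(f"unknown config key {path + key!r}")
            if isinstance(base[key], dict):
                if not isinstance(val, dict):
                    raise ValueError(f"config key {path + key!r} expects a mapping")
                merge(base[key], val, path + key + ".")
            else:
                base[key] = val

    merge(cfg, user, "")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# TM-region query extraction


@dataclass
class TMAnnotation:
    """Seven TM-helix intervals on the reference row of a seed alignment,
    in ungapped reference coordinates (0-based half-open)."""

    reference_id: str
    intervals: list[tuple[int, int]]

    def validate(self, ref_len: int) -> None:
        if len(self.intervals) != 7:
            raise ValueError("TM annotation must contain exactly 7 intervals")
        prev_end = 0
        for s, e in self.intervals:
            if s < prev_end or e <= s:
                raise ValueError("TM intervals must be sorted and non-overlapping")
            prev_end = e
        if prev_end > ref_len:
            raise ValueError("TM intervals exceed the reference length")


def extract_tm_query(
    seed_msa: MSA, tm_annotation: TMAnnotation, flank: int = 50
) -> list[TMQuery]:
    """Carve TM1-flank .. TM7+flank out of every alignment member.

    Coordinates are defined on the annotated reference sequence, mapped
    through the alignment columns, and clamped to sequence bounds;
    members that are entirely gapped in the region are skipped.
    """
    rows = seed_msa.rows()
    if tm_annotation.reference_id not in rows:
        raise ValueError(
            f"reference {tm_annotation.reference_id!r} not in alignment"
        )
    ref = rows[tm_annotation.reference_id]
    ref_len = sum(1 for c in ref if c != "-")
    tm_annotation.validate(ref_len)
    q_start = max(tm_annotation.intervals[0][0] - flank, 0)
    q_end = min(tm_annotation.intervals[-1][1] + flank, ref_len)
    col_of = []
    for col, c in enumerate(ref):
        if c != "-":
            col_of.append(col)
    c1, c2 = col_of[q_start], col_of[q_end - 1] + 1
    out = []
    for sid, row in rows.items():
        seq = row[c1:c2].replace("-", "")
        if not seq:
            continue
        out.append(
            TMQuery(
                query_id=f"TMq_{sid}",
                sequence=seq,
                provenance=(
                    f"alignment region ref[{q_start}:{q_end}] "
                    f"(TM1-{flank}aa..TM7+{flank}aa on {tm_annotation.reference_id})"
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# pipeline


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: dict | str | None = None) -> dict:
    """Execute every stage on a synthetic study; returns the result bundle."""
    cfg = load_config(config)
    seed = int(cfg["seed"])
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    bundle: dict = {"config": cfg, "config_hash": config_hash(cfg)}
    provenance: dict = {"config_hash": bundle["config_hash"], "seed": seed,
                        "stages": {}}

    # -- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        fixture = build_family(
            FixtureConfig(
                species_newick=cfg["fixture"]["species_newick"],
                pseudo_rate=float(cfg["fixture"]["pseudo_rate"]),
            ),
            seed + SEED_OFFSETS["simulate"],
        )
        paths = write_fixture(
            list(fixture.genomes.values()),
            fixture.truth_records,
            fixture.species_tree,
            os.path.join(outdir, "fixture"),
        )
        write_fasta(
            os.path.join(outdir, "fixture", "queries.fa"),
            {q.query_id: q.sequence for q in fixture.queries},
        )
        bundle["fixture"] = fixture
        provenance["stages"][stage] = {
            "n_genes": len(fixture.truth_labels),
            "n_queries": len(fixture.queries),
        }
        log.info("%s: %d genes, %d queries", stage,
                 len(fixture.truth_labels), len(fixture.queries))
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- mine ---------------------------------------------------------------
    stage = "mine"
    try:
        params = SearchParams(**{k: v for k, v in cfg["mining"].items()})
        models = {}
        proteins: dict[str, str] = {}
        statuses: dict[str, str] = {}
        for sp in sorted(fixture.genomes):
            ms = mining.mine_genome(fixture.genomes[sp].scaffolds,
                                    fixture.queries, params)
            models[sp] = ms
            for m in ms:
                gid = f"{sp}|{m.model_id}"
                proteins[gid] = m.protein.replace("*", "X")
                statuses[gid] = m.status
            with open(os.path.join(outdir, f"models_{sp}.gff3"), "w") as fh:
                fh.write(mining.models_to_gff3(ms))
        write_fasta(os.path.join(outdir, "model_proteins.fa"), proteins)
        bundle["models"] = models
        bundle["statuses"] = statuses
        provenance["stages"][stage] = {
            sp: {
                "n_models": len(ms),
                "n_intact": sum(1 for m in ms if m.status == "intact"),
            }
            for sp, ms in models.items()
        }
        log.info("%s: %s", stage, provenance["stages"][stage])
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- cluster ------------------------------------------------------------
    stage = "cluster"
    try:
        rep_map: dict[str, str] = {}
        keep = dict(proteins)
        for sp in cfg["curation"]["species"]:
            sp_prot = {g: s for g, s in proteins.items()
                       if species_of(g) == sp and statuses[g] == "intact"}
            clusters = curation.greedy_cluster(
                sp_prot, float(cfg["curation"]["threshold"])
            )
            reps, mapping = curation.pick_representatives(clusters)
            rep_map.update(mapping)
            for gid in sp_prot:
                if gid not in reps:
                    keep.pop(gid)
        bundle["representative_map"] = rep_map
        provenance["stages"][stage] = {"n_after": len(keep)}
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- tree ---------------------------------------------------------------
    stage = "tree"
    try:
        intact_ids = {g for g in keep if statuses.get(g) == "intact"}
        tree_prot = {g: keep[g] for g in sorted(intact_ids)}
        tree_prot.update(
            {pid: fixture.proteins[pid] for pid in sorted(fixture.panel.all_ids())}
        )
        msa = phylogeny.progressive_align(tree_prot)
        msa = phylogeny.filter_columns(msa, float(cfg["phylogeny"]["min_cov"]))
        tree = phylogeny.bootstrap(
            msa,
            n=int(cfg["phylogeny"]["bootstrap"]),
            seed=seed + SEED_OFFSETS["bootstrap"],
        )
        tree = phylogeny.root_with_outgroup(tree, set(cfg["phylogeny"]["outgroup"]))
        with open(os.path.join(outdir, "gene_tree.nwk"), "w") as fh:
            fh.write(phylogeny.write_tree(tree))
        bundle["msa"] = msa
        bundle["tree"] = tree
        provenance["stages"][stage] = {
            "n_tips": len(tree_prot), "n_columns": msa.n_cols
        }
        log.info("%s: %d tips, %d columns", stage, len(tree_prot), msa.n_cols)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- classify -----------------------------------------------------------
    stage = "classify"
    try:
        support_min = float(cfg["classification"]["support_min"])
        assignments = assign_major_clade(tree, fixture.panel, support_min)
        assignments = assign_subfamily(tree, fixture.panel, assignments, support_min)
        # expand cluster representatives back to members
        expanded = list(assignments)
        by_id = {a.gene_id: a for a in assignments}
        for member, rep in rep_map.items():
            if member not in by_id and rep in by_id:
                a = by_id[rep]
                expanded.append(
                    type(a)(member, a.clade, a.subfamily, a.support, a.fallback)
                )
        table = copy_number_table(expanded, statuses)
        table.to_csv(os.path.join(outdir, "copy_numbers.tsv"), sep="\t")
        with open(os.path.join(outdir, "assignments.tsv"), "w") as fh:
            fh.write("gene_id\tclade\tsubfamily\tsupport\tfallback\n")
            for a in sorted(expanded, key=lambda a: a.gene_id):
                fh.write(
                    f"{a.gene_id}\t{a.clade}\t{a.subfamily}\t{a.support:.0f}\t"
                    f"{int(a.fallback)}\n"
                )
        bundle["assignments"] = expanded
        bundle["copy_table"] = table
        provenance["stages"][stage] = {"n_assigned": len(expanded)}
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- synteny ------------------------------------------------------------
    stage = "synteny"
    try:
        landmark_loci = [
            l
            for l in synteny.loci_from_truth(fixture.truth_records)
            if l.name_class.startswith("landmark")
        ]
        model_loci = []
        clade_of = {}
        for sp, ms in models.items():
            for m in ms:
                gid = f"{sp}|{m.model_id}"
                model_loci.append(
                    synteny.GeneLocus(gid, m.scaffold, m.start, m.end,
                                      m.strand, "v2r")
                )
                a = next((x for x in bundle["assignments"] if x.gene_id == gid), None)
                if a is not None:
                    clade_of[gid] = a.clade
        clusters = synteny.delimit_clusters(landmark_loci + model_loci)
        labels, contingency = synteny.classify_by_cluster(
            model_loci, clusters, clade_of
        )
        report = synteny.cluster_report(
            clusters, landmark_loci + model_loci, clade_of
        )
        with open(os.path.join(outdir, "synteny_report.tsv"), "w") as fh:
            fh.write(synteny.report_to_tsv(report))
        bundle["synteny"] = {
            "clusters": clusters,
            "labels": labels,
            "contingency": contingency,
            "report": report,
        }
        provenance["stages"][stage] = {"n_clusters": len(clusters)}
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- evolve -------------------------------------------------------------
    stage = "evolve"
    try:
        clade_cols = ["V2R2", "ancV2R", "tV2R"]
        table = bundle["copy_table"]
        agg = table[clade_cols].copy()
        fcols = [c for c in table.columns if c.startswith("fV2R")]
        agg["fV2R"] = table[fcols].sum(axis=1)
        presence = evo_dynamics.build_presence_matrix(agg)
        events = evo_dynamics.dollo_reconstruct(presence, fixture.species_tree)
        totals = {sp: int(table.loc[sp, "total"]) for sp in table.index}
        states, deltas = evo_dynamics.ancestral_copy_numbers(
            totals, fixture.species_tree
        )
        expansions = evo_dynamics.detect_expansions(
            states, deltas, fixture.species_tree,
            float(cfg["evo"]["fold_min"]), int(cfg["evo"]["abs_min"]),
        )
        presence.to_csv(os.path.join(outdir, "presence_absence.tsv"), sep="\t")
        bundle["presence"] = presence
        bundle["events"] = events
        bundle["ancestral_totals"] = states
        bundle["expansions"] = expansions
        provenance["stages"][stage] = {"n_expansions": len(expansions)}
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    bundle["provenance"] = provenance
    return bundle
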