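"""Landmark-flanked cluster analysis.

Fish-type V2R genes sit in one chromosomal cluster flanked by two
landmark genes, PLC eta1 and neprilysin, with the single-copy V2R2 and
ancV2R genes in tandem next to PLC eta1; tetrapod-type genes live on
other chromosomes.  This module delimits those clusters from an
annotation, classifies genes as in/out of cluster, and renders ordered
gene-arrangement reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .simulate import LANDMARK_NEP, LANDMARK_PLC, TruthRecord, read_truth_gff3


@dataclass
class GeneLocus:
    gene_id: str
    scaffold: str
    start: int  # 0-based half-open, forward
    end: int
    strand: str
    name_class: str  # landmark_PLC | landmark_neprilysin | v2r | other

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval for {self.gene_id}")


@dataclass
class SyntenyCluster:
    scaffold: str
    start: int  # inner edge of the left landmark
    end: int  # inner edge of the right landmark
    plc: GeneLocus
    neprilysin: GeneLocus
    members: list[GeneLocus] = field(default_factory=list)

    @property
    def flank_orientation(self) -> str:
        return "PLC-first" if self.plc.start < self.neprilysin.start else "NEP-first"


def loci_from_truth(records: list[TruthRecord]) -> list[GeneLocus]:
    out = []
    for rec in records:
        if rec.clade in (LANDMARK_PLC, LANDMARK_NEP):
            nc = rec.clade
        elif rec.clade in ("V2R2", "ancV2R", "fV2R", "tV2R"):
            nc = "v2r"
        else:
            nc = "other"
        out.append(
            GeneLocus(rec.gene_id, rec.scaffold, rec.start, rec.end, rec.strand, nc)
        )
    return out


def loci_from_gff3(path: str) -> list[GeneLocus]:
    return loci_from_truth(read_truth_gff3(path))


def delimit_clusters(loci: list[GeneLocus]) -> list[SyntenyCluster]:
    """Pair nearest PLC-eta1/neprilysin landmarks per scaffold.

    Each disjoint pair delimits one cluster spanning the interval between
    the landmarks' inner edges; overlapping candidate pairs keep the
    smaller interval.
    """
    by_scaffold: dict[str, list[GeneLocus]] = {}
    for l in loci:
        by_scaffold.setdefault(l.scaffold, []).append(l)
    clusters: list[SyntenyCluster] = []
    any_plc = any(l.name_class == LANDMARK_PLC for l in loci)
    any_nep = any(l.name_class == LANDMARK_NEP for l in loci)
    for scaffold in sorted(by_scaffold):
        group = by_scaffold[scaffold]
        plcs = sorted((l for l in group if l.name_class == LANDMARK_PLC),
                      key=lambda l: l.start)
        neps = sorted((l for l in group if l.name_class == LANDMARK_NEP),
                      key=lambda l: l.start)
        pairs = sorted(
            ((p, n) for p in plcs for n in neps),
            key=lambda pn: (
                max(pn[0].end, pn[1].end) - min(pn[0].start, pn[1].start),
                pn[0].start,
            ),
        )
        used: set[str] = set()
        accepted: list[SyntenyCluster] = []
        for p, n in pairs:
            if p.gene_id in used or n.gene_id in used:
                continue
            left, right = (p, n) if p.start <= n.start else (n, p)
            if left.end > right.start:
                continue  # overlapping landmarks: no interval between them
            cand = SyntenyCluster(scaffold, left.end, right.start, p, n)
            if any(c.start < cand.end and cand.start < c.end for c in accepted):
                warnings.warn(
                    f"overlapping landmark pairs on {scaffold}; keeping the "
                    "smaller interval"
                )
                continue
            accepted.append(cand)
            used |= {p.gene_id, n.gene_id}
        clusters.extend(accepted)
    if not clusters and (any_plc or any_nep):
        warnings.warn("landmark genes present but no same-scaffold pair found")
    clusters.sort(key=lambda c: (c.scaffold, c.start))
    return clusters


def classify_by_cluster(
    loci: list[GeneLocus],
    clusters: list[SyntenyCluster],
    assignments: dict[str, str] | None = None,
) -> tuple[dict[str, dict], pd.DataFrame]:
    """Strict-containment in/out labels plus a clade x in/out table.

    A gene is "in" iff its interval lies entirely inside a cluster
    interval; genes straddling a landmark boundary are "out" and flagged
    ``boundary``.
    """
    assignments = assignments or {}
    labels: dict[str, dict] = {}
    rows = []
    for locus in loci:
        if locus.name_class in (LANDMARK_PLC, LANDMARK_NEP):
            continue
        status, boundary = "out", False
        for cl in clusters:
            if cl.scaffold != locus.scaffold:
                continue
            if cl.start <= locus.start and locus.end <= cl.end:
                status = "in"
                cl.members.append(locus)
                break
            if locus.start < cl.end and cl.start < locus.end:
                boundary = True
        clade = assignments.get(locus.gene_id, "unassigned")
        labels[locus.gene_id] = {
            "in_cluster": status == "in",
            "boundary": boundary,
            "clade": clade,
        }
        rows.append((clade, status))
    table = (
        pd.DataFrame(rows, columns=["clade", "location"])
        .value_counts()
        .unstack(fill_value=0)
        if rows
        else pd.DataFrame()
    )
    for col in ("in", "out"):
        if len(table) and col not in table.columns:
            table[col] = 0
    return labels, table


def cluster_report(
    clusters: list[SyntenyCluster],
    loci: list[GeneLocus],
    assignments: dict[str, str] | None = None,
    margin: int = 50_000,
) -> list[dict]:
    """Ordered gene arrangement per cluster (landmarks included).

    Reports every locus within ``margin`` of the cluster interval sorted
    by start (so the V2R2/ancV2R tandem next to PLC eta1 shows up even
    though those genes are single copies, not part of the expansion),
    and notes V2R2/ancV2R tandem adjacency when observed.
    """
    assignments = assignments or {}
    out = []
    for cl in clusters:
        window = (cl.plc.start - margin, cl.neprilysin.end + margin)
        entries = []
        for locus in sorted(loci, key=lambda l: l.start):
            if locus.scaffold != cl.scaffold:
                continue
            if locus.end <= window[0] or locus.start >= window[1]:
                continue
            label = (
                locus.name_class
                if locus.name_class != "v2r"
                else assignments.get(locus.gene_id, "v2r")
            )
            entries.append(
                {"gene_id": locus.gene_id, "label": label,
                 "start": locus.start, "end": locus.end, "strand": locus.strand}
            )
        order = [e["label"] for e in entries]
        tandem = any(
            {a, b} == {"V2R2", "ancV2R"} for a, b in zip(order, order[1:])
        )
        out.append(
            {
                "scaffold": cl.scaffold,
                "interval": (cl.start, cl.end),
                "entries": entries,
                "v2r2_ancv2r_tandem": tandem,
            }
        )
    return out


def report_to_tsv(report: list[dict]) -> str:
    lines = ["scaffold\tcluster_start\tcluster_end\tposition\tgene_id\tlabel\tstrand"]
    for cl in report:
        for i, e in enumerate(cl["entries"]):
            lines.append(
                f"{cl['scaffold']}\t{cl['interval'][0]}\t{cl['interval'][1]}\t"
                f"{i}\t{e['gene_id']}\t{e['label']}\t{e['strand']}"
            )
    return "\n".join(lines) + "\n"
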