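"""Redundancy reduction before tree building.

Greedy length-sorted clustering at a global percent-identity threshold
(default 80%), the scheme used to thin very large per-species receptor
repertoires while keeping a representative of every cluster.  "Identity"
is matches over all alignment columns of a global alignment, gaps
counting as mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phylogeny import pairwise_align


@dataclass
class SequenceCluster:
    representative: str
    members: list[str] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)


def global_identity(a: str, b: str) -> float:
    """Matches / alignment columns under global affine alignment."""
    _, ra, rb = pairwise_align(a, b)
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return matches / len(ra)


def greedy_cluster(
    proteins: dict[str, str], threshold: float = 0.80
) -> list[SequenceCluster]:
    """Cluster sequences at >= ``threshold`` identity to a representative.

    Sequences are processed longest first (ties by id); each joins the
    first cluster whose representative it matches at or above the
    threshold, else founds a new cluster.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    for sid, seq in proteins.items():
        if not seq:
            raise ValueError(f"empty sequence {sid!r}")
    order = sorted(proteins, key=lambda s: (-len(proteins[s]), s))
    clusters: list[SequenceCluster] = []
    for sid in order:
        placed = False
        for cl in clusters:
            ident = global_identity(proteins[sid], proteins[cl.representative])
            if ident >= threshold:
                cl.members.append(sid)
                cl.identities[sid] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                SequenceCluster(representative=sid, members=[sid],
                                identities={sid: 1.0})
            )
    return clusters


def pick_representatives(
    clusters: list[SequenceCluster],
) -> tuple[list[str], dict[str, str]]:
    """Returns (representative ids, member -> representative map)."""
    reps = [cl.representative for cl in clusters]
    mapping = {m: cl.representative for cl in clusters for m in cl.members}
    return reps, mapping


def expand_counts(mapping: dict[str, str]) -> dict[str, int]:
    """Members represented by each representative (for count re-expansion)."""
    out: dict[str, int] = {}
    for rep in mapping.values():
        out[rep] = out.get(rep, 0) + 1
    return out


def clusters_to_tsv(clusters: list[SequenceCluster]) -> str:
    lines = ["member\trepresentative\tidentity"]
    for cl in clusters:
        for m in cl.members:
            lines.append(f"{m}\t{cl.representative}\t{cl.identities[m]:.4f}")
    return "\n".join(lines) + "\n"
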