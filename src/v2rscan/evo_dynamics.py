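"""Presence/absence and copy-number evolution on a species tree.

Clade presence/absence is reconstructed under Dollo parsimony (a single
gain at the most recent common ancestor of the presence leaves, minimal
losses below it) — appropriate for multigene clades, which are lost far
more easily than re-invented.  Total copy numbers are reconstructed by
linear-cost (Sankoff, |delta|) parsimony; branches whose reconstructed
count at least doubles and grows by a configurable absolute amount are
reported as sudden expansions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd


def _name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or f"node{id(node) % 10_000}"


def build_presence_matrix(copy_table: pd.DataFrame) -> pd.DataFrame:
    """P/A matrix from a counts table (P iff count > 0)."""
    return copy_table.map(lambda v: "P" if v > 0 else "A")


@dataclass
class CladeEvents:
    clade: str
    gain_node: str | None  # None when absent everywhere
    loss_branches: list[str] = field(default_factory=list)
    states: dict[str, str] = field(default_factory=dict)  # node name -> P/A

    @property
    def n_losses(self) -> int:
        return len(self.loss_branches)


@dataclass
class EventReconstruction:
    per_clade: dict[str, CladeEvents]

    def __getitem__(self, clade: str) -> CladeEvents:
        return self.per_clade[clade]


def dollo_reconstruct(
    matrix: pd.DataFrame, species_tree: dendropy.Tree
) -> EventReconstruction:
    """Single-gain Dollo reconstruction of each clade column.

    The gain sits at the MRCA of all presence leaves; losses are the
    maximal all-absent clades below the gain (one loss event per branch
    leading into such a clade).
    """
    leaves = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    missing = set(matrix.index) - leaves
    if missing:
        raise ValueError(f"matrix species not in tree: {sorted(missing)}")
    per_clade = {}
    for clade in matrix.columns:
        present = {sp for sp in matrix.index if matrix.loc[sp, clade] == "P"}
        if not present:
            per_clade[clade] = CladeEvents(clade, None)
            continue
        gain = species_tree.mrca(taxon_labels=present)

        def leafset(node):
            return {lf.taxon.label for lf in node.leaf_iter()}

        states: dict[str, str] = {}
        losses: list[str] = []

        def walk(node, gained: bool) -> None:
            if node is gain:
                gained = True
            if not gained:
                states[_name(node)] = "A"
                for ch in node.child_nodes():
                    walk(ch, False)
                return
            if leafset(node) & present:
                states[_name(node)] = "P"
                for ch in node.child_nodes():
                    walk(ch, True)
            else:
                # maximal all-absent clade: one loss on the branch into it
                losses.append(_name(node))
                states[_name(node)] = "A"
                for ch in node.child_nodes():
                    walk(ch, False)

        walk(species_tree.seed_node, False)
        per_clade[clade] = CladeEvents(clade, _name(gain), sorted(losses), states)
    return EventReconstruction(per_clade)


def dollo_event_count(events: CladeEvents) -> int:
    """Events under Dollo: one gain (if anywhere present) + losses."""
    return (0 if events.gain_node is None else 1) + events.n_losses


# ---------------------------------------------------------------------------
# linear-cost ancestral copy numbers


def _min_convolve_linear(cost: np.ndarray) -> np.ndarray:
    """g(s) = min_t cost(t) + |s - t| in O(M) (two running minima)."""
    M = len(cost)
    left = np.empty(M)
    acc = np.inf
    for s in range(M):
        acc = min(acc + 1, cost[s])  # min_{t<=s} cost(t) + (s - t)
        left[s] = acc
    right = np.empty(M)
    acc = np.inf
    for s in range(M - 1, -1, -1):
        acc = min(acc + 1, cost[s])
        right[s] = acc
    return np.minimum(left, right)


def ancestral_copy_numbers(
    totals: dict[str, int], species_tree: dendropy.Tree
) -> tuple[dict[str, int], dict[str, int]]:
    """Sankoff reconstruction of per-node totals under |delta| branch cost.

    Returns (node name -> count, child node name -> delta from parent).
    Interval-optimal solutions are resolved to the floor of the interval
    midpoint, applied top-down conditional on the parent's choice.
    """
    for sp, v in totals.items():
        if v < 0:
            raise ValueError(f"negative count for {sp}")
    leaves = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    missing = leaves - set(totals)
    if missing:
        raise ValueError(f"totals missing for species: {sorted(missing)}")
    M = max(totals.values()) + 1
    cost: dict[int, np.ndarray] = {}
    order = list(species_tree.postorder_node_iter())
    for node in order:
        if node.is_leaf():
            c = np.full(M, np.inf)
            c[totals[node.taxon.label]] = 0.0
        else:
            c = np.zeros(M)
            for ch in node.child_nodes():
                c = c + _min_convolve_linear(cost[id(ch)])
        cost[id(node)] = c

    states: dict[str, int] = {}
    chosen: dict[int, int] = {}
    deltas: dict[str, int] = {}

    def pick(arr: np.ndarray) -> int:
        opt = np.nonzero(arr <= arr.min() + 1e-9)[0]
        return int((opt[0] + opt[-1]) // 2)

    root = species_tree.seed_node
    chosen[id(root)] = pick(cost[id(root)])
    states[_name(root)] = chosen[id(root)]
    for node in species_tree.preorder_node_iter():
        sp_state = chosen[id(node)]
        for ch in node.child_nodes():
            arr = cost[id(ch)] + np.abs(np.arange(M) - sp_state)
            chosen[id(ch)] = pick(arr)
            states[_name(ch)] = chosen[id(ch)]
            deltas[_name(ch)] = chosen[id(ch)] - sp_state
    return states, deltas


def parsimony_cost(totals: dict[str, int], species_tree: dendropy.Tree) -> float:
    """Minimum total |delta| over all ancestral assignments."""
    M = max(totals.values()) + 1
    cost: dict[int, np.ndarray] = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            c = np.full(M, np.inf)
            c[totals[node.taxon.label]] = 0.0
        else:
            c = np.zeros(M)
            for ch in node.child_nodes():
                c = c + _min_convolve_linear(cost[id(ch)])
        cost[id(node)] = c
    return float(cost[id(species_tree.seed_node)].min())


@dataclass
class Expansion:
    branch: str  # child node name
    parent_count: int
    child_count: int

    @property
    def fold(self) -> float:
        return np.inf if self.parent_count == 0 else self.child_count / self.parent_count


def detect_expansions(
    states: dict[str, int],
    deltas: dict[str, int],
    species_tree: dendropy.Tree,
    fold_min: float = 2.0,
    abs_min: int = 40,
) -> list[Expansion]:
    """Branches whose reconstructed count grows >= fold_min x and by
    >= abs_min copies (a parent count of 0 with gains always qualifies)."""
    out = []
    for node in species_tree.preorder_node_iter():
        if node is species_tree.seed_node:
            continue
        child = _name(node)
        parent = _name(node.parent_node)
        pc, cc = states[parent], states[child]
        if cc - pc < abs_min and not (pc == 0 and cc > 0):
            continue
        if pc == 0:
            if cc > 0:
                out.append(Expansion(child, pc, cc))
            continue
        if cc / pc >= fold_min and cc - pc >= abs_min:
            out.append(Expansion(child, pc, cc))
    return out
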