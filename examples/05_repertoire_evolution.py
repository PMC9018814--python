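"""Reconstruct clade gains/losses and copy-number history on the
published vertebrate data.

Uses the packaged clade-level intact counts (19 species) and the
lineage-level presence/absence matrix.  Dollo parsimony allows one gain
and any number of losses per clade; copy numbers are reconstructed by
linear (|delta|-cost) parsimony with the jawed-vertebrate root anchored
by the agnathan zero count.
"""

from v2rscan import evo_dynamics as ed
from v2rscan import tables

pa = tables.load_printed_presence_absence()
rec = ed.dollo_reconstruct(pa, tables.load_lineage_tree())
print("Dollo reconstruction of the four major clades:")
for clade in pa.columns:
    ev = rec[clade]
    losses = ", ".join(ev.loss_branches) or "none"
    print(f"  {clade:7s} gained at {ev.gain_node:14s} losses: {losses}")
print("(t-V2R originates on the Osteichthyes stem and is lost in teleosts;"
      "\n V2R2 is present in every jawed-vertebrate ancestor with no losses)")

df = tables.load_printed_copy_numbers()
totals = {sp: int(df.loc[sp, "total"]) for sp in df.index
          if df.loc[sp, "fig2b"] == 1}
totals["lamprey"] = 0  # agnathans carry no V2Rs
tree = tables.load_vertebrate_tree_with_agnathan()
states, deltas = ed.ancestral_copy_numbers(totals, tree)

print("\nreconstructed ancestral repertoire sizes:")
for node in ("Gnathostomata", "Chondrichthyes", "Osteichthyes",
             "Sarcopterygii", "Tetrapoda"):
    print(f"  {node:15s} {states[node]}")

print("\nbranches with a sudden expansion (>=2x and >=40 extra copies):")
for e in ed.detect_expansions(states, deltas, tree):
    print(f"  {e.branch:22s} {e.parent_count} -> {e.child_count}")
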