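# v2rscan

Mining, classification and evolutionary reconstruction of **vomeronasal
type-2 receptor (V2R / OlfC)** gene repertoires.

V2Rs are class-C G-protein-coupled receptors that detect amino acids and
peptides in the olfactory/vomeronasal systems of vertebrates. The family
splits into four ancient clades — the conserved single-copy **V2R2**, the
single-copy orthologous **ancV2R**, the fish-type **f-V2R** expansion
(organised in a genomic cluster flanked by the landmark genes *PLC eta1*
and *neprilysin*, and subdivided into numbered subfamilies), and the
tetrapod-type **t-V2R** expansion (dispersed across chromosomes). Counting
intact copies of each clade across genomes, and mapping clade
presence/absence onto the species tree, reveals when the repertoire
expanded (the Osteichthyes stem, the frog lineage) and which lineages lost
which clades (t-V2Rs in teleosts, f-V2Rs in amniotes).

`v2rscan` implements that whole analysis as a tested Python library:

* **`simulate` / `fixtures`** — synthetic genomes with planted multi-exon
  receptor genes and full ground truth: per-clade birth–death gene
  histories on a species tree, Poisson protein evolution with uniform
  replacement, GT..AG introns, landmark-flanked cluster architecture, and
  pseudogenes (internal stop, 1–2 nt frameshift, truncation < 600 nt).
* **`mining`** — a translated seeded search (k-mer neighborhood seeds,
  two-hit diagonals, X-drop extension, Karlin–Altschul E-values
  `E = K·m·n·e^(−λS)`) followed by a spliced protein-to-genome dynamic
  program with explicit intron and frameshift states. A gene is *intact*
  iff it has no internal stop, no frameshift, and a coding length of at
  least 600 nt.
* **`curation`** — greedy 80%-identity clustering with representative
  re-expansion.
* **`phylogeny`** — progressive alignment (affine gaps), < 50%-coverage
  column filtering, Poisson-corrected distances `d = −ln(1 − p)`,
  neighbor joining with deterministic tie-breaking, 100-replicate
  bootstrap supports, outgroup rooting, Robinson–Foulds distances and
  newick I/O (externally computed trees can be imported).
* **`classification`** — the CaSR sister-clade rule for family
  delimitation, smallest-supported-anchor-pure-clade assignment to the
  four major clades and f-V2R subfamilies (novel marker-free subfamilies
  are named `a1`, `a2`, …), single-copy species-tree-concordant ortholog
  detection, the 2:1 whole-genome-duplication ratio test, and per-species
  copy-number tables.
* **`synteny`** — landmark-pair cluster delimitation, strict-containment
  membership, and ordered gene-arrangement reports.
* **`evo_dynamics`** — Dollo reconstruction of clade presence/absence
  (one gain, minimal losses) and linear-parsimony ancestral copy numbers
  with sudden-expansion detection.
* **`tables`** — the published clade-level intact counts for 19 vertebrate
  genomes and the lineage-level presence/absence matrix, as worked-example
  inputs.

Real multi-gigabyte assemblies are deliberately out of scope; every stage
is exercised offline on the synthetic fixtures, with the published tables
used as printed inputs.

## Worked example

Classify a simulated two-species repertoire (see
`examples/03_classify_repertoire.py`; all examples run in seconds):

```python
from v2rscan import phylogeny as ph
from v2rscan.classification import assign_major_clade, assign_subfamily, copy_number_table
from v2rscan.fixtures import default_fixture

fam = default_fixture(seed=20)
msa = ph.filter_columns(ph.progressive_align(fam.proteins), min_cov=0.5)
tree = ph.root_with_outgroup(ph.bootstrap(msa, n=100, seed=11), {"OUT|CaSR1"})
a = assign_subfamily(tree, fam.panel, assign_major_clade(tree, fam.panel))
statuses = {r.gene_id: r.status for r in fam.truth_records}
print(copy_number_table(a, statuses).to_string())
```

prints

```
         V2R2  ancV2R  tV2R  fV2R_1  fV2R_2  fV2R_3  fV2R_a1  fV2R_unplaced  total
species
spA         1       1     2       2       3       1        2              0     12
spB         1       1     1       2       3       2        2              0     12
```

— each row is one species' intact repertoire: one V2R2 and one ancV2R
(the ancient single-copy clades), a small t-V2R complement, and f-V2Rs
broken down by subfamily, with `fV2R_a1` a novel marker-free subfamily
the classifier discovered and named. Pseudogenes (6 of the 30 planted
genes) are excluded from the counts.

Running the evolutionary reconstruction on the published data
(`examples/05_repertoire_evolution.py`) prints the t-V2R gain on the
Osteichthyes stem with a single loss on the teleost branch, zero V2R2
losses, and the expansion branches
`Osteichthyes 27 → 69`, `reedfish 69 → 188`,
`western_clawed_frog 275 → 691`.

A thin CLI mirrors the stages:

```bash
v2rscan simulate --seed 20 --out fixture/
v2rscan mine --genome fixture/genome_spA.fa --queries fixture/queries.fa --out mined/
v2rscan all --seed 20 --out run/          # full pipeline
```

## Layout

```
src/v2rscan/        library (one module per pipeline stage; data/ holds
                    the published tables and reference trees)
examples/           one narrative script per capability
tests/              pytest suite incl. independent brute-force oracles
scripts/acceptance.py
docs/methods.md     models, parameters, design decisions, limitations
```
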