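# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `v2rscan`. Everything stated here is computed by the test
suite or `scripts/acceptance.py`; nothing is quoted from elsewhere.

## The analysis in one paragraph

Candidate V2R loci are found in genomic DNA by a translated seeded
search using the seven-transmembrane (TM) region of known receptors as
queries; spliced gene models are reconstructed over each locus and
called intact or pseudogene; redundancy is optionally reduced by
identity clustering; a bootstrapped gene tree of the predicted proteins
plus a reference panel assigns every gene to one of the four major
clades (V2R2, ancV2R, f-V2R, t-V2R) and, within f-V2Rs, to a numbered
subfamily; landmark-flanked synteny validates the f-V2R/t-V2R split
independently of the tree; and per-species copy numbers and clade
presence/absence are mapped onto the species tree to reconstruct gains,
losses and expansions.

## Synthetic-data generator

The generator defines the study conditions for every downstream test.

* **Gene histories.** Each clade evolves by a linear birth–death process
  along the species tree (exact event-time simulation; exponential
  waiting times at rate b+d per lineage, birth probability b/(b+d)).
  Clade origins and forced-loss branches are scenario parameters. A
  pure-birth branch of length t has expected leaf count e^(bt); the test
  suite checks this against 2,000 Monte-Carlo replicates within 3 SE.
* **Sequence evolution.** Per-site Poisson substitutions with uniform
  replacement over the 20 amino acids. The expected fraction of changed
  sites on a branch of length t is (19/20)(1 − e^(−rt)); this closed
  form is what makes the model testable, and is why an empirical
  rate-matrix model (e.g. JTT) is not used. Gamma rate heterogeneity is
  not modelled.
* **Gene planting.** Proteins are back-translated with a fixed
  (lexicographically smallest) codon per amino acid, split into exons at
  codon boundaries (phase-0 introns only, GT..AG, 200–1500 nt, exons
  ≥ 150 nt placed by a stars-and-bars draw that always succeeds), and
  embedded in i.i.d. uniform-ACGT background DNA on either strand.
  f-V2Rs go inside the cluster scaffold between the PLC-eta1 and
  neprilysin landmarks, with V2R2 and ancV2R in tandem next to PLC-eta1;
  t-V2Rs go on a separate scaffold. Intergenic gaps are 5–15 kb so that
  neighbouring paralogs are unambiguous at the locus level.
* **Pseudogenes.** A configured fraction of genes (default 20%,
  restricted in the standard fixture to the expanded f-/t-V2R clades,
  since the ancient single-copy clades are observed intact across
  vertebrates) receive one of three lesions, cycled deterministically:
  an internal stop codon (TAA at a random middle codon), a 1–2 nt
  frameshift indel, or truncation to a random coding length in
  [450, 599] nt — just under the 600-nt intactness rule.
* **Default fixture.** Two species at 0.12 substitutions/site from their
  ancestor; per species one V2R2, one ancV2R, three t-V2Rs and ten
  f-V2Rs (three marker-bearing subfamilies of 3/3/2 genes plus a
  two-gene marker-free subfamily that the classifier should discover as
  novel); 600 kb cluster + 400 kb dispersed scaffold per species
  (~1 Mb/species); 30 genes total, 6 pseudogenes. The family tree also
  carries the reference panel: a CaSR leaf (whose sister clade defines
  the family), distant Tas1r/GRM/GABA-B/GPCR6 outgroups, one anchor
  leaf per clade and one marker per numbered subfamily. Branch depths
  put within-clade identity near 75% and between-clade identity near
  50%, comfortably inside the ≥ 60%-identity regime the recovery
  properties assume. All randomness flows from one seed through named
  `SeedSequence` spawns; fixtures are byte-stable.

What the generator does **not** emulate: realistic codon usage or GC
skew, repeats, assembly gaps, segmental duplications, diploidy, intron
phase 1/2, and the very large VFTM ectodomain of real V2Rs (queries and
planted genes are TM-region-sized). Passing tests therefore demonstrate
algorithmic correctness under the stated model, not parity with
heuristic annotation of real multi-gigabyte assemblies — which is why
the published per-genome counts are treated as printed worked-example
inputs rather than recomputation targets.

## Mining

* **Queries.** TM-region queries run from 50 aa upstream of TM1 to 50 aa
  downstream of TM7, mapped through the seed alignment's annotated
  reference row and clamped at sequence bounds (`extract_tm_query`).
* **Seeded search.** Word size k = 3 with a neighborhood threshold
  T = 11 under BLOSUM62; two-hit trigger on a diagonal within 40 aa;
  X-drop 20 ungapped extension. E-values use E = K·m·n·e^(−λS) with λ
  solved exactly from Σ pᵢpⱼe^(λ sᵢⱼ) = 1 under the amino-acid
  background implied by uniform DNA read in frame (λ ≈ 0.307), and
  K frozen at 0.13; cutoff E ≤ 1e−5. On 50 replicate 100-kb random
  genomes the search returns zero hits, as the theory predicts.
  Gapped refinement is not a separate HSP stage: it is performed by the
  spliced gene-model DP over the merged locus window.
* **Loci and windows.** Same-strand HSPs within 3 kb merge into a locus
  (any planted intron is ≤ 1.5 kb); the model window is the locus ± 2 kb.
  A wider window would envelop neighbouring paralogs at the fixture's
  5–15 kb spacing and let the local aligner model the neighbour instead.
* **Spliced gene model.** A local protein-to-DNA dynamic program with
  states for codon match (3 nt), frameshift consumption (2 or 4 nt,
  penalty 15), affine codon gaps (open 11 / extend 1), and introns
  (GT..AG, ≥ 40 nt, penalty 20 + 0.01/nt — the length term stops the
  aligner from "splicing" across intergenic DNA into a neighbouring
  paralog to dodge a frameshift penalty). Two post-processing guards
  keep models honest: a model may not skip ≥ 30 consecutive query
  residues between anchors (longer skips mark chance re-anchoring; only
  the dominant segment is kept), and terminal path segments must
  maintain a mean per-codon score ≥ 1 (random codons average below
  zero, genuine homology well above; this prevents chance extensions
  past a truncation point from inflating the coding length).
  The DP is exact for phase-0 introns and is verified against an
  enumeration oracle on toy windows.
* **Status call.** `too_short` iff CDS < 600 nt (strictly); otherwise
  `pseudo_frameshift` if any frameshift state was used (an indel is the
  primary lesion — it routinely creates premature stops downstream, so
  it takes precedence over `pseudo_stop`); otherwise `pseudo_stop` on
  any internal stop; `partial` at scaffold edges; else `intact`.
  Models overlapping reciprocally ≥ 50% are deduplicated by score, then
  CDS length, then position.

On the default fixture, mining attains recall 1.0 and precision 1.0 for
intact genes and reproduces all six pseudogenization reasons; across
other seeds both stay ≥ 0.9.

## Curation

Greedy clustering processes sequences longest-first and joins a
sequence to the first cluster whose founder it matches at ≥ 80% global
identity (matches / alignment columns, gaps count against identity,
affine global alignment). "Similarity" is interpreted as percent
identity — the simplest reproducible reading — and the member →
representative map allows exact count re-expansion. Clustering is
applied per species, controlled by a config list (empty by default).

## Phylogeny

Alignment is progressive: a 3-mer-distance UPGMA guide tree, then
profile–profile Needleman–Wunsch with affine gaps (11/1) and
frequency-weighted BLOSUM62 column scores. Columns with strictly less
than 50% non-gap coverage are removed. Distances are Poisson-corrected
mismatch fractions over mutually non-gap columns, d = −ln(1 − p), with
p ≥ 0.95 flagged as saturated (∞). Neighbor joining uses the Q
criterion with ties broken toward the lexicographically smallest pair
of cluster keys; negative branch lengths are clamped to zero with the
deficit moved to the sister edge. Bootstrap supports (default 100
replicates) are the percentage of column-resampled trees containing
each bipartition of the point tree. Rooting places the root on the edge
separating a monophyletic outgroup.

Maximum-likelihood inference and substitution-model selection are
deliberately replaced by this corrected-distance pipeline: it is
deterministic, fast at desk scale, and every component has a brute-force
oracle (NJ recovers all additive matrices on ≤ 6 taxa exactly; the
aligner matches exhaustive DP; RF matches bipartition enumeration).
Externally computed ML trees can be imported via `read_tree` and used
by every downstream step.

A statistical caveat found while testing: bootstrap supports of an
alignment and its 10× duplication agree only for decisively supported
splits; borderline supports concentrate toward 0/100 as alignments
grow, so the duplication-invariance property is checked in the
strong-signal regime.

## Classification

The family is the sister clade of the smallest clade containing the
CaSR anchors; genes outside it (e.g. drawn toward Tas1r) are non-V2R.
Each family gene is assigned to the smallest clade with bootstrap
support ≥ 50 (nodes without a support value count as confident)
containing anchors of exactly one major clade; genes with no such node
fall back to the nearest anchor by patristic distance (flagged, ties to
the lexicographically smaller clade name). Subfamily assignment repeats
the rule with subfamily markers; supported marker-free clades of ≥ 2
unresolved f-V2R genes become novel subfamilies "a1", "a2", … in
decreasing size order (singletons stay "unplaced" to avoid naming noise
clades). The support floor is a parameter; 50 is the default because
published support reporting conventionally bins at 50/75.

Single-copy ortholog detection reports maximal supported clades with at
most one gene per species, at least three species, and an induced
topology identical (RF = 0) to the species tree. The 2:1 WGD test
counts, for each reference-species gene, the focal-species leaves in
the smallest containing clade that holds any focal gene; the reported
fraction is of reference genes with exactly two focal co-orthologs.
Species are parsed from gene ids as the prefix before the first `|`.

## Synteny

Clusters are delimited by pairing the nearest PLC-eta1/neprilysin
landmarks per scaffold; the cluster interval runs between the
landmarks' inner edges. Membership is strict containment; genes
straddling a landmark are "out" and flagged `boundary` (how truncated
assemblies treat such genes is genuinely ambiguous, so the flag
preserves the information). The arrangement report covers the cluster
plus a 50-kb margin so the single-copy V2R2/ancV2R tandem next to
PLC-eta1 appears even when it lies just outside the inner interval.

## Copy-number evolution

Presence/absence uses Dollo parsimony — one gain at the MRCA of the
presence leaves, losses on the branches into maximal all-absent clades —
because multigene-clade re-invention is biologically implausible while
losses are routine. On the published lineage matrix this places the
t-V2R gain on the Osteichthyes stem with a single teleost loss,
reconstructs V2R2 as present in every jawed-vertebrate ancestor with
zero losses, and reconstructs ancV2R as present in the Osteichthyes
ancestor with losses covering the teleost, coelacanth and amniote
lineages. Dollo optimality is verified against exhaustive single-gain
enumeration on 8-leaf trees.

Ancestral totals use Sankoff parsimony with |Δ| branch cost (O(M) lower
envelopes per node); interval-optimal solutions resolve to the floor of
the interval midpoint, applied top-down. The worked example anchors the
jawed-vertebrate root with an agnathan leaf at count 0 — agnathan
genomes carry no V2Rs — without which the root interval is wide and the
midpoint rule masks the basal expansion. Branches are reported as
sudden expansions when the count at least doubles **and** grows by ≥ 40
copies (both thresholds are config; the underlying claim in the
literature is qualitative). On the published totals this recovers the
Osteichthyes stem (27 → 69) and the western clawed frog terminal branch
(275 → 691), plus the reedfish terminal branch (69 → 188). The tetrapod
stem rises only 1.7× (89 → 154) under parsimony and does not meet the
two-fold rule — the "tetrapod expansion" reading rests on comparing
extant tetrapod repertoires to fish, not on a reconstructed ancestral
jump — and the thresholds were left at their stated defaults rather
than adjusted to force it.

## Pipeline and reproducibility

`run_pipeline` chains simulate → mine → cluster → tree → classify →
synteny → evolve, writing FASTA/GFF3/newick/TSV artefacts plus a
provenance record (config hash, seed, per-stage counts). One global
seed is fanned out by fixed offsets; reruns with the same config are
byte-identical (asserted in the tests). Config files are flat YAML
merged over defaults; unknown keys are errors.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open, forward strand, with a strand flag;
minus-strand features store forward coordinates. FASTA is written at 60
columns. Two-taxon "trees" are a single edge (reported as two half
edges); RF on fewer than four shared leaves warns and returns 0;
saturated distance pairs make NJ refuse rather than guess. Stops in
six-frame translations are `*`, N-containing codons are `X`. Seeds are
kept below 2³¹.

## Limitations

Beyond the generator's simplifications listed above: the search lacks
composition-based score adjustment and sum statistics; the gene-model
DP does not model splice-site strength beyond the GT..AG dinucleotides
and allows phase-0 introns only; NJ + bootstrap is not a substitute for
ML on deep or rate-heterogeneous divergences (import an external tree
for that); and subfamily naming depends on the marker panel — a clade
with no nearby marker can only be "novel" or "unplaced".
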