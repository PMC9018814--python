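"""Synthetic-data generator: birth-death histories, sequence evolution,
gene planting and fixture round-trips."""

import math
import os

import numpy as np
import pytest

from v2rscan import simulate as sim
from v2rscan._seq import revcomp, translate
from v2rscan.phylogeny import read_tree, robinson_foulds, write_tree

ST4 = "((spA:1,spB:1)AB:1,(spC:1,spD:1)CD:1)root;"


def _tree(nwk):
    t = read_tree(nwk)
    t.is_rooted = True
    return t


class TestSimulateFamily:
    def test_no_events_gives_one_gene_per_species_and_species_topology(self):
        st = _tree(ST4)
        scenario = sim.CladeScenario({c: sim.CladeParams() for c in sim.CLADES})
        gene_trees, counts = sim.simulate_family(st, scenario, seed=1)
        for sp in ("spA", "spB", "spC", "spD"):
            assert all(counts[sp][c] == 1 for c in sim.CLADES)
        gt = gene_trees["fV2R"]
        # relabel gene leaves by species and compare topologies
        for lf in gt.leaf_node_iter():
            lf.taxon.label = lf.taxon.label.split("|")[0]
        assert robinson_foulds(gt, st) == 0

    def test_forced_loss_empties_descendant_species(self):
        st = _tree(ST4)
        scenario = sim.CladeScenario(
            {"tV2R": sim.CladeParams(forced_loss=("CD",))}
        )
        _, counts = sim.simulate_family(st, scenario, seed=5)
        assert counts["spC"]["tV2R"] == 0 and counts["spD"]["tV2R"] == 0
        assert counts["spA"]["tV2R"] == 1 and counts["spB"]["tV2R"] == 1

    def test_unknown_origin_branch_raises(self):
        st = _tree(ST4)
        scenario = sim.CladeScenario(
            {"fV2R": sim.CladeParams(origin="nonexistent")}
        )
        with pytest.raises(sim.ConfigurationError):
            sim.simulate_family(st, scenario, seed=0)

    def test_birth_process_mean_matches_analytic_expectation(self):
        # pure birth at rate b on a branch of length t: E[leaves] = e^{bt}
        b, t, reps = 0.2, 5.0, 2000
        st = _tree(f"(x:{t});")
        total = 0
        sq = 0
        for s in range(reps):
            _, counts = sim.simulate_family(
                st, sim.CladeScenario({"fV2R": sim.CladeParams(birth=b)}), seed=s
            )
            n = counts["x"]["fV2R"]
            total += n
            sq += n * n
        mean = total / reps
        expected = math.exp(b * t)
        var = sq / reps - mean**2
        se = math.sqrt(var / reps)
        assert abs(mean - expected) < 3 * se

    def test_determinism(self):
        st = _tree(ST4)
        scenario = sim.CladeScenario(
            {c: sim.CladeParams(birth=0.3, death=0.1) for c in sim.CLADES}
        )
        a = sim.simulate_family(st, scenario, seed=9)
        b = sim.simulate_family(st, scenario, seed=9)
        assert a[1] == b[1]
        assert write_tree(a[0]["fV2R"]) == write_tree(b[0]["fV2R"])


class TestEvolveSequences:
    def test_zero_path_length_keeps_root(self):
        st = _tree("(a:0,b:0):0;")
        seqs = sim.evolve_sequences(st, "MKWV" * 20, 1.0, seed=0)
        assert set(seqs.values()) == {"MKWV" * 20}

    def test_expected_divergence_uniform_replacement(self):
        # P(site differs from root after branch t) = (19/20)(1 - e^{-rt})
        r, t, L = 0.5, 1.0, 10_000
        root = "".join(np.random.default_rng(0).choice(list(sim.AA20), L))
        st = _tree(f"(leaf:{t});")
        seqs = sim.evolve_sequences(st, root, r, seed=3)
        frac = sum(1 for x, y in zip(root, seqs["leaf"]) if x != y) / L
        p = (19 / 20) * (1 - math.exp(-r * t))
        se = math.sqrt(p * (1 - p) / L)
        assert abs(frac - p) < 3 * se

    def test_same_seed_identical(self):
        st = _tree("((a:1,b:1):0.5,c:1.5);")
        s1 = sim.evolve_sequences(st, "ACDEFGHIKL" * 10, 0.8, seed=4)
        s2 = sim.evolve_sequences(st, "ACDEFGHIKL" * 10, 0.8, seed=4)
        assert s1 == s2

    def test_bad_inputs(self):
        st = _tree("(a:1);")
        with pytest.raises(ValueError):
            sim.evolve_sequences(st, "", 0.1, seed=0)
        with pytest.raises(ValueError):
            sim.evolve_sequences(st, "MKB!", 0.1, seed=0)


def _specs(prot, n_f=3, n_t=1):
    specs = [
        sim.PlantSpec(f"sp|fV2R{i:03d}", "sp", "fV2R", "1", prot)
        for i in range(n_f)
    ]
    specs += [
        sim.PlantSpec(f"sp|tV2R{i:03d}", "sp", "tV2R", "", prot)
        for i in range(n_t)
    ]
    specs.append(sim.PlantSpec("sp|V2R2001", "sp", "V2R2", "", prot))
    specs.append(sim.PlantSpec("sp|ancV2R001", "sp", "ancV2R", "", prot))
    return specs


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(1)
    prot = "".join(rng.choice(list(sim.AA20), 300))
    gp = sim.GenomeParams(cluster_scaffold_length=150_000,
                          dispersed_scaffold_length=80_000)
    genome, truth = sim.plant_genes(_specs(prot), gp, 0.0, seed=2)
    return genome, truth


class TestPlantGenes:
    def test_intact_roundtrip(self, planted):
        genome, truth = planted
        for rec in truth:
            if rec.status != "intact":
                continue
            seq = genome.scaffolds[rec.scaffold]
            cds = "".join(seq[s:e] for s, e in rec.exons)
            if rec.strand == "-":
                cds = revcomp(cds)
            assert translate(cds) == rec.protein

    def test_fv2r_inside_landmark_interval(self, planted):
        genome, truth = planted
        plc = next(r for r in truth if r.clade == sim.LANDMARK_PLC)
        nep = next(r for r in truth if r.clade == sim.LANDMARK_NEP)
        for rec in truth:
            if rec.clade == "fV2R":
                assert rec.scaffold == plc.scaffold
                assert plc.end <= rec.start and rec.end <= nep.start
            if rec.clade == "tV2R":
                assert rec.scaffold != plc.scaffold

    def test_no_overlapping_features(self, planted):
        _, truth = planted
        by_scaf = {}
        for rec in truth:
            by_scaf.setdefault(rec.scaffold, []).append((rec.start, rec.end))
        for ivs in by_scaf.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_truncated_pseudogene_below_600nt(self):
        rng = np.random.default_rng(3)
        prot = "".join(rng.choice(list(sim.AA20), 300))
        gp = sim.GenomeParams(cluster_scaffold_length=400_000,
                              dispersed_scaffold_length=80_000)
        genome, truth = sim.plant_genes(_specs(prot, n_f=9), gp, 1.0, seed=4)
        reasons = {r.status for r in truth if r.status != "landmark"}
        assert reasons == {"stop", "frameshift", "truncated"}
        for rec in truth:
            if rec.status == "truncated":
                assert sum(e - s for s, e in rec.exons) <= 599

    def test_scaffold_too_small_errors(self):
        prot = "A" * 300
        gp = sim.GenomeParams(cluster_scaffold_length=5_000,
                              dispersed_scaffold_length=5_000)
        with pytest.raises(sim.ConfigurationError):
            sim.plant_genes(_specs(prot), gp, 0.0, seed=0)

    def test_bad_pseudo_rate(self):
        with pytest.raises(sim.ConfigurationError):
            sim.plant_genes(_specs("A" * 300), pseudo_rate=1.5)


class TestWriteFixture:
    def test_roundtrip_and_determinism(self, planted, tmp_path):
        genome, truth = planted
        st = _tree("(sp:1);")
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = sim.write_fixture([genome], truth, st, str(d1))
        p2 = sim.write_fixture([genome], truth, st, str(d2))
        # byte-identical artefacts
        for k in p1:
            assert open(p1[k]).read() == open(p2[k]).read()
        # GFF3 round-trip restores coordinates exactly
        back = sim.read_truth_gff3(p1["gff3"])
        orig = {r.gene_id: r for r in truth}
        assert len(back) == len(orig)
        for rec in back:
            o = orig[rec.gene_id]
            assert (rec.start, rec.end, rec.strand) == (o.start, o.end, o.strand)
            assert rec.exons == sorted(o.exons)
        # FASTA 60-column, re-read identical
        from Bio import SeqIO

        lines = open(p1["genome_sp"]).read().splitlines()
        assert all(len(l) <= 60 for l in lines if not l.startswith(">"))
        recs = {r.id: str(r.seq) for r in SeqIO.parse(p1["genome_sp"], "fasta")}
        assert recs == genome.scaffolds

    def test_empty_truth_gives_valid_gff3(self, tmp_path):
        st = _tree("(sp:1);")
        genome = sim.SyntheticGenome("sp", {"s": "ACGT" * 10})
        paths = sim.write_fixture([genome], [], st, str(tmp_path))
        text = open(paths["gff3"]).read()
        assert text.startswith("##gff-version 3")
        assert sim.read_truth_gff3(paths["gff3"]) == []


class TestWgdFamily:
    def test_duplicated_and_single_copy_patterns(self):
        t = sim.simulate_wgd_family(5, duplicated=True, seed=1)
        focal = [l for l in t.leaf_node_iter()
                 if l.taxon.label.startswith("teleost")]
        assert len(focal) == 10
        t2 = sim.simulate_wgd_family(5, duplicated=False, seed=1)
        focal2 = [l for l in t2.leaf_node_iter()
                  if l.taxon.label.startswith("teleost")]
        assert len(focal2) == 5
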