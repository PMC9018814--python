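"""Alignment, distances, NJ, bootstrap, rooting and tree comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    affine_align_score_enum,
    affine_align_score_memo,
    all_unrooted_topologies,
    random_additive_matrix,
    rf_oracle,
    tree_path_matrix,
)
from v2rscan import phylogeny as ph

AA = "ACDEFGHIKLMNPQRSTVWY"


def _t(nwk, rooted=False):
    t = ph.read_tree(nwk)
    t.is_rooted = rooted
    return t


class TestProgressiveAlign:
    def test_identical_pair_gap_free(self):
        msa = ph.progressive_align({"a": "MKWLV", "b": "MKWLV"})
        assert msa.rows() == {"a": "MKWLV", "b": "MKWLV"}

    def test_single_sequence_passthrough(self):
        msa = ph.progressive_align({"x": "MKV"})
        assert msa.rows() == {"x": "MKV"}

    def test_column_count_at_least_longest_input(self):
        seqs = {"a": "MKWLVAHT", "b": "MKWT", "c": "MKWLVAH"}
        msa = ph.progressive_align(seqs)
        assert msa.n_cols >= 8
        rows = msa.rows()
        for sid, s in seqs.items():
            assert rows[sid].replace("-", "") == s

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.text(AA, min_size=1, max_size=7),
        st.text(AA, min_size=1, max_size=7),
    )
    def test_pairwise_matches_enumeration_oracle(self, a, b):
        score, _, _ = ph.pairwise_align(a, b)
        assert score == pytest.approx(affine_align_score_enum(a, b))

    def test_pairwise_matches_independent_dp_at_12aa(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = "".join(rng.choice(list(AA), rng.integers(8, 13)))
            b = "".join(rng.choice(list(AA), rng.integers(8, 13)))
            score, _, _ = ph.pairwise_align(a, b)
            assert score == pytest.approx(affine_align_score_memo(a, b))


class TestFilterColumns:
    def _msa(self, cov_percent):
        # 100 rows; a column with cov_percent non-gap symbols
        rows = {}
        for i in range(100):
            rows[f"s{i:03d}"] = ("A" if i < cov_percent else "-") + "AW"
        return ph.msa_from_strings(rows)

    def test_strict_boundary_49_removed_50_retained(self):
        assert ph.filter_columns(self._msa(49), 0.5).n_cols == 2
        assert ph.filter_columns(self._msa(50), 0.5).n_cols == 3

    def test_all_gap_column_removed(self):
        msa = ph.msa_from_strings({"a": "M-K", "b": "M-K"})
        assert ph.filter_columns(msa).rows() == {"a": "MK", "b": "MK"}

    def test_all_columns_removed_errors(self):
        msa = ph.msa_from_strings({"a": "MK--", "b": "--MK", "c": "-..."[:0] + "----"})
        with pytest.raises(ValueError):
            ph.filter_columns(msa, 0.8)

    def test_idempotent_and_never_grows(self):
        msa = ph.progressive_align(
            {"a": "MKWLVAHT", "b": "MKWT", "c": "MKWLVAH", "d": "WT"}
        )
        once = ph.filter_columns(msa, 0.5)
        twice = ph.filter_columns(once, 0.5)
        assert once.n_cols <= msa.n_cols
        assert twice.rows() == once.rows()


class TestDistances:
    def test_identical_rows_zero(self):
        msa = ph.msa_from_strings({"a": "MKWLV", "b": "MKWLV"})
        assert ph.distances(msa).matrix[0, 1] == 0.0

    def test_poisson_correction_at_p_01(self):
        # 10% mismatches -> d = -ln(0.9)
        row_a = "A" * 100
        row_b = "C" * 10 + "A" * 90
        d = ph.distances(ph.msa_from_strings({"a": row_a, "b": row_b}))
        assert d.matrix[0, 1] == pytest.approx(-math.log(0.9), abs=1e-12)

    def test_monotone_in_p(self):
        prev = -1.0
        for k in range(0, 95, 10):
            row_b = "C" * k + "A" * (100 - k)
            d = ph.distances(ph.msa_from_strings({"a": "A" * 100, "b": row_b}))
            assert d.matrix[0, 1] > prev
            prev = d.matrix[0, 1]

    def test_saturated_pair_is_infinite(self):
        d = ph.distances(ph.msa_from_strings({"a": "A" * 100, "b": "C" * 100}))
        assert np.isinf(d.matrix[0, 1])

    def test_zero_shared_columns_warns_and_saturates(self):
        msa = ph.msa_from_strings({"a": "MK--", "b": "--MK"})
        with pytest.warns(UserWarning):
            d = ph.distances(msa)
        assert np.isinf(d.matrix[0, 1])


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        t = ph.neighbor_joining(
            ph.DistanceMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        )
        ls = {l.taxon.label: l.edge.length for l in t.leaf_node_iter()}
        assert sum(ls.values()) == pytest.approx(3.0)

    def test_three_taxa_closed_form(self):
        # d_AB=5, d_AC=9, d_BC=10 -> la=2, lb=3, lc=7
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        t = ph.neighbor_joining(ph.DistanceMatrix(["A", "B", "C"], D))
        ls = {l.taxon.label: l.edge.length for l in t.leaf_node_iter()}
        assert ls == pytest.approx({"A": 2.0, "B": 3.0, "C": 7.0})

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,C:3,D:1)
        D = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        t = ph.neighbor_joining(ph.DistanceMatrix(list("ABCD"), D))
        P = tree_path_matrix(t, list("ABCD"))
        assert np.allclose(P, D)

    @pytest.mark.parametrize("n", [5, 6])
    def test_additive_recovery_all_topologies(self, n):
        labels = [f"T{i}" for i in range(n)]
        rng = np.random.default_rng(42)
        for topo in all_unrooted_topologies(labels):
            D, _ = random_additive_matrix(topo, labels, rng)
            t = ph.neighbor_joining(ph.DistanceMatrix(labels, D))
            assert np.allclose(tree_path_matrix(t, labels), D, atol=1e-9)

    def test_saturated_matrix_rejected(self):
        D = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            ph.neighbor_joining(ph.DistanceMatrix(list("ABC"), D))


class TestBootstrap:
    def _signal_msa(self):
        # (a,b) vs (c,d) separated by a moderate mutated block; kept well
        # below the Poisson saturation point so no replicate degenerates
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list(AA), 44))
        other = list(base)
        for i in rng.choice(44, 15, replace=False):
            other[i] = AA[(AA.index(other[i]) + 1) % 20]
        other = "".join(other)

        def tweak(s, pos):
            out = list(s)
            out[pos] = AA[(AA.index(out[pos]) + 3) % 20]
            return "".join(out)

        rows = {"a": base, "b": tweak(base, 0),
                "c": other, "d": tweak(other, 1)}
        return ph.msa_from_strings(rows)

    def test_perfect_signal_gets_support_100(self):
        t = ph.bootstrap(self._signal_msa(), n=50, seed=3)
        sups = [n.support for n in t.preorder_node_iter()
                if getattr(n, "support", None) is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_same_seed_reproducible(self):
        t1 = ph.bootstrap(self._signal_msa(), n=20, seed=9)
        t2 = ph.bootstrap(self._signal_msa(), n=20, seed=9)
        assert ph.write_tree(t1) == ph.write_tree(t2)

    def test_supports_bounded(self, fam, noisy_tree):
        for n in noisy_tree.preorder_node_iter():
            s = getattr(n, "support", None)
            if s is not None:
                assert 0.0 <= s <= 100.0

    def test_duplicated_alignment_supports_close(self):
        # every internal edge carries its own 8-column signature, so all
        # supports sit in the decisive regime where duplication leaves the
        # expected support unchanged (borderline splits concentrate toward
        # 0/100 as alignments grow and are excluded by construction)
        rng = np.random.default_rng(1)
        base = list("".join(rng.choice(list(AA), 48)))

        def mutate(s, lo, hi):
            out = list(s)
            for p in range(lo, hi):
                out[p] = AA[(AA.index(out[p]) + 7) % 20]
            return out

        anc_ab = mutate(base, 0, 8)      # ((a,b) vs rest)
        anc_a = mutate(anc_ab, 8, 16)
        anc_b = mutate(anc_ab, 16, 24)
        anc_c = mutate(base, 24, 32)
        rows = {}
        for name, anc in (("a", anc_a), ("b", anc_b), ("c", anc_c)):
            for k in (1, 2):
                s = list(anc)
                s[40 + 2 * k] = AA[(AA.index(s[40 + 2 * k]) + k) % 20]
                rows[f"{name}{k}"] = "".join(s)
        msa = ph.msa_from_strings(rows)
        dup = ph.MSA(list(msa.ids), np.tile(msa.matrix, (1, 10)))

        def mean_supports(m, seeds):
            acc: dict[frozenset, list[float]] = {}
            for sd in seeds:
                t = ph.bootstrap(m, n=200, seed=sd)
                for nd in t.preorder_node_iter():
                    s = getattr(nd, "support", None)
                    if s is not None:
                        key = frozenset(l.taxon.label for l in nd.leaf_iter())
                        acc.setdefault(key, []).append(s)
            return {k: sum(v) / len(v) for k, v in acc.items()}

        s1 = mean_supports(msa, (5, 15, 25))
        s2 = mean_supports(dup, (6, 16, 26))
        shared = set(s1) & set(s2)
        assert shared
        for k in shared:
            assert abs(s1[k] - s2[k]) <= 10.0


class TestRooting:
    def test_single_leaf_outgroup(self):
        t = _t("((A:1,B:1):1,(C:1,O:4):1);")
        r = ph.root_with_outgroup(t, {"O"})
        kids = r.seed_node.child_nodes()
        sides = [frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids]
        assert frozenset({"O"}) in sides

    def test_all_leaves_outgroup_errors(self):
        t = _t("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError):
            ph.root_with_outgroup(t, {"A", "B", "C"})

    def test_non_monophyletic_outgroup_names_offenders(self):
        t = _t("((A:1,C:1):1,(B:1,D:1):1);")
        with pytest.raises(ValueError, match="not monophyletic"):
            ph.root_with_outgroup(t, {"A", "B"})

    def test_rooting_preserves_bipartitions(self):
        t = _t("((A:1,B:1):1,(C:1,(D:1,O:1):1):1);")
        before = ph.bipartitions(t)
        r = ph.root_with_outgroup(t, {"O"})
        assert ph.bipartitions(r) == before


class TestRobinsonFoulds:
    def test_identical_zero(self):
        t1 = _t("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = _t("((B:2,A:1):1,(D:1,C:5):1);")
        assert ph.robinson_foulds(t1, t2) == 0

    def test_alternative_four_taxon_resolutions_distance_two(self):
        t1 = _t("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = _t("((A:1,C:1):1,(B:1,D:1):1);")
        assert ph.robinson_foulds(t1, t2) == 2

    def test_matches_oracle_on_random_topologies(self):
        labels = [f"L{i}" for i in range(8)]
        rng = np.random.default_rng(7)

        def random_tree():
            topos = None
            # grow by random attachment
            import dendropy

            t = dendropy.Tree(taxon_namespace=dendropy.TaxonNamespace())
            nodes = []
            for lab in labels:
                leaf = dendropy.Node()
                leaf.taxon = t.taxon_namespace.new_taxon(lab)
                leaf.edge.length = 1.0
                nodes.append(leaf)
            while len(nodes) > 3:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                b = nodes.pop(j)
                a = nodes.pop(i)
                p = dendropy.Node()
                p.edge.length = 1.0
                p.add_child(a)
                p.add_child(b)
                nodes.append(p)
            for nd in nodes:
                t.seed_node.add_child(nd)
            t.is_rooted = False
            return t

        for _ in range(10):
            t1, t2 = random_tree(), random_tree()
            assert ph.robinson_foulds(t1, t2) == rf_oracle(t1, t2)

    def test_symmetry(self):
        t1 = _t("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        t2 = _t("((A:1,D:1):1,(C:1,(B:1,E:1):1):1);")
        assert ph.robinson_foulds(t1, t2) == ph.robinson_foulds(t2, t1)

    def test_fewer_than_four_shared_leaves_warns_zero(self):
        t1 = _t("((A:1,B:1):1,C:1);")
        t2 = _t("((A:1,B:1):1,D:1);")
        with pytest.warns(UserWarning):
            assert ph.robinson_foulds(t1, t2) == 0


class TestNewickIO:
    def test_roundtrip_byte_identical_after_canonical_ordering(self):
        s = "(A:1.0,(B:1.0,C:1.0)90:2.0);\n"
        t = ph.read_tree(s)
        out = ph.write_tree(t)
        assert ph.write_tree(ph.read_tree(out)) == out
        assert out == s

    def test_quoted_labels_with_spaces(self):
        t = ph.read_tree("('left one':1,'right two':2);")
        assert ph.leaf_labels(t) == {"left one", "right two"}

    def test_supports_parsed_to_nodes(self):
        t = ph.read_tree("((A:1,B:1)75:1,(C:1,D:1)100:1);")
        sups = sorted(
            n.support for n in t.preorder_node_iter()
            if getattr(n, "support", None) is not None
        )
        assert sups == [75.0, 100.0]

    def test_empty_string_errors(self):
        with pytest.raises(ValueError):
            ph.read_tree("   ")

    def test_unbalanced_parentheses_error(self):
        with pytest.raises(ValueError):
            ph.read_tree("((A:1,B:1;")
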