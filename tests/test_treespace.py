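"""Phyletic distances, NJ reconstruction, branch ratios, paired test, discordance."""

import itertools

import numpy as np
import pytest
from oracles import random_tree

from picoevo import treespace
from picoevo.model import EvoTree, PhyleticPattern, StrainMetadata
from picoevo.treespace import (
    BranchRatioRecord,
    branch_ratio_analysis,
    clade_base_nodes,
    nj_tree,
    paired_ratio_test,
    phyletic_distances,
    robinson_foulds,
    tree_discordance,
)


def _pattern(rows, strains=None, clogs=None):
    rows = np.asarray(rows)
    strains = strains or [f"s{i}" for i in range(rows.shape[0])]
    clogs = clogs or [f"c{j}" for j in range(rows.shape[1])]
    return PhyleticPattern(strains, clogs, rows)


class TestPhyleticDistances:
    def test_identical_and_disjoint(self):
        pat = _pattern([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        d = phyletic_distances(pat)
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_matches_set_arithmetic(self):
        rng = np.random.default_rng(8)
        pat = _pattern(rng.integers(0, 2, (8, 40)) | (rng.random((8, 40)) < 0.1))
        d = phyletic_distances(pat)
        for i, j in itertools.combinations(range(8), 2):
            fi = pat.families_of(pat.strains[i])
            fj = pat.families_of(pat.strains[j])
            want = 1.0 - len(fi & fj) / len(fi | fj)
            assert d[i, j] == pytest.approx(want)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(9)
        pat = _pattern((rng.random((7, 60)) < 0.5).astype(int) + 0)
        d = phyletic_distances(pat)
        n = d.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_zero_family_strain_rejected(self):
        pat = _pattern([[1, 1], [0, 0]])
        with pytest.raises(ValueError, match="zero families"):
            phyletic_distances(pat)

    def test_non_core_scope_drops_universal_families(self):
        pat = _pattern([[1, 1, 0], [1, 0, 1], [1, 1, 1]])
        d_all = phyletic_distances(pat, scope="all_families")
        d_nc = phyletic_distances(pat, scope="non_core")
        assert d_nc[0, 1] >= d_all[0, 1]  # dropping shared families expands distances


def _additive_distances(tree):
    leaves = tree.leaf_ids
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.patristic_distance(leaves[i], leaves[j])
    return d, leaves


class TestNJ:
    def test_four_taxon_split_recovery(self):
        src = EvoTree.from_newick("((A:1,B:1.5):1,(C:0.8,D:1.2):1);", "unitless")
        d, taxa = _additive_distances(src)
        tree, _ = nj_tree(d, taxa, bootstrap=0)
        assert robinson_foulds(tree, src) == 0

    def test_additive_matrix_rf_zero_and_path_lengths(self):
        rng = np.random.default_rng(10)
        for trial in range(5):
            src = random_tree(10, rng, unit="unitless")
            d, taxa = _additive_distances(src)
            tree, _ = nj_tree(d, taxa, bootstrap=0)
            assert robinson_foulds(tree, src) == 0
            for i, a in enumerate(taxa):
                for j in range(i + 1, len(taxa)):
                    assert tree.patristic_distance(a, taxa[j]) == pytest.approx(
                        d[i, j], abs=1e-9
                    )

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(11)
        src = random_tree(8, rng, unit="unitless")
        d, taxa = _additive_distances(src)
        base, _ = nj_tree(d, taxa, bootstrap=0)
        perm = list(rng.permutation(len(taxa)))
        d2 = d[np.ix_(perm, perm)]
        taxa2 = [taxa[i] for i in perm]
        tree2, _ = nj_tree(d2, taxa2, bootstrap=0)
        assert robinson_foulds(base, tree2) == 0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d, ["a", "b"], bootstrap=0)

    def test_bootstrap_supports_high_on_clean_signal(self):
        # two blocks of strains with disjoint family sets
        rng = np.random.default_rng(12)
        block = np.zeros((6, 80), dtype=int)
        block[:3, :40] = 1
        block[3:, 40:] = 1
        noise = (rng.random((6, 80)) < 0.05).astype(int)
        pat = _pattern(block ^ noise)
        d = phyletic_distances(pat)
        tree, supports = nj_tree(d, list(pat.strains), pattern=pat, bootstrap=50, seed=0)
        split = min(
            frozenset(pat.strains[:3]), frozenset(pat.strains[3:]),
            key=lambda s: (len(s), sorted(s)),
        )
        assert supports[split] >= 90.0


class TestRobinsonFoulds:
    def test_identical_zero(self, four_leaf_tree):
        assert robinson_foulds(four_leaf_tree, four_leaf_tree) == 0

    def test_matches_bipartition_symmetric_difference(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            a = random_tree(12, rng)
            b = random_tree(12, rng)
            # brute-force bipartition sets
            def biparts(tree):
                leaves = frozenset(tree.leaf_ids)
                out = set()
                for node in tree.preorder():
                    if node.parent is None or node.is_leaf:
                        continue
                    below = tree.leafset_below(node)
                    if 1 < len(below) < len(leaves) - 1:
                        out.add(min(below, leaves - below, key=lambda s: (len(s), sorted(s))))
                return out

            assert robinson_foulds(a, b) == len(biparts(a) ^ biparts(b))

    def test_leaf_mismatch_rejected(self, four_leaf_tree):
        other = EvoTree.from_newick("((A:1,B:1):1,(C:1,E:1):1);", "subs/site")
        with pytest.raises(ValueError, match="only in B"):
            robinson_foulds(four_leaf_tree, other)


class TestBranchRatios:
    def test_ultrametric_clade_arithmetic(self):
        tree = EvoTree.from_newick("((A:2,B:2)X:4,(C:1,D:1)Y:5)R;", "unitless")
        recs = branch_ratio_analysis(tree, ["X"], "core")
        assert recs[0].external == pytest.approx(2.0)
        assert recs[0].internal == pytest.approx(4.0)
        assert recs[0].ratio == pytest.approx(0.5)

    def test_star_clade_external_is_leaf_edge_mean(self):
        tree = EvoTree.from_newick("((A:3,B:5)X:2,C:9)R;", "unitless")
        recs = branch_ratio_analysis(tree, ["X"], "core")
        assert recs[0].external == pytest.approx(4.0)

    def test_root_rejected(self, four_leaf_tree):
        with pytest.raises(ValueError, match="root"):
            branch_ratio_analysis(four_leaf_tree, [four_leaf_tree.root.id], "core")

    def test_mean_path_matches_per_leaf_traversal(self):
        rng = np.random.default_rng(14)
        tree = random_tree(10, rng)
        depth = tree.depths()
        nodes = [n.id for n in tree.internal_nodes if n.parent is not None]
        recs = branch_ratio_analysis(tree, nodes, "core")
        for rec in recs:
            leaves = tree.leafset_below(tree.node(rec.node_id))
            want = np.mean([depth[l] - depth[rec.node_id] for l in leaves])
            assert rec.external == pytest.approx(want)


class TestPairedTest:
    def _recs(self, ratios, tag):
        return [
            BranchRatioRecord(f"n{i}", r, 1.0, r, tag) for i, r in enumerate(ratios)
        ]

    def test_identical_ratios_p_one(self):
        core = self._recs([1.0, 2.0, 3.0], "core")
        phyl = self._recs([1.0, 2.0, 3.0], "phyletic")
        res = paired_ratio_test(core, phyl)
        assert res.p_value == 1.0
        assert res.direction == 0

    def test_constant_shift_exact_p(self):
        core = self._recs(list(np.arange(10) + 1.0), "core")
        phyl = self._recs(list(np.arange(10) + 2.0), "phyletic")
        res = paired_ratio_test(core, phyl)
        assert res.p_value == pytest.approx(2 / 2**10)
        assert res.direction > 0

    def test_exact_matches_enumeration(self):
        """For n <= 8 the exact signed-rank p equals full enumeration."""
        rng = np.random.default_rng(15)
        for _ in range(5):
            diffs = rng.normal(0.3, 1.0, size=7)
            diffs = diffs[diffs != 0]
            core = self._recs(np.zeros(len(diffs)), "core")
            phyl = self._recs(diffs, "phyletic")
            res = paired_ratio_test(core, phyl)
            # enumeration over all sign assignments
            ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
            w_obs = ranks[diffs > 0].sum()
            n = len(diffs)
            ws = []
            for signs in itertools.product([0, 1], repeat=n):
                ws.append(sum(r for r, s in zip(ranks, signs) if s))
            ws = np.array(ws)
            p_le = np.mean(ws <= w_obs + 1e-12)
            p_ge = np.mean(ws >= w_obs - 1e-12)
            p_enum = min(1.0, 2.0 * min(p_le, p_ge))
            assert res.p_value == pytest.approx(p_enum, abs=1e-12)

    def test_unpaired_node_rejected(self):
        core = self._recs([1.0, 2.0], "core")
        phyl = self._recs([1.0, 2.0, 3.0], "phyletic")
        with pytest.raises(ValueError, match="n2"):
            paired_ratio_test(core, phyl)


class TestDiscordance:
    def test_identical_topologies(self, clade_metadata):
        a = EvoTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);", "subs/site")
        b = EvoTree.from_newick("((A:2,B:2):2,(C:2,D:2):2);", "unitless")
        rep = tree_discordance(a, b, clade_metadata)
        assert rep.rf_distance == 0
        assert rep.broken_in_b == []

    def test_leaf_swap_breaks_clades(self, clade_metadata):
        a = EvoTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);", "subs/site")
        b = EvoTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);", "unitless")
        rep = tree_discordance(a, b, clade_metadata)
        assert set(rep.broken_in_b) == {"I", "II"}

    def test_clade_base_detection(self, clade_metadata):
        tree = EvoTree.from_newick("((A:1,B:1)X:1,(C:1,D:1)Y:1)R;", "subs/site")
        nodes = clade_base_nodes(tree, clade_metadata)
        assert set(nodes) == {"X", "Y"}
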