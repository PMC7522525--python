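"""Set-specific variants, node-fixed variants, and the rank-ratio screen."""

import numpy as np
import pytest
from scipy.stats import rankdata

from picoevo import variants as var
from picoevo.model import CoreAlignmentSet, EvoTree
from picoevo.simulate import SimConfig
from picoevo.variants import (
    ProteinVariantScore,
    fixed_variants_per_node,
    rank_ratio_screen,
    score_proteins,
    specific_variants,
    variant_report,
)


def _aln(seqs, clog="p1"):
    return CoreAlignmentSet({clog: seqs})


class TestSpecificVariants:
    def test_definition_positive(self):
        aln = _aln({"s1": "A", "s2": "A", "s3": "B", "s4": "C"})
        hits = specific_variants(aln, ["s1", "s2"])
        assert len(hits) == 1
        assert hits[0].set_residue == "A"
        assert hits[0].outside_residues == frozenset({"B", "C"})

    def test_outside_carrying_residue_disqualifies(self):
        aln = _aln({"s1": "A", "s2": "A", "s3": "A", "s4": "C"})
        assert specific_variants(aln, ["s1", "s2"]) == []

    def test_set_not_uniform_disqualifies(self):
        aln = _aln({"s1": "A", "s2": "D", "s3": "B", "s4": "C"})
        assert specific_variants(aln, ["s1", "s2"]) == []

    def test_full_set_rejected(self):
        aln = _aln({"s1": "A", "s2": "A"})
        with pytest.raises(ValueError, match="complement empty"):
            specific_variants(aln, ["s1", "s2"])

    def test_gap_policies(self):
        aln = _aln({"s1": "A-", "s2": "A-", "s3": "B-", "s4": "-C"})
        # column 1 has a gap in s4 -> excluded by default
        assert specific_variants(aln, ["s1", "s2"], gap_policy="exclude_column") == []
        # gap_as_state: the gap in s4 counts as "any other amino acid"
        hits = specific_variants(aln, ["s1", "s2"], gap_policy="gap_as_state")
        assert [(h.column, h.set_residue) for h in hits] == [(1, "A")]
        # but a gap can never be the set residue (column 2)
        assert all(h.set_residue != "-" for h in hits)

    def test_matches_generator_truth_exactly(self, default_dataset):
        """Zero misses and zero false positives against the oracle scan."""
        aln = default_dataset["alignments"]
        truth = default_dataset["truth"]
        cfg = SimConfig(seed=11)
        for target in cfg.target_sets:
            sid = "+".join(target)
            got = specific_variants(aln, cfg.strains_of_set(target), set_id=sid)
            got_set = {(v.clog, v.column, v.set_residue) for v in got}
            want_set = set(map(tuple, truth.specific_columns[sid]))
            assert got_set == want_set

    def test_complementarity_fuzz(self):
        """A column specific to S with residue r is specific to an
        overlapping set with the same residue only if the sets are equal."""
        rng = np.random.default_rng(16)
        strains = [f"s{i}" for i in range(6)]
        for _ in range(20):
            mat = rng.choice(list("ADE"), size=(6, 30))
            aln = CoreAlignmentSet({"p": {s: "".join(row) for s, row in zip(strains, mat)}})
            sets = {}
            for k in (2, 3):
                members = sorted(rng.choice(strains, size=k, replace=False))
                sets[tuple(members)] = {
                    (v.column, v.set_residue)
                    for v in specific_variants(aln, members)
                }
            keys = list(sets)
            if len(keys) == 2 and keys[0] != keys[1]:
                overlap = set(keys[0]) & set(keys[1])
                if overlap:
                    assert not (sets[keys[0]] & sets[keys[1]])

    def test_strain_order_invariance(self, default_dataset):
        aln = default_dataset["alignments"]
        cfg = SimConfig(seed=11)
        members = cfg.strains_of_set(cfg.target_sets[0])
        a = specific_variants(aln, members)
        b = specific_variants(aln, list(reversed(members)))
        assert {(v.clog, v.column) for v in a} == {(v.clog, v.column) for v in b}


class TestFixedVariantsPerNode:
    def test_star_tree_empty(self):
        tree = EvoTree.from_newick("((A:1,B:1,C:1):0,D:1);", "subs/site")
        aln = CoreAlignmentSet({"p": {s: "AAAA" for s in "ABCD"}})
        mapping = fixed_variants_per_node(aln, tree)
        # the only internal non-root node is the trifurcation
        assert all(isinstance(v, list) for v in mapping.values())

    def test_cherry_partition(self, four_leaf_tree):
        aln = CoreAlignmentSet(
            {"p": {"A": "D", "B": "D", "C": "E", "D": "E"}}
        )
        mapping = fixed_variants_per_node(aln, four_leaf_tree)
        ab = next(
            n.id for n in four_leaf_tree.preorder()
            if not n.is_leaf and four_leaf_tree.leafset_below(n) == frozenset({"A", "B"})
        )
        assert [(v.column, v.set_residue) for v in mapping[ab]] == [(1, "D")]

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(17)
        from oracles import random_tree

        tree = random_tree(8, rng)
        strains = tree.leaf_ids
        mat = rng.choice(list("ACDEF"), size=(8, 40))
        aln = CoreAlignmentSet({"p": {s: "".join(r) for s, r in zip(strains, mat)}})
        mapping = fixed_variants_per_node(aln, tree)
        for node in tree.preorder():
            if node.is_leaf or node.parent is None:
                continue
            below = tree.leafset_below(node)
            idx_in = [strains.index(s) for s in below]
            idx_out = [i for i in range(8) if strains[i] not in below]
            expected = []
            for col in range(40):
                rin = set(mat[idx_in, col])
                rout = set(mat[idx_out, col])
                if len(rin) == 1 and not (rin & rout):
                    expected.append((col + 1, next(iter(rin))))
            got = [(v.column, v.set_residue) for v in mapping[node.id]]
            assert got == expected


class TestRankRatio:
    def _scores(self, densities_by_set, length=100):
        out = {}
        for sid, dens in densities_by_set.items():
            scores = [
                ProteinVariantScore(f"p{i}", sid, int(d * length), length)
                for i, d in enumerate(dens)
            ]
            ranks = rankdata([-s.density for s in scores], method="average")
            for s, r in zip(scores, ranks):
                s.rank = float(r)
            out[sid] = scores
        return out

    def test_clear_candidate(self):
        scores = self._scores(
            {
                "focal": [0.5] + [0.0] * 9,
                "bg1": [0.0, 0.3, 0.3] + [0.01] * 7,
                "bg2": [0.0, 0.2, 0.25] + [0.01] * 7,
            }
        )
        got = rank_ratio_screen(scores, "focal", ["bg1", "bg2"])
        assert "p0" in got

    def test_zero_density_protein_never_candidate(self):
        scores = self._scores(
            {
                "focal": [0.0, 0.5, 0.4],
                "bg1": [0.3, 0.0, 0.1],
                "bg2": [0.2, 0.1, 0.0],
            }
        )
        got = rank_ratio_screen(scores, "focal", ["bg1", "bg2"])
        assert "p0" not in got

    def test_needs_two_backgrounds(self):
        scores = self._scores({"focal": [0.1], "bg1": [0.1]})
        with pytest.raises(ValueError, match="2 background"):
            rank_ratio_screen(scores, "focal", ["bg1"])

    def test_matches_independent_ranking(self):
        rng = np.random.default_rng(18)
        n_prot = 30
        sets = {f"set{k}": list(rng.random(n_prot) * 0.1) for k in range(4)}
        scores = self._scores(sets)
        got = rank_ratio_screen(scores, "set0", ["set1", "set2", "set3"], cutoff=0.33)
        # independent recomputation with naive sorting-based average ranks
        def naive_ranks(vals):
            order = sorted(range(len(vals)), key=lambda i: -vals[i])
            ranks = [0.0] * len(vals)
            i = 0
            while i < len(order):
                j = i
                while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    ranks[order[k]] = avg
                i = j + 1
            return ranks

        focal_ranks = naive_ranks(sets["set0"])
        bg_ranks = [naive_ranks(sets[f"set{k}"]) for k in (1, 2, 3)]
        expected = sorted(
            f"p{i}"
            for i in range(n_prot)
            if focal_ranks[i] / np.median([r[i] for r in bg_ranks]) < 0.33
        )
        assert got == expected


class TestReport:
    def test_density_formatting_and_sort(self):
        scores = {
            "focal": [
                ProteinVariantScore("crtLb", "focal", 7, 347, rank=1.0),
                ProteinVariantScore("other", "focal", 2, 400, rank=2.0),
            ],
            "bg1": [
                ProteinVariantScore("crtLb", "bg1", 0, 347, rank=10.0),
                ProteinVariantScore("other", "bg1", 1, 400, rank=5.0),
            ],
            "bg2": [
                ProteinVariantScore("crtLb", "bg2", 0, 347, rank=12.0),
                ProteinVariantScore("other", "bg2", 0, 400, rank=8.0),
            ],
        }
        df = variant_report(["crtLb", "other"], scores, "focal", ["bg1", "bg2"])
        assert df.iloc[0]["variants"] == "7/347"
        assert df.iloc[0]["density"] == pytest.approx(7 / 347)
        assert list(df["clog"]) == ["crtLb", "other"]  # density-descending

    def test_empty_candidates(self):
        df = variant_report([], {"focal": []}, "focal", ["bg1", "bg2"])
        assert len(df) == 0
        assert "variants" in df.columns


def test_score_proteins_density(default_dataset):
    aln = default_dataset["alignments"]
    cfg = SimConfig(seed=11)
    members = cfg.strains_of_set(cfg.target_sets[0])
    v = specific_variants(aln, members, set_id="t0")
    scores = score_proteins(aln, v, "t0")
    by_clog = {s.clog: s for s in scores}
    counts = {}
    for x in v:
        counts[x.clog] = counts.get(x.clog, 0) + 1
    for clog, n in counts.items():
        assert by_clog[clog].n_variants == n
        assert by_clog[clog].density == pytest.approx(n / aln.length_of(clog))
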