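"""Gene-content dendrogram vs core-protein tree comparison.

The gene-content (phyletic) tree is built by neighbor joining from the
Jaccard distance matrix of family presence sets, with bootstrap supports
from column resampling.  Comparison with the core-protein tree covers
topology (Robinson-Foulds distance, per-clade monophyly) and branch-length
structure: for each clade-base node, the ratio of mean external length
(node to descendant leaves) to internal length (node to parent) is
computed in both trees and the paired ratios are compared with a Wilcoxon
signed-rank test.  A larger external/internal ratio in the phyletic tree
than in the core tree indicates that gene content keeps churning within
clades after the core sequences have settled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import wilcoxon
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .model import EvoTree, PhyleticPattern, StrainMetadata


def phyletic_distances(
    pattern: PhyleticPattern, scope: str = "all_families"
) -> np.ndarray:
    """Strain x strain Jaccard distance matrix from the phyletic pattern.

    ``scope`` is ``all_families`` or ``non_core`` (families absent from at
    least one strain); the non-core scope drops universally shared families,
    which compress all distances uniformly.
    """
    presence = pattern.presence
    if scope == "non_core":
        presence = presence[:, ~presence.all(axis=0)]
    elif scope != "all_families":
        raise ValueError(f"unknown scope {scope!r}")
    sizes = presence.sum(axis=1)
    if (sizes == 0).any():
        empty = [s for s, n in zip(pattern.strains, sizes) if n == 0]
        raise ValueError(f"strains with zero families in scope: {empty}")
    return squareform(pdist(presence, metric="jaccard"))


def nj_tree(
    dist: np.ndarray,
    taxa: list[str],
    pattern: PhyleticPattern | None = None,
    bootstrap: int = 100,
    scope: str = "all_families",
    seed: int = 0,
) -> tuple[EvoTree, dict[frozenset, float]]:
    """Neighbor-joining tree from a distance matrix, with bootstrap supports.

    Bootstrap replicates resample CLOG columns of the pattern with
    replacement, recompute Jaccard distances and rebuild NJ; support of a
    bipartition is the percentage of replicates in which it recurs.
    Returns the (arbitrarily rooted) tree and a map from leaf bipartition
    (frozenset of leaves on one side) to support in [0, 100].
    """
    dist = np.asarray(dist, dtype=float)
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    tree = _nj_evotree(dist, taxa)
    supports: dict[frozenset, float] = {}
    if pattern is not None and bootstrap > 0:
        rng = np.random.default_rng(seed)
        target = _bipartitions(tree)
        hits = {bp: 0 for bp in target}
        presence = pattern.presence
        n_cols = presence.shape[1]
        for _ in range(bootstrap):
            cols = rng.integers(n_cols, size=n_cols)
            bp_pattern = PhyleticPattern(
                list(pattern.strains),
                [f"b{i}" for i in range(n_cols)],
                pattern.counts[:, cols],
            )
            try:
                d = phyletic_distances(bp_pattern, scope=scope)
            except ValueError:
                continue
            rep = _nj_evotree(d, taxa)
            found = _bipartitions(rep)
            for bp in hits:
                if bp in found:
                    hits[bp] += 1
        supports = {bp: 100.0 * k / bootstrap for bp, k in hits.items()}
    return tree, supports


def _nj_evotree(dist: np.ndarray, taxa: list[str]) -> EvoTree:
    dm = DistanceMatrix(dist, ids=taxa)
    tnode = _skbio_nj(dm)
    # skbio returns an unrooted tree as a basal trifurcation; keep the shape
    # by attaching a zero-length root split on the first basal child.
    newick = str(tnode).strip()
    return EvoTree.from_newick(newick, "unitless", outgroup=None) \
        if _is_rooted_newick(newick) else EvoTree.from_newick(_root_trifurcation(newick), "unitless")


def _is_rooted_newick(newick: str) -> bool:
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
    return len(t.seed_node.child_nodes()) <= 2


def _root_trifurcation(newick: str) -> str:
    """Turn a basal trifurcation (A,B,C); into ((B,C):0,A); deterministically."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
    children = t.seed_node.child_nodes()
    first = children[0]
    new_root = dendropy.Node()
    inner = dendropy.Node()
    inner.edge.length = 0.0
    for c in children[1:]:
        t.seed_node.remove_child(c)
        inner.add_child(c)
    t.seed_node.remove_child(first)
    new_root.add_child(first)
    new_root.add_child(inner)
    t.seed_node = new_root
    return t.as_string(schema="newick", suppress_rooting=True).strip()


def _bipartitions(tree: EvoTree) -> set[frozenset]:
    """Non-trivial leaf bipartitions, each canonicalized to the smaller side."""
    all_leaves = frozenset(tree.leaf_ids)
    out = set()
    for node in tree.preorder():
        if node.parent is None or node.is_leaf:
            continue
        below = tree.leafset_below(node)
        if len(below) <= 1 or len(below) >= len(all_leaves) - 1:
            continue
        other = all_leaves - below
        out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
    return out


def robinson_foulds(tree_a: EvoTree, tree_b: EvoTree) -> int:
    """Robinson-Foulds distance (symmetric difference of bipartition sets)."""
    if set(tree_a.leaf_ids) != set(tree_b.leaf_ids):
        a, b = set(tree_a.leaf_ids), set(tree_b.leaf_ids)
        raise ValueError(
            f"leaf sets differ: only in A {sorted(a - b)}, only in B {sorted(b - a)}"
        )
    return len(_bipartitions(tree_a) ^ _bipartitions(tree_b))


# ---------------------------------------------------------------------------
# Branch-ratio analysis
# ---------------------------------------------------------------------------


@dataclass
class BranchRatioRecord:
    node_id: str
    external: float     # mean path length node -> descendant leaves
    internal: float     # parent edge length
    ratio: float
    tree_tag: str       # "core" | "phyletic"


def clade_base_nodes(tree: EvoTree, metadata: StrainMetadata, level: str = "clade") -> list[str]:
    """Ids of nodes whose descendant leaves exactly form one monophyletic group."""
    groups = metadata.groups(level)
    targets = {frozenset(members): g for g, members in groups.items() if len(members) >= 2}
    out = []
    for node in tree.preorder():
        if node.is_leaf or node.parent is None:
            continue
        if tree.leafset_below(node) in targets:
            out.append(node.id)
    return out


def branch_ratio_analysis(
    tree: EvoTree, nodes: list[str], tree_tag: str = "core"
) -> list[BranchRatioRecord]:
    """External/internal branch-length ratio for each clade-base node.

    External = mean over descendant leaves of the node-to-leaf path length;
    internal = the node's parent edge length.
    """
    records = []
    depth = tree.depths()
    for nid in nodes:
        node = tree.node(nid)
        if node.parent is None:
            raise ValueError(f"node {nid!r} is the root (no parent edge)")
        leaves = tree.leafset_below(node)
        external = float(np.mean([depth[l] - depth[nid] for l in leaves]))
        internal = node.length
        ratio = external / internal if internal > 0 else float("inf")
        records.append(BranchRatioRecord(nid, external, internal, ratio, tree_tag))
    return records


@dataclass
class PairedRatioTest:
    statistic: float
    p_value: float
    direction: int       # sign of the median (phyletic - core) difference
    n_pairs: int


def paired_ratio_test(
    core_records: list[BranchRatioRecord],
    phyletic_records: list[BranchRatioRecord],
) -> PairedRatioTest:
    """Wilcoxon signed-rank test on per-node (phyletic - core) ratio differences.

    Exact null distribution for n <= 25 pairs, normal approximation with
    continuity correction above.  Matching is by node id; an unpaired node
    is an error.
    """
    core = {r.node_id: r.ratio for r in core_records}
    phyl = {r.node_id: r.ratio for r in phyletic_records}
    unpaired = set(core) ^ set(phyl)
    if unpaired:
        raise ValueError(f"unpaired nodes: {sorted(unpaired)}")
    nodes = sorted(core)
    diffs = np.array([phyl[n] - core[n] for n in nodes])
    direction = int(np.sign(np.median(diffs)))
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        return PairedRatioTest(0.0, 1.0, 0, len(nodes))
    method = "exact" if len(nonzero) <= 25 else "approx"
    stat, p = wilcoxon(nonzero, alternative="two-sided", method=method, correction=True)
    return PairedRatioTest(float(stat), float(p), direction, len(nodes))


# ---------------------------------------------------------------------------
# Discordance report
# ---------------------------------------------------------------------------


@dataclass
class DiscordanceReport:
    rf_distance: int
    monophyly_a: dict[str, bool]
    monophyly_b: dict[str, bool]
    broken_in_b: list[str]      # clades monophyletic in A but not in B


def tree_discordance(
    tree_a: EvoTree,
    tree_b: EvoTree,
    metadata: StrainMetadata,
    level: str = "clade",
) -> DiscordanceReport:
    """Topology comparison: RF distance and per-clade monophyly in each tree."""
    rf = robinson_foulds(tree_a, tree_b)

    def monophyly(tree: EvoTree) -> dict[str, bool]:
        leaves = set(tree.leaf_ids)
        clades = {}
        nodesets = {tree.leafset_below(n) for n in tree.preorder()}
        for g, members in metadata.groups(level).items():
            members = frozenset(m for m in members if m in leaves)
            if not members:
                continue
            clades[g] = members in nodesets or len(members) == 1
        return clades

    mono_a = monophyly(tree_a)
    mono_b = monophyly(tree_b)
    broken = sorted(g for g in mono_a if mono_a[g] and not mono_b.get(g, False))
    return DiscordanceReport(rf, mono_a, mono_b, broken)
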