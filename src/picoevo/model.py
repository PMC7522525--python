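"""Shared domain types for the picocyanobacterial comparative-genomics pipeline.

The central objects are the phyletic pattern (strains x gene-family copy
counts), a rooted tree whose branch lengths carry a declared unit
(substitutions/site, million years, or unitless), per-strain annotated gene
maps, and sets of single-copy core-protein alignments.  Everything downstream
(pan-genome structure, gain/loss reconstruction, island detection, tree-space
comparison, variant screens) consumes these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import dendropy
import numpy as np


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


class ReconciliationError(ValueError):
    """Raised when companion inputs disagree (strain sets, CLOG sets, leaves)."""


# ---------------------------------------------------------------------------
# Phyletic pattern
# ---------------------------------------------------------------------------

@dataclass
class PhyleticPattern:
    """Strains x CLOG copy-count matrix.

    A CLOG (cluster of likely orthologous genes) is a gene family across
    genomes.  ``counts[i, j]`` is the number of copies of family ``clogs[j]``
    in strain ``strains[i]``.  All presence/absence analyses use the
    binarized view (presence = count >= 1); copy numbers are retained for
    reporting only.
    """

    strains: list[str]
    clogs: list[str]
    counts: np.ndarray  # (n_strains, n_clogs) non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.strains), len(self.clogs)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.strains)} strains x {len(self.clogs)} CLOGs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("copy counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("copy counts must be non-negative")
        if len(set(self.strains)) != len(self.strains):
            raise FormatError("duplicate strain ids in phyletic pattern")
        if len(set(self.clogs)) != len(self.clogs):
            raise FormatError("duplicate CLOG ids in phyletic pattern")
        self._strain_index = {s: i for i, s in enumerate(self.strains)}
        self._clog_index = {c: j for j, c in enumerate(self.clogs)}

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_clogs(self) -> int:
        return len(self.clogs)

    @property
    def presence(self) -> np.ndarray:
        """Boolean presence/absence view (count >= 1)."""
        return self.counts >= 1

    def strain_index(self, strain: str) -> int:
        return self._strain_index[strain]

    def clog_index(self, clog: str) -> int:
        return self._clog_index[clog]

    def families_of(self, strain: str) -> set[str]:
        row = self.presence[self._strain_index[strain]]
        return {c for c, p in zip(self.clogs, row) if p}

    def subset_strains(self, strains: Iterable[str]) -> "PhyleticPattern":
        strains = list(strains)
        idx = [self._strain_index[s] for s in strains]
        return PhyleticPattern(strains, list(self.clogs), self.counts[idx])


# ---------------------------------------------------------------------------
# Rooted tree with unit-tagged branch lengths
# ---------------------------------------------------------------------------

VALID_UNITS = ("subs/site", "My", "unitless")


class TreeNode:
    """Node of an :class:`EvoTree`; ``length`` is the edge to the parent."""

    __slots__ = ("id", "parent", "children", "length", "label_from_input")

    def __init__(self, id: str = "", length: float = 0.0) -> None:
        self.id = id
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.length = float(length)
        self.label_from_input = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.id!r}, length={self.length})"


class EvoTree:
    """Rooted tree with non-negative branch lengths and a declared unit.

    Internal node ids are stable: input labels are kept when present,
    otherwise ids ``N<k>`` are assigned in preorder, so two trees with the
    same topology receive the same ids.  Leaf labels are strain ids.
    """

    def __init__(self, root: TreeNode, unit: str) -> None:
        if unit not in VALID_UNITS:
            raise ValueError(f"unknown branch-length unit {unit!r}; use one of {VALID_UNITS}")
        self.root = root
        self.unit = unit
        self._assign_ids()
        for node in self.preorder():
            if node.length < 0:
                raise ValueError(f"negative branch length on node {node.id!r}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, unit: str, outgroup: str | None = None) -> "EvoTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=True)
        if outgroup is not None:
            taxon = dtree.taxon_namespace.get_taxon(outgroup)
            if taxon is None:
                raise ReconciliationError(f"outgroup {outgroup!r} not found among leaves")
            node = dtree.find_node_with_taxon_label(outgroup)
            dtree.to_outgroup_position(node, update_bipartitions=False)
        nchild = len(dtree.seed_node.child_nodes())
        if nchild > 2:
            raise FormatError(
                "unrooted tree (basal multifurcation); supply an outgroup to root it"
            )
        root = cls._convert(dtree.seed_node)
        return cls(root, unit)

    @staticmethod
    def _convert(dnode: dendropy.Node) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = TreeNode(label or "", dnode.edge.length or 0.0)
        node.label_from_input = label is not None
        for child in dnode.child_nodes():
            node.add_child(EvoTree._convert(child))
        return node

    def _assign_ids(self) -> None:
        counter = 0
        for node in self.preorder():
            if not node.id:
                counter += 1
                node.id = f"N{counter}"
        ids = [n.id for n in self.preorder()]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate node ids in tree")
        self._index = {n.id: n for n in self.preorder()}

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        yield from reversed(list(self.preorder()))

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_ids(self) -> list[str]:
        return [n.id for n in self.leaves]

    @property
    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    def node(self, node_id: str) -> TreeNode:
        return self._index[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def leafset_below(self, node: TreeNode) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.id)
            else:
                stack.extend(n.children)
        return frozenset(out)

    # -- metrics -----------------------------------------------------------

    def depths(self) -> dict[str, float]:
        """Path length from the root to each node."""
        depth = {self.root.id: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                depth[node.id] = depth[node.parent.id] + node.length
        return depth

    def node_ages(self) -> dict[str, float]:
        """Age of each node = max depth minus its depth (leaves at ~0 on a chronogram)."""
        depth = self.depths()
        height = max(depth[l] for l in self.leaf_ids)
        return {nid: height - d for nid, d in depth.items()}

    def patristic_distance(self, a: str, b: str) -> float:
        depth = self.depths()
        pa = self._path_to_root(self.node(a))
        pb = set(n.id for n in self._path_to_root(self.node(b)))
        mrca = next(n for n in pa if n.id in pb)
        return depth[a] + depth[b] - 2.0 * depth[mrca.id]

    def _path_to_root(self, node: TreeNode) -> list[TreeNode]:
        path = [node]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        return path

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depth = self.depths()
        d = [depth[l] for l in self.leaf_ids]
        span = max(d) - min(d)
        return span <= rel_tol * max(max(d), 1e-300)

    def total_length(self) -> float:
        return sum(n.length for n in self.preorder() if n.parent is not None)

    # -- serialization -----------------------------------------------------

    def to_newick(self, internal_labels: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                base = node.id
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = node.id if (internal_labels or node.label_from_input) else ""
                base = f"({inner}){label}"
            if node.parent is None:
                return base
            return f"{base}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def copy(self) -> "EvoTree":
        def clone(node: TreeNode) -> TreeNode:
            c = TreeNode(node.id, node.length)
            c.label_from_input = node.label_from_input
            for child in node.children:
                c.add_child(clone(child))
            return c

        return EvoTree(clone(self.root), self.unit)

    def with_lengths(self, lengths: Mapping[str, float], unit: str) -> "EvoTree":
        """Copy of the tree with per-node parent-edge lengths replaced."""
        tree = self.copy()
        tree.unit = unit
        for node in tree.preorder():
            if node.parent is not None:
                tree.node(node.id).length = float(lengths[node.id])
        return tree


# ---------------------------------------------------------------------------
# Annotated genomes
# ---------------------------------------------------------------------------

@dataclass
class CDSFeature:
    """One CDS; coordinates are 1-based inclusive as in GFF3."""

    start: int
    end: int
    strand: str
    clog: str | None
    full_length: bool = True
    gained: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(f"invalid CDS coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """Ordered CDS features of one strain; substrate of island detection."""

    strain: str
    length: int
    features: list[CDSFeature] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > self.length:
                raise FormatError(
                    f"{self.strain}: CDS {f.start}..{f.end} exceeds genome length {self.length}"
                )

    @property
    def clogs(self) -> set[str]:
        return {f.clog for f in self.features if f.clog is not None}


# ---------------------------------------------------------------------------
# Strain metadata
# ---------------------------------------------------------------------------

@dataclass
class StrainMetadata:
    """Per-strain taxonomic labels: sub-cluster, clade, sub-clade, ESTU."""

    table: dict[str, dict[str, str | None]]

    LEVELS = ("sub_cluster", "clade", "subclade", "ESTU")

    def __post_init__(self) -> None:
        for strain, row in self.table.items():
            for key in self.LEVELS:
                row.setdefault(key, None)

    @property
    def strains(self) -> list[str]:
        return list(self.table)

    def label(self, strain: str, level: str) -> str | None:
        return self.table[strain].get(level)

    def groups(self, level: str) -> dict[str, list[str]]:
        """Map group label -> member strains at a taxonomic level."""
        out: dict[str, list[str]] = {}
        for strain, row in self.table.items():
            lab = row.get(level)
            if lab is not None:
                out.setdefault(lab, []).append(strain)
        return out

    def check_covers(self, pattern: PhyleticPattern) -> None:
        missing = [s for s in pattern.strains if s not in self.table]
        if missing:
            raise ReconciliationError(f"strains absent from metadata: {missing}")


# ---------------------------------------------------------------------------
# Core-protein alignments
# ---------------------------------------------------------------------------

@dataclass
class CoreAlignmentSet:
    """Single-copy core amino-acid alignments, one per CLOG.

    Each alignment maps strain id -> gapped sequence; within a CLOG all
    sequences have equal length and every strain occurs exactly once.
    """

    alignments: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for clog, aln in self.alignments.items():
            lengths = {len(s) for s in aln.values()}
            if len(lengths) > 1:
                raise FormatError(f"ragged alignment in {clog}: lengths {sorted(lengths)}")

    @property
    def clog_ids(self) -> list[str]:
        return sorted(self.alignments)

    @property
    def strains(self) -> list[str]:
        first = self.alignments[self.clog_ids[0]]
        return sorted(first)

    def length_of(self, clog: str) -> int:
        aln = self.alignments[clog]
        return len(next(iter(aln.values())))

    @property
    def total_residues(self) -> int:
        """Sum of alignment lengths over all families (columns, gaps included)."""
        return sum(self.length_of(c) for c in self.alignments)

    def concatenated(self) -> dict[str, str]:
        """Per-strain concatenation over families in sorted CLOG-id order."""
        strains = self.strains
        for clog in self.clog_ids:
            if sorted(self.alignments[clog]) != strains:
                raise ReconciliationError(
                    f"alignment {clog} does not cover the common strain set"
                )
        return {s: "".join(self.alignments[c][s] for c in self.clog_ids) for s in strains}

    def matrix(self, clog: str, strain_order: list[str]) -> np.ndarray:
        """Alignment as a (n_strains, length) array of single characters."""
        aln = self.alignments[clog]
        return np.array([list(aln[s]) for s in strain_order])
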