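"""Genomic-island detection and the inter-strain island-sharing network.

A genomic island is a chromosomal region enriched in recently gained genes.
Detection slides fixed-size windows (default 10 kb, 100 bp step) along each
genome and flags windows where gained CDS nucleotides make up more than 50%
of all coding nucleotides in the window (both clipped to the window).
Maximal runs of consecutive qualifying windows are merged, then each region
is trimmed inward so that its first and last genes are full-length gained
genes; regions with fewer than two genes are dropped.

Islands from different strains are connected in a network when their gene
(CLOG) content Jaccard similarity reaches 0.1 — i.e. they share at least 10%
of their pooled gene content.  Edges also carry the patristic distance
between the two strains on the core-protein tree.  Modules are found by
Louvain modularity optimization; the resolution parameter scales the
null-model term (higher resolution, more and smaller modules).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import AnnotatedGenome, CDSFeature, EvoTree


@dataclass
class Island:
    strain: str
    island_id: str                  # e.g. GI007
    first_gene: int                 # 0-based index into the genome's feature list
    last_gene: int
    start: int                      # 1-based inclusive nucleotide span
    end: int
    clogs: list[str] = field(default_factory=list)
    gained_clogs: list[str] = field(default_factory=list)
    wraps_origin: bool = False

    @property
    def n_genes(self) -> int:
        return len(self.clogs)

    @property
    def key(self) -> tuple[str, str]:
        return (self.strain, self.island_id)


def detect_islands(
    genome: AnnotatedGenome,
    gained: set[str],
    window: int = 10_000,
    step: int = 100,
    ratio_threshold: float = 0.5,
    min_genes: int = 2,
) -> list[Island]:
    """Detect gained-gene-enriched regions in one genome.

    ``gained`` is the set of CLOG ids gained on the strain's terminal
    branch (features whose ``gained`` flag is set are also honored).
    Windows with zero coding nucleotides never qualify.  On circular
    genomes windows wrap; an island spanning the origin is reported with
    ``end < start`` and ``wraps_origin`` set.
    """
    if window < step:
        raise ValueError("window must be >= step")
    if not genome.features:
        return []
    length = genome.length
    coding = np.zeros(length, dtype=np.int8)
    gained_nt = np.zeros(length, dtype=np.int8)
    for f in genome.features:
        coding[f.start - 1:f.end] = 1
        if _is_gained(f, gained):
            gained_nt[f.start - 1:f.end] = 1
    if genome.circular:
        coding = np.concatenate([coding, coding[:window]])
        gained_nt = np.concatenate([gained_nt, gained_nt[:window]])
        starts = np.arange(0, length, step)
    else:
        if length < window:
            starts = np.array([0])
            window = length
        else:
            starts = np.arange(0, length - window + 1, step)
    ccod = np.concatenate([[0], np.cumsum(coding)])
    cgain = np.concatenate([[0], np.cumsum(gained_nt)])
    ends = starts + window
    tot = ccod[ends] - ccod[starts]
    gai = cgain[ends] - cgain[starts]
    qualifies = (tot > 0) & (gai > ratio_threshold * tot)

    regions = _runs_to_regions(starts, qualifies, window)
    islands: list[Island] = []
    for r_start, r_end in regions:
        isl = _trim_region(genome, gained, r_start, r_end, min_genes, length)
        if isl is not None:
            islands.append(isl)
    islands = _dedupe(islands)
    for i, isl in enumerate(islands, start=1):
        isl.island_id = f"GI{i:03d}"
    return islands


def _is_gained(f: CDSFeature, gained: set[str]) -> bool:
    return f.gained or (f.clog is not None and f.clog in gained)


def _runs_to_regions(starts: np.ndarray, qualifies: np.ndarray, window: int):
    """Merge maximal runs of consecutive qualifying windows into regions."""
    regions = []
    run_start = None
    for s, q in zip(starts, qualifies):
        if q and run_start is None:
            run_start = s
        elif not q and run_start is not None:
            regions.append((int(run_start) + 1, int(prev) + window))  # 1-based inclusive
            run_start = None
        prev = s
    if run_start is not None:
        regions.append((int(run_start) + 1, int(prev) + window))
    return regions


def _trim_region(
    genome: AnnotatedGenome,
    gained: set[str],
    r_start: int,
    r_end: int,
    min_genes: int,
    length: int,
) -> Island | None:
    """Trim a candidate region so it starts and ends with full-length gained genes."""
    members = []
    for i, f in enumerate(genome.features):
        s, e = f.start, f.end
        if genome.circular and r_end > length:
            in_region = (e >= r_start) or (s <= r_end - length)
        else:
            in_region = (s <= r_end) and (e >= r_start)
        if in_region:
            members.append(i)
    members = _trim_boundary_blocks(genome.features, members, gained)
    if len(members) < min_genes:
        return None
    first, last = members[0], members[-1]
    feats = [genome.features[i] for i in members]
    start, end = feats[0].start, feats[-1].end
    wraps = genome.circular and end < start
    return Island(
        strain=genome.strain,
        island_id="",
        first_gene=first,
        last_gene=last,
        start=start,
        end=end,
        clogs=[f.clog for f in feats if f.clog is not None],
        gained_clogs=[f.clog for f in feats if f.clog is not None and _is_gained(f, gained)],
        wraps_origin=wraps,
    )


def _boundary_ok(f: CDSFeature, gained: set[str]) -> bool:
    return f.full_length and _is_gained(f, gained)


def _trim_boundary_blocks(features, members: list[int], gained: set[str]) -> list[int]:
    """Trim a member-gene run inward to full-length gained boundary genes.

    Besides dropping non-gained boundary genes, a boundary *block* of gained
    genes is dropped when the non-gained gap separating it from the next
    gained gene carries more coding nucleotides than the block itself — the
    same >50% gained-coding enrichment that defines qualifying windows,
    applied locally.  This stops scattered gained singletons in the window
    flanks from dragging ancestral genes into the island.
    """
    def coding(idx: list[int]) -> int:
        return sum(features[i].length for i in idx)

    changed = True
    while changed and members:
        changed = False
        for side in (0, -1):
            while members and not _boundary_ok(features[members[side]], gained):
                members.pop(side)
                changed = True
            if not members:
                break
            # boundary block of consecutive gained genes, then the non-gained gap
            seq = members if side == 0 else members[::-1]
            block = []
            gap = []
            for i in seq:
                if not gap and _boundary_ok(features[i], gained):
                    block.append(i)
                elif not _is_gained(features[i], gained):
                    gap.append(i)
                else:
                    break
            if block and gap and len(block) + len(gap) < len(members) \
                    and coding(gap) >= coding(block):
                for i in block + gap:
                    members.remove(i)
                changed = True
    return members


def _dedupe(islands: list[Island]) -> list[Island]:
    seen = set()
    out = []
    for isl in sorted(islands, key=lambda i: (i.first_gene, i.last_gene)):
        key = (isl.first_gene, isl.last_gene)
        if key not in seen:
            seen.add(key)
            out.append(isl)
    return out


# ---------------------------------------------------------------------------
# Island-sharing network
# ---------------------------------------------------------------------------


def island_similarity(a: Island, b: Island) -> float:
    """Jaccard similarity of the two islands' CLOG sets."""
    sa, sb = set(a.clogs), set(b.clogs)
    if not sa or not sb:
        raise ValueError("cannot compare an empty island")
    return len(sa & sb) / len(sa | sb)


def build_network(
    islands: list[Island],
    core_tree: EvoTree | None = None,
    edge_threshold: float = 0.1,
) -> nx.Graph:
    """Build the island-sharing graph.

    Nodes are (strain, island id) pairs; an edge connects two islands of
    *different* strains whose CLOG-content Jaccard similarity is at least
    ``edge_threshold``.  Edges carry ``jaccard`` and, when a core tree is
    given, ``patristic_distance`` between the strains.  Isolated islands
    remain as singleton nodes.
    """
    if core_tree is not None:
        missing = {i.strain for i in islands} - set(core_tree.leaf_ids)
        if missing:
            raise ValueError(f"strains missing from core tree: {sorted(missing)}")
    g = nx.Graph()
    for isl in islands:
        g.add_node(isl.key, strain=isl.strain, n_genes=isl.n_genes)
    dist_cache: dict[tuple[str, str], float] = {}
    for i in range(len(islands)):
        for j in range(i + 1, len(islands)):
            a, b = islands[i], islands[j]
            if a.strain == b.strain:
                continue
            sim = island_similarity(a, b)
            if sim >= edge_threshold:
                attrs = {"jaccard": sim}
                if core_tree is not None:
                    pair = tuple(sorted((a.strain, b.strain)))
                    if pair not in dist_cache:
                        dist_cache[pair] = core_tree.patristic_distance(*pair)
                    attrs["patristic_distance"] = dist_cache[pair]
                g.add_edge(a.key, b.key, **attrs)
    return g


def detect_modules(
    network: nx.Graph,
    resolution: float = 0.2,
    seed: int = 0,
) -> dict:
    """Louvain modularity modules; returns node -> module id (0-based).

    Edge weights are the Jaccard similarities.  The assignment is
    deterministic given the seed; module ids are renumbered by sorted
    smallest member for stability.
    """
    if network.number_of_nodes() == 0:
        return {}
    communities = nx.community.louvain_communities(
        network, weight="jaccard", resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda c: sorted(c)[0])
    return {node: i for i, comm in enumerate(communities) for node in comm}
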