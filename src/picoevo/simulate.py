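"""Synthetic-data generator with ground truth for every pipeline stage.

The generator emits the objects the analyses consume — an ultrametric
chronogram plus a companion substitutions/site tree, a phyletic pattern
produced by a gain/loss process on that chronogram, per-strain annotated
genomes in which a fraction of recently gained genes is planted in
contiguous island loci, single-copy core-protein alignments carrying planted
clade-specific residues, and divergence-controlled nucleotide pairs — and a
:class:`TruthLog` recording the events behind each of them.

Gains are irreversible per family (a family gained once is never re-gained
on another branch), so every gained family is attributable to exactly one
branch and per-branch truth is unambiguous.  Truth for set-specific variant
columns is defined by a definition scan of the *final* alignments, so
columns that satisfy the specificity definition by chance are part of the
truth rather than spurious false positives.

All emissions are bit-reproducible given (config, seed): a single global
seed spawns one independent substream per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import AnnotatedGenome, CDSFeature, CoreAlignmentSet, EvoTree, PhyleticPattern, TreeNode

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the simulated world.

    Rates are per million years (My).  Defaults describe a desk-scale
    version of a marine picocyanobacterial radiation: 16 strains in 4
    clades, a root about 1,000 My old, a core-protein substitution rate
    giving root-to-tip divergence of ~0.25 substitutions/site, a root
    repertoire of 1,000 gene families, and gain/loss rates that leave a
    persistent core alongside substantial strain-specific gene content.
    """

    n_strains: int = 16
    n_clades: int = 4
    clade_map: dict[str, str] | None = None  # strain -> clade; derived if None
    fixed_newick: str | None = None          # chronogram topology override (ages in My)
    root_age: float = 1000.0                 # My
    subs_rate: float = 2.5e-4                # substitutions/site/My on core proteins
    rate_sigma: float = 0.3                  # lognormal sd of per-branch rate multipliers
    n0: int = 1000                           # gene families at the root
    gain_rate: float = 0.5                   # families gained per branch per My
    loss_rate: float = 1.0e-3                # per-family loss rate per My
    islands_per_strain: int = 3              # minimum number of planted islands
    island_fraction: float = 0.9             # share of terminal gains placed in islands
    island_genes_min: int = 5
    island_genes_max: int = 10
    cds_length_mean: float = 900.0           # bp
    cds_length_sd: float = 0.0
    gap_length_mean: float = 100.0           # bp, intergenic
    gap_length_sd: float = 0.0
    n_core_families: int = 20
    family_length_mean: float = 250.0        # aa
    family_length_sd: float = 50.0
    planted_variants: int = 5                # per family per target set
    target_sets: list[tuple[str, ...]] | None = None  # unions of clades; one per clade if None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 3:
            raise ValueError("n_strains must be >= 3")
        for name in ("subs_rate", "gain_rate", "loss_rate", "root_age"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.clade_map is None:
            strains = [f"S{i+1:02d}" for i in range(self.n_strains)]
            self.clade_map = {
                s: f"clade{(i * self.n_clades) // self.n_strains + 1}"
                for i, s in enumerate(strains)
            }
        if self.target_sets is None:
            clades = sorted(set(self.clade_map.values()))
            self.target_sets = [(c,) for c in clades]

    @property
    def strains(self) -> list[str]:
        return list(self.clade_map)

    def strains_of_set(self, target: Sequence[str]) -> list[str]:
        clades = set(target)
        unknown = clades - set(self.clade_map.values())
        if unknown:
            raise ValueError(f"target set references unknown clades: {sorted(unknown)}")
        return [s for s, c in self.clade_map.items() if c in clades]


@dataclass
class PlantedIsland:
    strain: str
    first_gene: int          # 0-based index into the strain's gene order
    last_gene: int
    start: int               # 1-based inclusive nucleotide span
    end: int
    clogs: list[str] = field(default_factory=list)


@dataclass
class TruthLog:
    """Ground truth emitted alongside the synthetic data."""

    chronogram: EvoTree | None = None
    root_families: list[str] = field(default_factory=list)
    branch_gains: dict[str, list[str]] = field(default_factory=dict)   # child node id -> CLOGs
    branch_losses: dict[str, list[str]] = field(default_factory=dict)
    islands: dict[str, list[PlantedIsland]] = field(default_factory=dict)
    # set id -> list of (clog, column[1-based], set residue)
    specific_columns: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)

    def replay_presence(self, tree: EvoTree) -> dict[str, set[str]]:
        """Replay gains/losses from the root; returns per-leaf family sets."""
        present: dict[str, set[str]] = {tree.root.id: set(self.root_families)}
        for node in tree.preorder():
            if node.parent is None:
                continue
            s = set(present[node.parent.id])
            s -= set(self.branch_losses.get(node.id, ()))
            s |= set(self.branch_gains.get(node.id, ()))
            present[node.id] = s
        return {l: present[l] for l in tree.leaf_ids}


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    return _substreams(config.seed, 6)[stage]


# ---------------------------------------------------------------------------
# Chronogram + substitutions tree
# ---------------------------------------------------------------------------


def simulate_chronogram(config: SimConfig) -> tuple[EvoTree, EvoTree]:
    """Simulate an ultrametric chronogram (My) and a companion subs/site tree.

    The chronogram coalesces strains within clades first (node ages in the
    lower 40% of the root age), then joins clade ancestors, the final join
    occurring exactly at ``root_age``.  The substitutions tree shares the
    topology; each branch length is duration x ``subs_rate`` x a lognormal
    rate multiplier with sd ``rate_sigma`` (mean 1, so ``rate_sigma=0``
    makes the two trees exactly proportional).
    """
    rng = _stage_rng(config, 0)
    if config.fixed_newick is not None:
        chrono = EvoTree.from_newick(config.fixed_newick, "My")
    else:
        chrono = _random_clade_tree(config, rng)
    lengths = {}
    for node in chrono.preorder():
        if node.parent is None:
            continue
        mult = 1.0
        if config.rate_sigma > 0:
            mult = rng.lognormal(-config.rate_sigma**2 / 2.0, config.rate_sigma)
        lengths[node.id] = node.length * config.subs_rate * mult
    subs = chrono.with_lengths(lengths, "subs/site")
    return chrono, subs


def _random_clade_tree(config: SimConfig, rng: np.random.Generator) -> EvoTree:
    ages: dict[TreeNode, float] = {}
    clades: dict[str, list[TreeNode]] = {}
    for strain, clade in config.clade_map.items():
        node = TreeNode(strain)
        node.label_from_input = True
        ages[node] = 0.0
        clades.setdefault(clade, []).append(node)

    def coalesce(lineages: list[TreeNode], node_ages: np.ndarray) -> TreeNode:
        for age in np.sort(node_ages):
            i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
            parent = TreeNode("")
            ages[parent] = float(age)
            for k in (j, i):  # pop larger index first
                child = lineages.pop(k)
                child.length = ages[parent] - ages[child]
                parent.add_child(child)
            lineages.append(parent)
        return lineages[0]

    roots = []
    for clade in sorted(clades):
        lineages = clades[clade]
        node_ages = rng.uniform(0.05, 0.4, size=len(lineages) - 1) * config.root_age
        roots.append(coalesce(lineages, node_ages))
    if len(roots) > 1:
        node_ages = rng.uniform(0.5, 1.0, size=len(roots) - 1) * config.root_age
        node_ages[np.argmax(node_ages)] = config.root_age
        root = coalesce(roots, node_ages)
    else:
        root = roots[0]
    root.length = 0.0
    return EvoTree(root, "My")


# ---------------------------------------------------------------------------
# Gene content
# ---------------------------------------------------------------------------


def simulate_gene_content(
    tree: EvoTree, config: SimConfig, truth: TruthLog | None = None
) -> tuple[PhyleticPattern, TruthLog]:
    """Evolve gene content along the chronogram by gains and losses.

    On a branch of duration ``t``, each family present at the parent is lost
    with probability ``1 - exp(-loss_rate * t)``, and ``Poisson(gain_rate * t)``
    new families (fresh CLOG ids) appear.  The emitted pattern contains the
    families present in at least one tip (absent-everywhere families are
    unobservable in real data).
    """
    if tree.unit != "My":
        raise ValueError("gene-content simulation expects a chronogram in My")
    rng = _stage_rng(config, 1)
    truth = truth or TruthLog()
    truth.chronogram = tree
    root_fams = [f"F{i:05d}" for i in range(config.n0)]
    truth.root_families = root_fams
    present: dict[str, list[str]] = {tree.root.id: root_fams}
    counter = 0
    for node in tree.preorder():
        if node.parent is None:
            continue
        t = node.length
        parent_fams = present[node.parent.id]
        p_loss = 1.0 - np.exp(-config.loss_rate * t)
        keep = rng.random(len(parent_fams)) >= p_loss
        lost = [f for f, k in zip(parent_fams, keep) if not k]
        n_gain = rng.poisson(config.gain_rate * t)
        gained = [f"G{counter + i:06d}" for i in range(n_gain)]
        counter += n_gain
        truth.branch_losses[node.id] = lost
        truth.branch_gains[node.id] = gained
        present[node.id] = [f for f, k in zip(parent_fams, keep) if k] + gained
    leaf_sets = {l: set(present[l]) for l in tree.leaf_ids}
    observed = sorted(set().union(*leaf_sets.values()))
    strains = tree.leaf_ids
    counts = np.zeros((len(strains), len(observed)), dtype=np.int64)
    col = {f: j for j, f in enumerate(observed)}
    for i, s in enumerate(strains):
        for f in leaf_sets[s]:
            counts[i, col[f]] = 1
    return PhyleticPattern(strains, observed, counts), truth


def simulate_ctmc_pattern(
    tree: EvoTree,
    alpha: float,
    beta: float,
    n_families: int,
    seed: int,
) -> tuple[PhyleticPattern, TruthLog]:
    """Evolve a fixed set of families under the two-state gain/loss CTMC.

    Unlike :func:`simulate_gene_content` (where every gain creates a fresh
    family), here each family can be gained and lost repeatedly, exactly
    matching the reconstruction model.  Per-branch truth records endpoint
    state changes (gain = absent at parent, present at child).  Families
    absent from every tip are dropped, as they are unobservable.
    """
    rng = np.random.default_rng(seed)
    s = alpha + beta
    pi1 = alpha / s
    fams = np.array([f"f{i:05d}" for i in range(n_families)])
    state: dict[str, np.ndarray] = {tree.root.id: rng.random(n_families) < pi1}
    truth = TruthLog()
    truth.chronogram = tree if tree.unit == "My" else None
    for node in tree.preorder():
        if node.parent is None:
            continue
        e = np.exp(-s * node.length)
        p01 = alpha / s * (1.0 - e)
        p11 = 1.0 - beta / s * (1.0 - e)
        parent = state[node.parent.id]
        u = rng.random(n_families)
        child = np.where(parent, u < p11, u < p01)
        state[node.id] = child
        truth.branch_gains[node.id] = list(fams[~parent & child])
        truth.branch_losses[node.id] = list(fams[parent & ~child])
    presence = np.stack([state[l] for l in tree.leaf_ids])
    keep = presence.any(axis=0)
    truth.root_families = list(fams[state[tree.root.id] & keep])
    pattern = PhyleticPattern(
        tree.leaf_ids, list(fams[keep]), presence[:, keep].astype(np.int64)
    )
    # restrict truth to observable families
    observable = set(fams[keep])
    for d in (truth.branch_gains, truth.branch_losses):
        for k in d:
            d[k] = [f for f in d[k] if f in observable]
    return pattern, truth


# ---------------------------------------------------------------------------
# Genome layout with planted islands
# ---------------------------------------------------------------------------


def layout_genomes(
    pattern: PhyleticPattern,
    truth: TruthLog,
    config: SimConfig,
) -> tuple[list[AnnotatedGenome], TruthLog]:
    """Lay out each strain's genes on a linear genome, planting islands.

    Families gained on the strain's terminal branch are split: enough to
    fill ``islands_per_strain`` contiguous island loci (sizes uniform in
    [island_genes_min, island_genes_max]), the rest interleaved uniformly
    among ancestral genes.  CDS and intergenic-gap lengths are drawn from
    the configured normal distributions (sd 0 = exact).
    """
    rng = _stage_rng(config, 2)
    genomes: list[AnnotatedGenome] = []
    for strain in pattern.strains:
        srng = np.random.default_rng(rng.integers(2**31))
        present = pattern.families_of(strain)
        gained = [f for f in truth.branch_gains.get(strain, ()) if f in present]
        ancestral = sorted(present - set(gained))
        if config.islands_per_strain * config.island_genes_min > len(gained):
            raise ValueError(
                f"{strain}: planted islands need at least "
                f"{config.islands_per_strain * config.island_genes_min} gained genes "
                f"but only {len(gained)} were gained on the terminal branch; "
                "increase gain_rate"
            )
        # Islands absorb ~island_fraction of the terminal gains (recently
        # gained genes cluster in island loci); the rest are interleaved as
        # scattered singletons.
        quota = int(round(config.island_fraction * len(gained)))
        sizes: list[int] = []
        while True:
            size = int(srng.integers(config.island_genes_min, config.island_genes_max + 1))
            if sum(sizes) + size > len(gained):
                break
            if len(sizes) >= config.islands_per_strain and sum(sizes) + size > quota:
                break
            sizes.append(size)
        gained_shuffled = list(srng.permutation(gained))
        island_sets = []
        pos = 0
        for size in sizes:
            island_sets.append(gained_shuffled[pos:pos + size])
            pos += size
        scattered = gained_shuffled[pos:]
        background = ancestral + scattered
        background = list(srng.permutation(background))
        # Insert islands as blocks at distinct inter-gene positions.
        order: list[tuple[str, bool]] = [(f, f in set(scattered)) for f in background]
        insert_at = sorted(
            srng.choice(len(background) + 1, size=len(island_sets), replace=False),
            reverse=True,
        )
        island_gene_idx: list[tuple[int, int, list[str]]] = []
        for at, genes in zip(insert_at, island_sets):
            order[at:at] = [(g, True) for g in genes]
        # Recover island gene index ranges from the final order.
        # (Blocks were inserted back-to-front, so ranges are found by scanning.)
        features: list[CDSFeature] = []
        coords: list[tuple[int, int]] = []
        cursor = 1
        for fam, is_gained in order:
            cds_len = max(30, int(round(srng.normal(config.cds_length_mean, config.cds_length_sd)))) \
                if config.cds_length_sd > 0 else int(config.cds_length_mean)
            start, end = cursor, cursor + cds_len - 1
            coords.append((start, end))
            strand = "+" if srng.random() < 0.5 else "-"
            features.append(CDSFeature(start, end, strand, fam, full_length=True, gained=is_gained))
            gap = max(1, int(round(srng.normal(config.gap_length_mean, config.gap_length_sd)))) \
                if config.gap_length_sd > 0 else int(config.gap_length_mean)
            cursor = end + gap + 1
        genome_length = coords[-1][1] + int(config.gap_length_mean) if coords else 0
        # Locate each planted island in the final order.
        fam_at = [fam for fam, _ in order]
        planted = []
        for genes in island_sets:
            first = fam_at.index(genes[0])
            last = first + len(genes) - 1
            assert fam_at[first:last + 1] == genes
            planted.append(
                PlantedIsland(
                    strain=strain,
                    first_gene=first,
                    last_gene=last,
                    start=coords[first][0],
                    end=coords[last][1],
                    clogs=list(genes),
                )
            )
        truth.islands[strain] = planted
        genomes.append(AnnotatedGenome(strain, genome_length, features))
    return genomes, truth


# ---------------------------------------------------------------------------
# Core alignments with planted clade-specific residues
# ---------------------------------------------------------------------------


def _evolve_sequences(
    tree: EvoTree, length: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Evolve one family under a symmetric 20-state replacement process."""
    k = len(AMINO_ACIDS)
    seqs: dict[str, np.ndarray] = {
        tree.root.id: rng.integers(k, size=length)
    }
    for node in tree.preorder():
        if node.parent is None:
            continue
        t = node.length  # expected substitutions per site
        p_same = 1.0 / k + (k - 1.0) / k * np.exp(-k / (k - 1.0) * t)
        parent = seqs[node.parent.id]
        stay = rng.random(length) < p_same
        child = parent.copy()
        n_change = int((~stay).sum())
        if n_change:
            # uniform over the 19 other residues
            shift = rng.integers(1, k, size=n_change)
            child[~stay] = (parent[~stay] + shift) % k
        seqs[node.id] = child
    return {l: seqs[l] for l in tree.leaf_ids}


def scan_specific_columns(
    alignment: dict[str, str], strain_set: Sequence[str], gap_chars: str = "-."
) -> list[tuple[int, str]]:
    """Brute-force definition scan: columns where every set strain shares one
    residue and no outside strain carries it.  Columns containing a gap are
    excluded.  Returns (1-based column, set residue) pairs."""
    inside = [alignment[s] for s in strain_set]
    outside = [alignment[s] for s in alignment if s not in set(strain_set)]
    length = len(inside[0])
    hits = []
    for col in range(length):
        residues_in = {seq[col] for seq in inside}
        residues_out = {seq[col] for seq in outside}
        if any(g in residues_in or g in residues_out for g in gap_chars):
            continue
        if len(residues_in) == 1 and not (residues_in & residues_out):
            hits.append((col + 1, next(iter(residues_in))))
    return hits


def simulate_core_alignments(
    tree: EvoTree, config: SimConfig, truth: TruthLog | None = None
) -> tuple[CoreAlignmentSet, TruthLog]:
    """Simulate single-copy core alignments and plant set-specific residues.

    Background columns evolve under a symmetric amino-acid replacement
    process on the substitutions/site tree.  For each configured target set
    (a union of clades) and family, ``planted_variants`` columns are
    overwritten so all set strains carry one residue and every other strain
    carries a different one.  Truth is the exhaustive definition scan of the
    final alignments, so chance-arising specific columns are included.
    """
    if tree.unit != "subs/site":
        raise ValueError("alignment simulation expects a substitutions/site tree")
    rng = _stage_rng(config, 3)
    truth = truth or TruthLog()
    k = len(AMINO_ACIDS)
    strains = tree.leaf_ids
    set_ids = ["+".join(t) for t in config.target_sets]
    set_strains = {sid: config.strains_of_set(t) for sid, t in zip(set_ids, config.target_sets)}
    for sid, members in set_strains.items():
        if not members or len(members) == len(strains):
            raise ValueError(f"target set {sid} must be a non-empty proper strain subset")
    alignments: dict[str, dict[str, str]] = {}
    for fam_i in range(config.n_core_families):
        clog = f"C{fam_i + 1:04d}"
        length = max(50, int(round(rng.normal(config.family_length_mean, config.family_length_sd))))
        seqs = _evolve_sequences(tree, length, rng)
        # plant distinct columns for each target set
        n_needed = config.planted_variants * len(set_ids)
        cols = rng.choice(length, size=min(n_needed, length), replace=False)
        pos = 0
        for sid in set_ids:
            members = set(set_strains[sid])
            for col in cols[pos:pos + config.planted_variants]:
                res = int(rng.integers(k))
                for s in strains:
                    if s in members:
                        seqs[s][col] = res
                    else:
                        seqs[s][col] = (res + int(rng.integers(1, k))) % k
            pos += config.planted_variants
        alignments[clog] = {s: "".join(AMINO_ACIDS[seqs[s]]) for s in strains}
    aln_set = CoreAlignmentSet(alignments)
    for sid in set_ids:
        records = []
        for clog in aln_set.clog_ids:
            for col, res in scan_specific_columns(alignments[clog], set_strains[sid]):
                records.append((clog, col, res))
        truth.specific_columns[sid] = records
    return aln_set, truth


# ---------------------------------------------------------------------------
# Divergence-controlled nucleotide pairs
# ---------------------------------------------------------------------------


def simulate_sequence_pair(
    identity_target: float, length: int, seed: int
) -> tuple[str, str]:
    """Two nucleotide sequences at a controlled identity (substitutions only).

    Each site of the copy is mutated independently with probability
    ``1 - identity_target`` to a different base, so realized identity is
    binomially distributed about the target.
    """
    if not (0.0 < identity_target <= 1.0):
        raise ValueError("identity_target must be in (0, 1]")
    rng = np.random.default_rng(seed)
    a = rng.integers(4, size=length)
    mutate = rng.random(length) < (1.0 - identity_target)
    b = a.copy()
    n = int(mutate.sum())
    if n:
        b[mutate] = (a[mutate] + rng.integers(1, 4, size=n)) % 4
    return "".join(NUCLEOTIDES[a]), "".join(NUCLEOTIDES[b])


# ---------------------------------------------------------------------------
# One-call orchestration
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimConfig) -> dict:
    """Run all generator stages; returns a dict of every emitted object."""
    chrono, subs = simulate_chronogram(config)
    pattern, truth = simulate_gene_content(chrono, config)
    genomes, truth = layout_genomes(pattern, truth, config)
    alignments, truth = simulate_core_alignments(subs, config, truth)
    return {
        "chronogram": chrono,
        "subs_tree": subs,
        "pattern": pattern,
        "genomes": genomes,
        "alignments": alignments,
        "truth": truth,
    }
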