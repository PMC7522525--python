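"""Clade-specific amino-acid variants in single-copy core proteins.

A variant is *specific* to a strain set when the alignment column shows one
identical residue in every strain of the set and any different residue in
every other strain.  Applied with the set of leaves below an internal tree
node, the same definition yields *node-fixed* variants (terminal branches
are excluded: a strain-specific residue cannot be called fixed).

To compare proteins of different lengths, per-protein variant counts are
normalized by alignment length, proteins are ranked per strain set by this
density (rank 1 = densest, average ranks for ties), and candidates for a
focal set (e.g. the cold-adapted clades I+IV thermotype) are proteins whose
focal rank is less than ``cutoff`` (default 0.33) times the median rank
across background sets — i.e. proteins ranking three times higher for the
focal set than elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import CoreAlignmentSet, EvoTree

GAP_CHARS = ("-", ".")


@dataclass
class SpecificVariant:
    clog: str
    column: int                 # 1-based alignment column
    set_residue: str
    outside_residues: frozenset[str]
    strain_set_id: str


@dataclass
class ProteinVariantScore:
    clog: str
    strain_set_id: str
    n_variants: int
    length: int
    rank: float = float("nan")

    @property
    def density(self) -> float:
        return self.n_variants / self.length


def specific_variants(
    alignments: CoreAlignmentSet,
    strain_set: Sequence[str],
    set_id: str = "set",
    gap_policy: str = "exclude_column",
) -> list[SpecificVariant]:
    """All columns specific to ``strain_set`` across all families.

    ``gap_policy``: ``exclude_column`` drops any column containing a gap in
    any strain; ``gap_as_state`` treats the gap as a 21st character that may
    satisfy "any other amino acid" outside the set but can never be the set
    residue.
    """
    if gap_policy not in ("exclude_column", "gap_as_state"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    strain_set = list(strain_set)
    if not strain_set:
        raise ValueError("strain_set must be non-empty")
    all_strains = alignments.strains
    if set(strain_set) >= set(all_strains):
        raise ValueError("complement empty: strain_set covers every strain")
    missing = set(strain_set) - set(all_strains)
    if missing:
        raise ValueError(f"strains absent from alignments: {sorted(missing)}")
    outside = [s for s in all_strains if s not in set(strain_set)]
    out: list[SpecificVariant] = []
    for clog in alignments.clog_ids:
        mat_in = alignments.matrix(clog, strain_set)
        mat_out = alignments.matrix(clog, outside)
        length = mat_in.shape[1]
        gaps_in = np.isin(mat_in, GAP_CHARS)
        gaps_out = np.isin(mat_out, GAP_CHARS)
        uniform = (mat_in == mat_in[0]).all(axis=0)
        if gap_policy == "exclude_column":
            usable = ~gaps_in.any(axis=0) & ~gaps_out.any(axis=0)
            qualifying = usable & uniform & ~(mat_out == mat_in[0]).any(axis=0)
        else:  # gap_as_state
            usable = ~gaps_in.any(axis=0)  # gap can never be the set residue
            qualifying = usable & uniform & ~(mat_out == mat_in[0]).any(axis=0)
        for col in np.nonzero(qualifying)[0]:
            out.append(
                SpecificVariant(
                    clog=clog,
                    column=int(col) + 1,
                    set_residue=str(mat_in[0, col]),
                    outside_residues=frozenset(str(r) for r in np.unique(mat_out[:, col])),
                    strain_set_id=set_id,
                )
            )
    return out


def fixed_variants_per_node(
    alignments: CoreAlignmentSet,
    tree: EvoTree,
    gap_policy: str = "exclude_column",
) -> dict[str, list[SpecificVariant]]:
    """Node-fixed variants: per non-root internal node, columns specific to
    the set of leaves below it.  Leaves and the root are excluded."""
    out: dict[str, list[SpecificVariant]] = {}
    for node in tree.preorder():
        if node.is_leaf or node.parent is None:
            continue
        below = sorted(tree.leafset_below(node))
        out[node.id] = specific_variants(
            alignments, below, set_id=node.id, gap_policy=gap_policy
        )
    return out


def score_proteins(
    alignments: CoreAlignmentSet,
    variants: list[SpecificVariant],
    set_id: str,
) -> list[ProteinVariantScore]:
    """Per-protein variant densities and ranks for one strain set.

    Every family in the alignment set is scored (zero-variant proteins get
    density 0 and share the worst average rank).
    """
    counts: dict[str, int] = {c: 0 for c in alignments.clog_ids}
    for v in variants:
        counts[v.clog] += 1
    scores = [
        ProteinVariantScore(
            clog=c,
            strain_set_id=set_id,
            n_variants=counts[c],
            length=alignments.length_of(c),
        )
        for c in alignments.clog_ids
    ]
    densities = np.array([s.density for s in scores])
    ranks = rankdata(-densities, method="average")
    for s, r in zip(scores, ranks):
        s.rank = float(r)
    return scores


def rank_ratio_screen(
    scores_by_set: Mapping[str, list[ProteinVariantScore]],
    focal_set: str,
    background_sets: Sequence[str],
    cutoff: float = 0.33,
) -> list[str]:
    """Proteins whose focal-set rank beats the median background rank 3x.

    ``background_sets`` must exclude single-strain sets (their "specific"
    variants are ordinary strain-private substitutions) and hold at least
    two sets.  A protein is a candidate iff
    ``rank_focal / median(background ranks) < cutoff``.
    """
    if len(background_sets) < 2:
        raise ValueError("need at least 2 background sets")
    if focal_set in background_sets:
        raise ValueError("focal set cannot be part of the background")
    focal = {s.clog: s.rank for s in scores_by_set[focal_set]}
    backgrounds = {b: {s.clog: s.rank for s in scores_by_set[b]} for b in background_sets}
    candidates = []
    for clog, r_focal in focal.items():
        bg = [backgrounds[b][clog] for b in background_sets if clog in backgrounds[b]]
        if not bg:
            continue
        if r_focal / float(np.median(bg)) < cutoff:
            candidates.append(clog)
    return sorted(candidates)


def variant_report(
    candidates: Sequence[str],
    scores_by_set: Mapping[str, list[ProteinVariantScore]],
    focal_set: str,
    background_sets: Sequence[str],
    annotations: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Candidate table sorted by focal variant density (descending).

    The ``variants`` column renders counts as ``n/length`` (e.g. ``7/347``).
    """
    focal = {s.clog: s for s in scores_by_set[focal_set]}
    backgrounds = {
        b: {s.clog: s.rank for s in scores_by_set.get(b, [])} for b in background_sets
    }
    rows = []
    for clog in candidates:
        s = focal[clog]
        bg = [backgrounds[b][clog] for b in background_sets if clog in backgrounds[b]]
        rows.append(
            {
                "clog": clog,
                "description": (annotations or {}).get(clog, ""),
                "n_variants": s.n_variants,
                "length": s.length,
                "variants": f"{s.n_variants}/{s.length}",
                "density": s.density,
                "rank_focal": s.rank,
                "rank_ratio": s.rank / float(np.median(bg)) if bg else float("nan"),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "clog", "description", "n_variants", "length",
            "variants", "density", "rank_focal", "rank_ratio",
        ],
    )
    if len(df):
        df = df.sort_values(["density", "clog"], ascending=[False, True]).reset_index(drop=True)
    return df
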