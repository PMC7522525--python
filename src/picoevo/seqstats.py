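"""Sequence-level relatedness and composition statistics.

ANI follows the fragment-based scheme: the query genome is cut into
consecutive 1,020-bp fragments, each is locally aligned against the subject
(both strands), and a fragment's best hit is retained when its identity
exceeds 30% over at least 70% of the fragment length.  ANI is the mean
identity of retained hits; the conserved-DNA fraction is the share of the
query covered by alignments above 90% identity.  Both directions are
computed and their mean reported.

AAI is the mean identity of best protein hits between two proteomes
(reciprocal best hits by default); because the two query directions can
disagree, the higher of the two directional values is kept.

GC3 is the G+C fraction at third codon positions, ambiguous bases excluded
from numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .model import StrainMetadata

# An aligner maps (query, subject) -> (identity fraction, coverage fraction
# of the query, aligned query span as 0-based half-open interval).
AlignerFn = Callable[[str, str], tuple[float, float, tuple[int, int]]]


def _make_nt_aligner() -> AlignerFn:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2

    def align(query: str, subject: str):
        alns = aligner.align(query, subject)
        try:
            best = alns[0]
        except IndexError:
            return 0.0, 0.0, (0, 0)
        counts = best.counts()
        aligned_cols = counts.identities + counts.mismatches + counts.gaps
        identity = counts.identities / aligned_cols if aligned_cols else 0.0
        qstart, qend = int(best.aligned[0][0][0]), int(best.aligned[0][-1][1])
        coverage = (qend - qstart) / len(query)
        return identity, coverage, (qstart, qend)

    return align


def _make_aa_aligner() -> AlignerFn:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1

    def align(query: str, subject: str):
        alns = aligner.align(query, subject)
        try:
            best = alns[0]
        except IndexError:
            return 0.0, 0.0, (0, 0)
        counts = best.counts()
        aligned_cols = counts.identities + counts.mismatches + counts.gaps
        identity = counts.identities / aligned_cols if aligned_cols else 0.0
        qstart, qend = int(best.aligned[0][0][0]), int(best.aligned[0][-1][1])
        coverage = (qend - qstart) / len(query)
        return identity, coverage, (qstart, qend)

    return align


@dataclass
class AniResult:
    ani: float                  # %, mean of the two directions
    conserved_dna: float        # %, mean of the two directions
    ani_ab: float
    ani_ba: float
    conserved_ab: float
    conserved_ba: float
    n_fragments_ab: int
    n_fragments_ba: int


def ani(
    genome_a: str,
    genome_b: str,
    fragment: int = 1020,
    min_identity: float = 0.3,
    min_coverage: float = 0.7,
    aligner: AlignerFn | None = None,
) -> AniResult:
    """Fragment-based ANI and conserved-DNA fraction between two genomes."""
    if len(genome_a) < fragment or len(genome_b) < fragment:
        raise ValueError(f"genomes must be at least one fragment ({fragment} bp) long")
    aligner = aligner or _make_nt_aligner()
    ani_ab, cons_ab, n_ab = _ani_oneway(genome_a, genome_b, fragment, min_identity, min_coverage, aligner)
    ani_ba, cons_ba, n_ba = _ani_oneway(genome_b, genome_a, fragment, min_identity, min_coverage, aligner)
    return AniResult(
        ani=(ani_ab + ani_ba) / 2.0,
        conserved_dna=(cons_ab + cons_ba) / 2.0,
        ani_ab=ani_ab, ani_ba=ani_ba,
        conserved_ab=cons_ab, conserved_ba=cons_ba,
        n_fragments_ab=n_ab, n_fragments_ba=n_ba,
    )


def _ani_oneway(
    query: str,
    subject: str,
    fragment: int,
    min_identity: float,
    min_coverage: float,
    aligner: AlignerFn,
) -> tuple[float, float, int]:
    subject_rc = str(Seq(subject).reverse_complement())
    identities = []
    conserved_bp = 0
    n_frag = len(query) // fragment  # tail shorter than one fragment is dropped
    for i in range(n_frag):
        frag = query[i * fragment:(i + 1) * fragment]
        fwd = aligner(frag, subject)
        rev = aligner(frag, subject_rc)
        identity, coverage, (qs, qe) = max(fwd, rev, key=lambda r: r[0] * r[1])
        if identity > min_identity and coverage >= min_coverage:
            identities.append(identity)
            if identity > 0.9:
                conserved_bp += qe - qs
    ani_pct = 100.0 * float(np.mean(identities)) if identities else 0.0
    conserved_pct = 100.0 * conserved_bp / len(query)
    return ani_pct, conserved_pct, len(identities)


@dataclass
class AaiResult:
    aai: float                  # %, max of the two directions
    aai_ab: float
    aai_ba: float
    pairs: list[tuple[str, str, float]]   # audit list from the winning direction


def aai(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    rbh: bool = True,
    min_identity: float = 0.3,
    min_coverage: float = 0.7,
    aligner: AlignerFn | None = None,
) -> AaiResult:
    """Average amino-acid identity; the higher directional value is kept."""
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    aligner = aligner or _make_aa_aligner()
    ab = _best_hits(proteome_a, proteome_b, min_identity, min_coverage, aligner)
    ba = _best_hits(proteome_b, proteome_a, min_identity, min_coverage, aligner)
    if rbh:
        recip_ab = [(q, s, i) for q, s, i in ab if any(q2 == s and s2 == q for q2, s2, _ in ba)]
        recip_ba = [(q, s, i) for q, s, i in ba if any(q2 == s and s2 == q for q2, s2, _ in ab)]
        ab, ba = recip_ab, recip_ba
    aai_ab = 100.0 * float(np.mean([i for _, _, i in ab])) if ab else 0.0
    aai_ba = 100.0 * float(np.mean([i for _, _, i in ba])) if ba else 0.0
    winner = ab if aai_ab >= aai_ba else ba
    return AaiResult(aai=max(aai_ab, aai_ba), aai_ab=aai_ab, aai_ba=aai_ba,
                     pairs=[(q, s, 100.0 * i) for q, s, i in winner])


def _best_hits(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    min_identity: float,
    min_coverage: float,
    aligner: AlignerFn,
) -> list[tuple[str, str, float]]:
    hits = []
    for qid, qseq in queries.items():
        best = None
        for sid, sseq in subjects.items():
            identity, coverage, _ = aligner(qseq, sseq)
            if identity > min_identity and coverage >= min_coverage:
                if best is None or identity > best[2]:
                    best = (qid, sid, identity)
        if best is not None:
            hits.append(best)
    return hits


def gc3(cds_sequences: Sequence[str]) -> float:
    """G+C fraction at third codon positions over a set of CDS sequences.

    Sequences are trimmed to whole codons (stop codon included); third
    positions with ambiguous bases are excluded from both numerator and
    denominator.  Invariant to the order of the sequences.
    """
    gc = 0
    total = 0
    for seq in cds_sequences:
        seq = seq.upper()
        if len(seq) < 3:
            raise ValueError("CDS shorter than one codon")
        thirds = seq[2:len(seq) - len(seq) % 3:3]
        for base in thirds:
            if base in "GC":
                gc += 1
                total += 1
            elif base in "AT":
                total += 1
    if total == 0:
        raise ValueError("no unambiguous third-codon positions")
    return gc / total


@dataclass
class PairwiseIdentity:
    strain_a: str
    strain_b: str
    ani: float | None = None
    conserved_dna: float | None = None
    aai: float | None = None
    identity_16s: float | None = None


def pair_table(
    identities: Sequence[PairwiseIdentity],
    metadata: StrainMetadata,
    aai_intra_clade_threshold: float = 80.0,
    aai_inter_sc_threshold: float = 65.0,
    s16_inter_sc_threshold: float = 98.0,
) -> pd.DataFrame:
    """Long-form pair table with taxonomic labels and descriptive flags.

    Each pair is labeled ``same_clade``, ``same_SC_diff_clade`` or
    ``diff_SC``; flags mark pairs crossing the descriptive AAI/16S
    thresholds (annotations only, no decision is taken on them).
    """
    rows = []
    for p in identities:
        clade_a, clade_b = (metadata.label(p.strain_a, "clade"), metadata.label(p.strain_b, "clade"))
        sc_a, sc_b = (metadata.label(p.strain_a, "sub_cluster"), metadata.label(p.strain_b, "sub_cluster"))
        if clade_a is not None and clade_a == clade_b:
            relation = "same_clade"
        elif sc_a is not None and sc_a == sc_b:
            relation = "same_SC_diff_clade"
        else:
            relation = "diff_SC"
        rows.append(
            {
                "strain_a": p.strain_a,
                "strain_b": p.strain_b,
                "relation": relation,
                "ani": p.ani,
                "conserved_dna": p.conserved_dna,
                "aai": p.aai,
                "identity_16s": p.identity_16s,
                "above_intra_clade_aai": (
                    p.aai is not None and relation == "same_clade"
                    and p.aai > aai_intra_clade_threshold
                ),
                "above_inter_sc_floor": (
                    p.aai is not None and p.identity_16s is not None
                    and p.aai > aai_inter_sc_threshold
                    and p.identity_16s > s16_inter_sc_threshold
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "strain_a", "strain_b", "relation", "ani", "conserved_dna",
            "aai", "identity_16s", "above_intra_clade_aai", "above_inter_sc_floor",
        ],
    )


def identity_16s(aligned_a: str, aligned_b: str) -> float:
    """Pairwise identity (%) from two prealigned 16S sequences.

    Columns where both sequences are gaps are excluded; other columns count
    toward the denominator.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned 16S sequences must have equal length")
    match = 0
    total = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in "-." and y in "-.":
            continue
        total += 1
        if x == y and x not in "-.":
            match += 1
    return 100.0 * match / total if total else 0.0
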