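"""Readers and writers for the standard formats the pipeline touches.

Dialects
--------
* Phyletic pattern: TSV, strains as rows, CLOG ids as header columns,
  integer copy counts in cells.
* Trees: newick with branch lengths; the caller declares the unit
  (``subs/site``, ``My`` or ``unitless``).  Trees must be rooted; an
  unrooted basal multifurcation is an error unless an outgroup is given.
* Genome annotations: GFF3, CLOG id carried in a named CDS attribute.
  Coordinates stay 1-based inclusive end to end.
* Core alignments: one aligned amino-acid FASTA per CLOG, headers are
  strain ids.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from gffutils.iterators import DataIterator

from .model import (
    AnnotatedGenome,
    CDSFeature,
    CoreAlignmentSet,
    EvoTree,
    FormatError,
    PhyleticPattern,
    ReconciliationError,
    StrainMetadata,
)

# ---------------------------------------------------------------------------
# Phyletic pattern
# ---------------------------------------------------------------------------


def read_phyletic_table(path: str | Path) -> PhyleticPattern:
    """Read a strains x CLOGs copy-count TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise FormatError("no strains in phyletic table (header only)")
    if df.shape[1] == 0:
        raise FormatError("no CLOG columns in phyletic table")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, val in enumerate(df[col]):
            try:
                counts[i, j] = int(val)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer cell {val!r} at strain {df.index[i]!r}, CLOG {col!r}"
                ) from None
    return PhyleticPattern(list(df.index), list(df.columns), counts)


def write_phyletic_table(pattern: PhyleticPattern, path: str | Path) -> None:
    df = pd.DataFrame(pattern.counts, index=pattern.strains, columns=pattern.clogs)
    df.index.name = "strain"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_tree(
    path: str | Path,
    unit: str,
    outgroup: str | None = None,
    metadata: StrainMetadata | None = None,
) -> EvoTree:
    """Read a rooted newick tree with a declared branch-length unit."""
    with open(path) as fh:
        newick = fh.read()
    tree = EvoTree.from_newick(newick, unit, outgroup=outgroup)
    if metadata is not None:
        missing = [l for l in tree.leaf_ids if l not in metadata.table]
        if missing:
            raise ReconciliationError(f"tree leaves absent from metadata: {missing}")
    return tree


def write_tree(tree: EvoTree, path: str | Path, internal_labels: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(internal_labels=internal_labels) + "\n")


# ---------------------------------------------------------------------------
# GFF3 genome annotations
# ---------------------------------------------------------------------------


def read_gff(path: str | Path, clog_attr: str = "clog") -> AnnotatedGenome:
    """Read CDS features of a single-replicon genome from GFF3.

    The CLOG assignment is taken from the CDS attribute named ``clog_attr``;
    features lacking it are retained with a null CLOG (with a warning).
    Genome length comes from the ``##sequence-region`` pragma when present,
    otherwise from the furthest feature end.  A ``gained`` attribute with
    value ``true`` marks genes acquired on the terminal branch; a ``partial``
    attribute with value ``true`` clears the full-length flag.
    """
    strain = None
    length = None
    circular = False
    features: list[CDSFeature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                strain, length = parts[1], int(parts[3])
            elif line.startswith("#!circular"):
                circular = line.split()[-1].lower() == "true"
    for feat in DataIterator(str(path)):
        if feat.featuretype != "CDS":
            continue
        if strain is None:
            strain = feat.seqid
        if feat.end < feat.start:
            raise FormatError(f"CDS end {feat.end} < start {feat.start}")
        clog = feat.attributes.get(clog_attr, [None])[0]
        if clog is None:
            warnings.warn(
                f"CDS at {feat.start}..{feat.end} lacks attribute {clog_attr!r}; "
                "retained with null CLOG",
                stacklevel=2,
            )
        gained = feat.attributes.get("gained", ["false"])[0].lower() == "true"
        partial = feat.attributes.get("partial", ["false"])[0].lower() == "true"
        features.append(
            CDSFeature(feat.start, feat.end, feat.strand or ".", clog,
                       full_length=not partial, gained=gained)
        )
    if strain is None:
        raise FormatError(f"no CDS features and no sequence-region pragma in {path}")
    if length is None:
        length = max((f.end for f in features), default=0)
    return AnnotatedGenome(strain, length, features, circular=circular)


def write_gff(genome: AnnotatedGenome, path: str | Path, clog_attr: str = "clog") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.strain} 1 {genome.length}\n")
        if genome.circular:
            fh.write("#!circular true\n")
        for i, f in enumerate(genome.features, start=1):
            attrs = [f"ID=cds{i:05d}"]
            if f.clog is not None:
                attrs.append(f"{clog_attr}={f.clog}")
            if f.gained:
                attrs.append("gained=true")
            if not f.full_length:
                attrs.append("partial=true")
            fh.write(
                f"{genome.strain}\tpicoevo\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t"
                + ";".join(attrs) + "\n"
            )


# ---------------------------------------------------------------------------
# Core alignments
# ---------------------------------------------------------------------------


def read_alignments(directory: str | Path, suffixes: tuple[str, ...] = (".faa", ".fasta", ".fa")) -> CoreAlignmentSet:
    """Read one aligned FASTA per CLOG from a directory; file stem = CLOG id."""
    directory = Path(directory)
    alignments: dict[str, dict[str, str]] = {}
    for name in sorted(os.listdir(directory)):
        p = directory / name
        if p.suffix not in suffixes:
            continue
        clog = p.stem
        aln: dict[str, str] = {}
        for rec in SeqIO.parse(str(p), "fasta"):
            if rec.id in aln:
                raise FormatError(f"duplicate strain {rec.id!r} in alignment {clog}")
            aln[rec.id] = str(rec.seq)
        if not aln:
            raise FormatError(f"empty alignment file {p}")
        alignments[clog] = aln
    if not alignments:
        raise FormatError(f"no alignment files found under {directory}")
    return CoreAlignmentSet(alignments)


def write_alignments(alignments: CoreAlignmentSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for clog in alignments.clog_ids:
        with open(directory / f"{clog}.faa", "w") as fh:
            for strain in sorted(alignments.alignments[clog]):
                fh.write(f">{strain}\n{alignments.alignments[clog][strain]}\n")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> StrainMetadata:
    """Read a strain metadata TSV (first column strain id; label columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    table = {
        str(strain): {k: (None if pd.isna(v) else str(v)) for k, v in row.items()}
        for strain, row in df.iterrows()
    }
    return StrainMetadata(table)


def write_metadata(metadata: StrainMetadata, path: str | Path) -> None:
    df = pd.DataFrame.from_dict(metadata.table, orient="index")
    df.index.name = "strain"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Cross-file validation
# ---------------------------------------------------------------------------


def validate(
    pattern: PhyleticPattern | None = None,
    tree: EvoTree | None = None,
    metadata: StrainMetadata | None = None,
    genomes: list[AnnotatedGenome] | None = None,
) -> list[str]:
    """Cross-check strain and CLOG sets across companion inputs.

    Returns a list of human-readable problems (empty = consistent).
    """
    problems: list[str] = []
    if pattern is not None and metadata is not None:
        missing = [s for s in pattern.strains if s not in metadata.table]
        if missing:
            problems.append(f"strains in pattern but not metadata: {missing}")
    if pattern is not None and tree is not None:
        pat = set(pattern.strains)
        leaves = set(tree.leaf_ids)
        if leaves - pat:
            problems.append(f"tree leaves absent from pattern: {sorted(leaves - pat)}")
        if pat - leaves:
            problems.append(f"pattern strains absent from tree: {sorted(pat - leaves)}")
    if pattern is not None and genomes is not None:
        known = set(pattern.clogs)
        for g in genomes:
            extra = g.clogs - known
            if extra:
                problems.append(
                    f"{g.strain}: {len(extra)} CLOG ids not in pattern "
                    f"(e.g. {sorted(extra)[:3]})"
                )
    return problems
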