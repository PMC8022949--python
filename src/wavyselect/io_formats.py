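"""Readers and writers for the standard formats the toolkit touches.

FASTA/FASTQ parsing goes through :mod:`Bio.SeqIO`; GFF3 rows are read with
pandas. All coordinates are converted to 0-based half-open intervals at the
boundary, so downstream arithmetic is BED-compatible.

The cluster-file dialect is the Carnac-LR convention: one cluster per
non-empty line, whitespace-separated tokens that are either 0-based read
indices (in FASTQ order) or read names.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Literal, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "LongRead",
    "ReadCluster",
    "FeatureRecord",
    "read_fastx",
    "write_fasta",
    "read_cluster_file",
    "read_gff3",
]


@dataclass(frozen=True)
class LongRead:
    """A single sequencing read (cDNA or genomic).

    Attributes
    ----------
    id : str
        Read name, unique within a read set.
    sequence : str
        Uppercase nucleotides over ``{A, C, G, T, N}``.
    quality : str, optional
        Per-base quality string (same length as ``sequence``) when the read
        came from FASTQ.
    """

    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadCluster:
    """A set of read ids putatively originating from one gene."""

    cluster_id: int
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id}: empty member list")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"cluster {self.cluster_id}: duplicate member ids")


@dataclass(frozen=True)
class FeatureRecord:
    """An annotated interval (gene or repeat), 0-based half-open."""

    chrom: str
    start: int
    end: int
    track: Literal["gene", "repeat"]

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: str | Path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped[0] == ">":
                return "fasta"
            if stripped[0] == "@":
                return "fastq"
            raise ValueError(
                f"{path}: not FASTA/FASTQ (first record starts with {stripped[0]!r})"
            )
    raise ValueError(f"{path}: no records")


def read_fastx(path: str | Path) -> list[LongRead]:
    """Read a FASTA or FASTQ file (optionally gzipped) into LongReads.

    The format is sniffed from the first non-blank character. Sequences are
    uppercased; FASTQ qualities are preserved; input order is preserved.

    Raises
    ------
    ValueError
        On an empty file, a duplicate read id, or a FASTQ record whose
        quality length differs from its sequence length.
    """
    fmt = _sniff_format(path)
    reads: list[LongRead] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate read id {rec.id!r}")
            seen.add(rec.id)
            quality = None
            if fmt == "fastq":
                phred = rec.letter_annotations["phred_quality"]
                quality = "".join(chr(q + 33) for q in phred)
            reads.append(LongRead(rec.id, str(rec.seq).upper(), quality))
    if not reads:
        raise ValueError(f"{path}: no records")
    return reads


def write_fasta(reads: Sequence[LongRead], path: str | Path, wrap: int = 80) -> None:
    """Write reads as FASTA in input order.

    Parameters
    ----------
    wrap : int
        Maximum sequence-line width; 0 writes one line per record.
    """
    if wrap < 0:
        raise ValueError("wrap must be >= 0")
    with _open_text(path, "wt") as fh:
        for read in reads:
            if not read.sequence:
                raise ValueError(f"read {read.id!r}: empty sequence")
            fh.write(f">{read.id}\n")
            if wrap == 0:
                fh.write(read.sequence + "\n")
            else:
                for i in range(0, read.length, wrap):
                    fh.write(read.sequence[i : i + wrap] + "\n")


def read_cluster_file(
    path: str | Path, reads: Optional[Sequence[LongRead]] = None
) -> list[ReadCluster]:
    """Read a Carnac-LR-style cluster file.

    One cluster per non-empty line; tokens on a line are either all integer
    0-based indices into ``reads`` (resolved to read ids when ``reads`` is
    supplied) or read-name strings. ``cluster_id`` is the 0-based rank of the
    line among non-empty lines.
    """
    id_set = {r.id for r in reads} if reads is not None else None
    clusters: list[ReadCluster] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(set(tokens)) != len(tokens):
                raise ValueError(f"{path}:{lineno}: duplicate token within cluster")
            all_int = all(t.lstrip("-").isdigit() for t in tokens)
            if all_int and reads is not None:
                members = []
                for t in tokens:
                    idx = int(t)
                    if not (0 <= idx < len(reads)):
                        raise ValueError(
                            f"{path}:{lineno}: read index {idx} out of range "
                            f"(have {len(reads)} reads)"
                        )
                    members.append(reads[idx].id)
            else:
                if id_set is not None:
                    for t in tokens:
                        if t not in id_set:
                            raise ValueError(
                                f"{path}:{lineno}: read name {t!r} not found"
                            )
                members = list(tokens)
            clusters.append(ReadCluster(len(clusters), tuple(members)))
    return clusters


_GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_gff3(
    path: str | Path,
    gene_types: Iterable[str] = ("gene",),
    repeat_types: Iterable[str] = ("match", "repeat_region"),
) -> list[FeatureRecord]:
    """Read gene and repeat features from a GFF3 annotation.

    Rows whose type column is in ``gene_types`` map to the gene track, rows
    in ``repeat_types`` to the repeat track; all other rows are dropped. The
    1-based inclusive GFF3 coordinates are converted to 0-based half-open.
    """
    gene_types = set(gene_types)
    repeat_types = set(repeat_types)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=_GFF3_COLUMNS,
            dtype=str,
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        return []
    records: list[FeatureRecord] = []
    for lineno, row in df.iterrows():
        track: Literal["gene", "repeat"]
        if row["type"] in gene_types:
            track = "gene"
        elif row["type"] in repeat_types:
            track = "repeat"
        else:
            continue
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise ValueError(f"{path}: non-integer coordinates: {exc}") from None
        if end < start:
            raise ValueError(f"{path}: end < start at data row {lineno + 1}")
        records.append(FeatureRecord(row["seqid"], start - 1, end, track))
    return records
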