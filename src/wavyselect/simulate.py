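"""Seeded generators for synthetic fixtures.

Three generators cover everything the toolkit consumes:

* multi-isoform transcriptomes, where isoforms of one gene share their
  3' end (suffixes of a common gene sequence, as oligo-dT-primed cDNA
  implies) and differ in length by at least a configurable separation;
* Nanopore-like cDNA read clusters: a full-length mode per isoform plus
  5'-truncated reads, with indel-rich per-base errors;
* shotgun genomic reads at fixed coverage from a random genome, sampling
  both strands.

Every generator is a pure function of its parameters including the seed, so
test fixtures and acceptance runs are reproducible. The error process is
deliberately simple (independent per-base substitution/insertion/deletion);
it does not model homopolymer bias or realistic quality strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _nt
from .io_formats import LongRead

__all__ = [
    "SimParams",
    "Transcript",
    "simulate_transcriptome",
    "simulate_cluster_reads",
    "simulate_genome_and_reads",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the cDNA cluster simulator.

    Error-rate defaults total 5% with balanced insertions and deletions, so
    the full-length read-length mode sits at the isoform length.
    """

    seed: int = 42
    n_genes: int = 10
    isoforms_per_gene: tuple[int, int] = (1, 3)
    isoform_length_range: tuple[int, int] = (800, 3000)
    min_isoform_separation: int = 300
    reads_per_cluster: int = 100
    full_length_prob: float = 0.7
    truncation_model: str = "uniform_5prime"
    sub_rate: float = 0.03
    ins_rate: float = 0.01
    del_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("full_length_prob", "sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_isoform_separation < 0:
            raise ValueError("min_isoform_separation must be >= 0")
        if self.n_genes < 0 or self.reads_per_cluster < 0:
            raise ValueError("counts must be >= 0")
        if self.truncation_model != "uniform_5prime":
            raise ValueError(f"unknown truncation model {self.truncation_model!r}")


@dataclass(frozen=True)
class Transcript:
    id: str
    sequence: str
    gene_id: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return _nt.decode(rng.integers(0, 4, size=n, dtype=np.uint8))


def _isoform_lengths(
    rng: np.random.Generator, n_iso: int, lo: int, hi: int, sep: int
) -> list[int]:
    # sample with guaranteed pairwise separation: draw in a range shrunk by
    # the total separation, sort, then re-add cumulative offsets
    span = hi - lo - (n_iso - 1) * sep
    if span < 0:
        raise ValueError(
            f"isoform_length_range {lo}..{hi} too narrow for {n_iso} isoforms "
            f"separated by >= {sep} bp"
        )
    base = np.sort(rng.integers(0, span + 1, size=n_iso))
    return [int(lo + b + i * sep) for i, b in enumerate(base)]


def simulate_transcriptome(params: SimParams) -> list[Transcript]:
    """Generate a multi-gene, multi-isoform transcriptome.

    Isoform ids are ``g<gene>_i<rank>``; within a gene, isoforms are the
    3'-terminal suffixes of one gene sequence, so all isoform lengths are
    pairwise at least ``min_isoform_separation`` apart.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.isoform_length_range
    iso_lo, iso_hi = params.isoforms_per_gene
    transcripts: list[Transcript] = []
    for g in range(params.n_genes):
        n_iso = int(rng.integers(iso_lo, iso_hi + 1))
        lengths = _isoform_lengths(rng, n_iso, lo, hi, params.min_isoform_separation)
        gene_seq = _random_sequence(rng, max(lengths))
        for i, length in enumerate(lengths):
            transcripts.append(Transcript(f"g{g}_i{i}", gene_seq[-length:], f"g{g}"))
    return transcripts


def _apply_errors(
    seq: str,
    rng: np.random.Generator,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
) -> str:
    codes = _nt.encode(seq)
    n = codes.size
    if del_rate > 0:
        codes = codes[rng.random(n) >= del_rate]
    n = codes.size
    if sub_rate > 0:
        hit = rng.random(n) < sub_rate
        # shift by 1..3 so a substitution always changes the base
        codes = codes.copy()
        codes[hit] = (codes[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    if ins_rate > 0:
        pos = np.nonzero(rng.random(n) < ins_rate)[0]
        codes = np.insert(
            codes, pos, rng.integers(0, 4, size=pos.size, dtype=np.uint8)
        )
    return _nt.decode(codes)


def simulate_cluster_reads(
    transcripts: Sequence[Transcript],
    params: SimParams,
    seed: Optional[int] = None,
) -> tuple[list[LongRead], list[bool]]:
    """Simulate one gene's worth of clustered cDNA reads with truth labels.

    ``round(full_length_prob * reads_per_cluster)`` reads are full-length,
    dealt round-robin across the gene's isoforms so every isoform receives
    its share; the remainder are 5'-truncated (the cut point is uniform over
    10-90% of the isoform length, keeping the 3' end). Errors are applied
    after truncation. Returns reads plus a parallel is-full-length flag list.
    """
    if not transcripts:
        raise ValueError("need at least one transcript")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.reads_per_cluster
    n_full = round(params.full_length_prob * n)
    gene = transcripts[0].gene_id
    reads: list[LongRead] = []
    labels: list[bool] = []
    for j in range(n):
        full = j < n_full
        if full:
            iso = transcripts[j % len(transcripts)]
            template = iso.sequence
        else:
            iso = transcripts[int(rng.integers(0, len(transcripts)))]
            cut = rng.uniform(0.1, 0.9)
            template = iso.sequence[int(cut * iso.length):]
        seq = _apply_errors(
            template, rng, params.sub_rate, params.ins_rate, params.del_rate
        )
        reads.append(LongRead(f"{gene}_r{j}", seq))
        labels.append(full)
    return reads, labels


def simulate_genome_and_reads(
    genome_length: int,
    coverage: float,
    read_length: int,
    sub_rate: float = 0.0,
    seed: int = 42,
) -> tuple[str, list[LongRead]]:
    """Random genome plus ``ceil(genome_length * coverage / read_length)``
    shotgun reads of fixed length, uniform start positions, both strands.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_length > genome_length:
        raise ValueError("read_length must be <= genome_length")
    rng = np.random.default_rng(seed)
    genome_codes = rng.integers(0, 4, size=genome_length, dtype=np.uint8)
    n_reads = math.ceil(genome_length * coverage / read_length)
    starts = rng.integers(0, genome_length - read_length + 1, size=n_reads)
    mat = genome_codes[starts[:, None] + np.arange(read_length)]
    minus = rng.random(n_reads) < 0.5
    mat[minus] = (3 - mat[minus])[:, ::-1]
    if sub_rate > 0:
        hit = rng.random(mat.shape) < sub_rate
        mat[hit] = (mat[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    ascii_mat = _nt._DECODE[mat]
    seqs = ascii_mat.view(f"S{read_length}").ravel().astype("U")
    reads = [LongRead(f"r{i}", s) for i, s in enumerate(seqs)]
    return _nt.decode(genome_codes), reads
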