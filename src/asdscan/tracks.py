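"""End-assigned, stranded per-nucleotide coverage tracks.

Ribosome-profiling footprints are assigned to the 3'-most base of each
alignment (in read orientation) and RNA-seq reads to the 5'-most base, giving
single-nucleotide tracks per (replicon, strand).  Tracks carry raw counts
until explicitly converted to rpm (reads per million mapped reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawRead",
    "AlignmentRecord",
    "CoverageTrack",
    "TrimResult",
    "LinkerSpec",
    "collapse_duplicates",
    "preprocess_read",
    "build_coverage",
    "rpm_normalize",
    "read_bed",
]

STRANDS = ("+", "-")


@dataclass(frozen=True)
class RawRead:
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("read sequence must be non-empty")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError("quality string length must match sequence length")


@dataclass(frozen=True)
class AlignmentRecord:
    """A collapsed alignment: 0-based half-open interval, weight >= 1."""

    replicon: str
    strand: str
    start: int
    end: int
    weight: int = 1

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.weight < 1:
            raise ValueError("weight must be >= 1")


@dataclass
class CoverageTrack:
    """Per-nucleotide signal per (replicon, strand).

    ``data`` maps (replicon, strand) -> float vector of replicon length;
    ``total_mapped`` is the sum of raw assigned counts and is preserved by
    rpm normalization so densities remain interconvertible.
    """

    data: dict[tuple[str, str], np.ndarray]
    lengths: dict[str, int]
    total_mapped: float
    normalized: bool = False

    def get(self, replicon: str, strand: str) -> np.ndarray:
        key = (replicon, strand)
        if key not in self.data:
            self.data[key] = np.zeros(self.lengths[replicon])
        return self.data[key]

    def values(
        self, replicon: str, strand: str, start: int, end: int
    ) -> np.ndarray:
        """Signal over a 0-based half-open interval, in transcript orientation."""
        vec = self.get(replicon, strand)[start:end]
        return vec[::-1] if strand == "-" else vec

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            data={k: v.copy() for k, v in self.data.items()},
            lengths=dict(self.lengths),
            total_mapped=self.total_mapped,
            normalized=self.normalized,
        )

    @classmethod
    def zeros(cls, lengths: dict[str, int]) -> "CoverageTrack":
        data = {
            (rep, strand): np.zeros(n)
            for rep, n in lengths.items()
            for strand in STRANDS
        }
        return cls(data=data, lengths=dict(lengths), total_mapped=0.0)


def collapse_duplicates(
    reads: Iterable[RawRead],
) -> list[tuple[RawRead, int]]:
    """Collapse identical sequences (UMI included) to one read + multiplicity.

    First-occurrence order is preserved and the first read's qualities are
    kept; the multiplicities sum to the input count.
    """
    seen: dict[str, int] = {}
    firsts: list[RawRead] = []
    for read in reads:
        if read.seq in seen:
            seen[read.seq] += 1
        else:
            seen[read.seq] = 1
            firsts.append(read)
    return [(read, seen[read.seq]) for read in firsts]


@dataclass(frozen=True)
class LinkerSpec:
    """3' linker layout: a 6-nt UMI immediately 5' of a constant sequence."""

    constant: str = "CACTCGGGCACCAAGGAC"
    umi3_len: int = 6
    max_mismatches: int = 1


@dataclass(frozen=True)
class TrimResult:
    insert: str | None
    umi5: str = ""
    umi3: str = ""
    rejected: str | None = None  # "no_linker" | "too_short"

    @property
    def ok(self) -> bool:
        return self.rejected is None


def _find_linker(seq: str, linker: str, max_mismatches: int) -> int:
    k = len(linker)
    for pos in range(0, len(seq) - k + 1):
        mism = 0
        for a, b in zip(seq[pos : pos + k], linker):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            return pos
    return -1


def preprocess_read(
    read: RawRead,
    linker: LinkerSpec = LinkerSpec(),
    umi5_len: int = 4,
    min_insert: int = 15,
) -> TrimResult:
    """Strip the 3' linker + UMI and the 5' UMI from a raw read.

    The read layout is ``[umi5][insert][umi3][constant linker]``; the constant
    linker is located by leftmost match with at most ``max_mismatches``
    mismatches.  Inserts shorter than ``min_insert`` after trimming are
    rejected with reason ``"too_short"``; reads with no linker with
    ``"no_linker"``.
    """
    pos = _find_linker(read.seq, linker.constant, linker.max_mismatches)
    if pos < 0:
        return TrimResult(None, rejected="no_linker")
    insert_end = pos - linker.umi3_len
    if insert_end - umi5_len < min_insert:
        return TrimResult(None, rejected="too_short")
    return TrimResult(
        insert=read.seq[umi5_len:insert_end],
        umi5=read.seq[:umi5_len],
        umi3=read.seq[insert_end:pos],
    )


def _assigned_position(aln: AlignmentRecord, end_mode: str) -> int:
    # the 3' end of a minus-strand alignment is the interval's lowest coordinate
    if end_mode == "three_prime":
        return aln.end - 1 if aln.strand == "+" else aln.start
    if end_mode == "five_prime":
        return aln.start if aln.strand == "+" else aln.end - 1
    raise ValueError(f"unknown end mode {end_mode!r}")


def build_coverage(
    alignments: Iterable[AlignmentRecord],
    genome_lengths: dict[str, int],
    end_mode: str,
    blacklist: Sequence[tuple[str, int, int]] = (),
) -> CoverageTrack:
    """End-assign alignments into a raw-count coverage track.

    Each alignment contributes its weight at exactly one nucleotide (3'-most
    for footprints, 5'-most for RNA-seq, strand-aware).  Alignments
    overlapping a ``blacklist`` interval (replicon, start, end; 0-based
    half-open; strand-blind) are dropped and not counted in ``total_mapped``.
    """
    track = CoverageTrack.zeros(genome_lengths)
    total = 0.0
    n_blacklisted = 0
    for aln in alignments:
        if aln.replicon not in genome_lengths:
            raise ValueError(f"unknown replicon {aln.replicon!r}")
        if aln.start < 0 or aln.end > genome_lengths[aln.replicon]:
            raise ValueError(
                f"alignment [{aln.start}, {aln.end}) outside replicon "
                f"{aln.replicon!r} (length {genome_lengths[aln.replicon]})"
            )
        if any(
            rep == aln.replicon and aln.start < bend and bstart < aln.end
            for rep, bstart, bend in blacklist
        ):
            n_blacklisted += aln.weight
            continue
        pos = _assigned_position(aln, end_mode)
        track.get(aln.replicon, aln.strand)[pos] += aln.weight
        total += aln.weight
    track.total_mapped = total
    track.n_blacklisted = n_blacklisted  # type: ignore[attr-defined]
    return track


def rpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Convert a raw-count track to reads per million mapped reads."""
    if track.normalized:
        raise ValueError("track is already rpm-normalized")
    if track.total_mapped <= 0:
        raise ValueError("cannot normalize a track with total_mapped == 0")
    out = track.copy()
    scale = 1e6 / track.total_mapped
    for key in out.data:
        out.data[key] = out.data[key] * scale
    out.normalized = True
    return out


def read_bed(path: str) -> list[AlignmentRecord]:
    """Read BED6 alignment records (score column = collapsed multiplicity)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return [
        AlignmentRecord(
            replicon=row.chrom,
            strand=row.strand,
            start=int(row.start),
            end=int(row.end),
            weight=max(1, int(row.score)) if not pd.isna(row.score) else 1,
        )
        for row in df.itertuples()
    ]
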