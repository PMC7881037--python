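"""Sequence and interval I/O plus synthetic-genome simulation.

Coordinates are 0-based, half-open everywhere. Soft-masked (lower-case)
input is upper-cased and treated as ordinary sequence; IUPAC ambiguity
codes other than N are rejected so that unexpected assemblies fail loudly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


class FastaError(Exception):
    """Base class for FASTA parsing problems."""


class MissingFileError(FastaError):
    """Input path does not exist."""


class EmptySequenceError(FastaError):
    """A record has a header but no sequence."""


class AlphabetError(FastaError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class MalformedFastaError(FastaError):
    """File does not start with a '>' header line."""


class IntervalError(ValueError):
    """An interval violates start < end or overlap constraints."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: disallowed characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, revcomp(self.sequence))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class IntervalSet:
    """Sorted, disjoint 0-based half-open intervals on one contig."""

    contig: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def covered_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def __contains__(self, pos: int) -> bool:
        import bisect

        i = bisect.bisect_right(self.intervals, (pos, float("inf"))) - 1
        return i >= 0 and self.intervals[i][0] <= pos < self.intervals[i][1]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.intervals)


def merge_intervals(
    raw: Iterable[tuple[int, int]], contig: str = ""
) -> IntervalSet:
    """Merge raw (start, end) pairs into a sorted, disjoint IntervalSet.

    Touching intervals ([0, 5) and [5, 9)) are coalesced; per-position
    membership is preserved exactly. Raises :class:`IntervalError` on any
    interval with ``start >= end``.
    """
    pairs = sorted(raw)
    merged: list[tuple[int, int]] = []
    for s, e in pairs:
        if s >= e:
            raise IntervalError(f"interval ({s}, {e}) has start >= end")
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return IntervalSet(contig, merged)


def interval_union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    if a.contig != b.contig:
        raise IntervalError("union across different contigs")
    return merge_intervals(list(a) + list(b), a.contig)


def interval_intersection(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Positions covered by both sets (two-pointer sweep over sorted runs)."""
    if a.contig != b.contig:
        raise IntervalError("intersection across different contigs")
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a.intervals) and j < len(b.intervals):
        s = max(a.intervals[i][0], b.intervals[j][0])
        e = min(a.intervals[i][1], b.intervals[j][1])
        if s < e:
            out.append((s, e))
        if a.intervals[i][1] < b.intervals[j][1]:
            i += 1
        else:
            j += 1
    return IntervalSet(a.contig, out)


def interval_difference(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Positions covered by ``a`` but not ``b``."""
    if a.contig != b.contig:
        raise IntervalError("difference across different contigs")
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a.intervals:
        cur = s
        while j < len(b.intervals) and b.intervals[j][1] <= cur:
            j += 1
        k = j
        while k < len(b.intervals) and b.intervals[k][0] < e:
            bs, be = b.intervals[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return IntervalSet(a.contig, out)


# ---------------------------------------------------------------------------
# FASTA / BED I/O
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream SequenceRecords from a (possibly gzipped) FASTA file.

    Sequences are upper-cased; the invariants of :class:`SequenceRecord`
    (alphabet, non-empty) are enforced per record as it is yielded.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    with _open_maybe_gzip(path) as handle:
        first = handle.readline()
        if not first.startswith(">"):
            raise MalformedFastaError(f"{path}: first line is not a '>' header")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise EmptySequenceError(f"record {rec.id!r} has empty sequence")
            yield SequenceRecord(rec.id, seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Load all records of a FASTA file into memory."""
    return list(iter_fasta(path))


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                out.write(rec.sequence[i : i + width] + "\n")


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write a 3-column BED (contig, start, end), 0-based half-open."""
    with open(path, "w") as out:
        for s, e in intervals:
            out.write(f"{intervals.contig}\t{s}\t{e}\n")


def read_bed(path: str | Path) -> IntervalSet:
    """Read a single-contig BED3 file back into an IntervalSet."""
    contig = ""
    pairs: list[tuple[int, int]] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            c, s, e = line.split("\t")[:3]
            if contig and c != contig:
                raise IntervalError("read_bed supports single-contig files")
            contig = c
            pairs.append((int(s), int(e)))
    return merge_intervals(pairs, contig)


# ---------------------------------------------------------------------------
# Synthetic genome simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSimSpec:
    """Parameters for a seeded random genome: length, GC content, N runs."""

    length: int
    gc_fraction: float = 0.41
    n_runs: tuple[tuple[int, int], ...] = ()
    seed: int = 0
    id: str = "sim"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        runs = sorted(self.n_runs)
        prev_end = 0
        for start, run_len in runs:
            if start < 0 or start + run_len > self.length:
                raise IntervalError(f"N run ({start}, len {run_len}) outside genome")
            if start < prev_end:
                raise IntervalError("overlapping N runs")
            prev_end = start + run_len


def simulate_genome(spec: GenomeSimSpec) -> SequenceRecord:
    """Draw an i.i.d. genome at the requested GC content, with N stretches.

    Non-N bases are sampled independently with P(G) = P(C) = gc/2 and
    P(A) = P(T) = (1 - gc)/2; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = rng.choice(bases, size=spec.length, p=probs)
    for start, run_len in spec.n_runs:
        arr[start : start + run_len] = ord("N")
    return SequenceRecord(spec.id, arr.tobytes().decode("ascii"))
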