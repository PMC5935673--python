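"""Desk-scale short-read alignment.

Two alignment modes, replacing a full genome aligner at toy scale:

* mismatch-tolerant alignment of small RNAs to transposon consensus
  sequences (default up to two mismatches), reporting every placement in
  the read's best (minimum-mismatch) stratum on either strand of any
  family;
* exact (zero-mismatch) genome alignment that counts the total number of
  equally good placements genome-wide (``n_hits``) so downstream analyses
  can restrict to uniquely mapping reads.

Both are index-accelerated but contractually identical to an exhaustive
scan over all positions x strands x targets: the consensus aligner uses
pigeonhole seeding (a read with at most ``m`` mismatches contains an exact
copy of one of ``m+1`` read chunks), the genome aligner a fixed-length
prefix seed verified by full string comparison.  ``N`` never matches, in
read or reference.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .io_formats import GenomicInterval, Read, revcomp


class AlignmentRecord(NamedTuple):
    """One placement of a read on a target's forward strand.

    ``pos`` is the 0-based leftmost coordinate of the aligned span on the
    target forward strand regardless of ``strand``; ``n_hits`` is the number
    of equally good (minimum-mismatch) placements across the whole target
    set for this read.
    """

    read_id: str
    target: str
    pos: int
    strand: str
    mismatches: int
    n_hits: int
    length: int


def _mismatch_count(a: str, b: str, max_mm: int) -> int:
    """Hamming distance with early abort; any N counts as a mismatch."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > max_mm:
                return mm
    return mm


class _SeedIndex:
    """Exact-substring index over a set of named sequences.

    Lazily builds one hash table per requested seed length, mapping every
    substring of that length to its (target, position) occurrences.
    """

    def __init__(self, targets: dict[str, str]):
        self.targets = {name: seq.upper() for name, seq in targets.items()}
        self._by_length: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _table(self, k: int) -> dict[str, list[tuple[str, int]]]:
        table = self._by_length.get(k)
        if table is None:
            table = defaultdict(list)
            for name, seq in self.targets.items():
                for i in range(len(seq) - k + 1):
                    table[seq[i:i + k]].append((name, i))
            self._by_length[k] = table
        return table

    def candidates(self, query: str, max_mm: int) -> set[tuple[str, int]]:
        """Candidate (target, pos) placements of ``query`` with <= max_mm
        mismatches, by pigeonhole over max_mm + 1 chunks.  The candidate set
        is a superset of all true placements; each still needs verification.
        """
        n_chunks = max_mm + 1
        length = len(query)
        if length < n_chunks:
            raise ValueError(f"read of length {length} too short for {max_mm} mismatches")
        bounds = [round(i * length / n_chunks) for i in range(n_chunks + 1)]
        out: set[tuple[str, int]] = set()
        for i in range(n_chunks):
            lo, hi = bounds[i], bounds[i + 1]
            for name, pos in self._table(hi - lo).get(query[lo:hi], ()):
                start = pos - lo
                if start >= 0 and start + length <= len(self.targets[name]):
                    out.add((name, start))
        return out


def _best_stratum_hits(index: _SeedIndex, read: Read, max_mm: int
                       ) -> list[tuple[str, int, str, int]]:
    """All (target, pos, strand, mm) placements in the read's minimum-mismatch
    stratum, provided that minimum is <= max_mm."""
    hits: list[tuple[str, int, str, int]] = []
    best = max_mm
    for strand, query in (("+", read.seq), ("-", revcomp(read.seq))):
        for target, pos in index.candidates(query, max_mm):
            ref = index.targets[target][pos:pos + len(query)]
            mm = _mismatch_count(query, ref, best)
            if mm <= best:
                if mm < best:
                    hits = [h for h in hits if h[3] == mm]
                    best = mm
                hits.append((target, pos, strand, mm))
    return [h for h in hits if h[3] == best]


def align_consensus(reads: Iterable[Read], consensus: dict[str, str],
                    max_mm: int = 2) -> list[AlignmentRecord]:
    """Align reads to transposon consensus sequences permitting mismatches.

    For each read, reports every placement (both strands, any family)
    achieving the read's minimum mismatch count, provided that minimum is
    at most ``max_mm``.  A read may align to several families; reads with
    no placement at ``max_mm`` simply produce no records.
    """
    index = _SeedIndex(consensus)
    records: list[AlignmentRecord] = []
    for read in reads:
        hits = _best_stratum_hits(index, read, max_mm)
        n = len(hits)
        records.extend(
            AlignmentRecord(read.id, target, pos, strand, mm, n, len(read.seq))
            for target, pos, strand, mm in hits
        )
    return records


class GenomeIndex:
    """Prefix-seed index for exact genome alignment, reusable across libraries."""

    def __init__(self, genome: dict[str, str], seed_len: int = 12):
        self.seed_len = seed_len
        self.chroms = {name: seq.upper() for name, seq in genome.items()}
        table: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.chroms.items():
            for i in range(len(seq) - seed_len + 1):
                table[seq[i:i + seed_len]].append((name, i))
        self.table = table

    def exact_hits(self, query: str) -> list[tuple[str, int]]:
        """All exact placements of ``query`` on the forward strands."""
        if len(query) < self.seed_len:
            candidates = [
                (name, i)
                for name, seq in self.chroms.items()
                for i in range(len(seq) - len(query) + 1)
            ]
        else:
            candidates = self.table.get(query[:self.seed_len], [])
        hits = []
        for name, pos in candidates:
            ref = self.chroms[name][pos:pos + len(query)]
            if len(ref) == len(query) and _mismatch_count(query, ref, 0) == 0:
                hits.append((name, pos))
        return hits


def align_genome_unique(reads: Iterable[Read],
                        genome: dict[str, str] | GenomeIndex,
                        seed_len: int = 12) -> list[AlignmentRecord]:
    """Exact (0-mismatch) genome alignment carrying genome-wide hit counts.

    Every exact placement on either strand is reported with ``n_hits`` equal
    to the total number of such placements; downstream consumers filter
    ``n_hits == 1`` to keep uniquely mapping reads.  Pass a prebuilt
    :class:`GenomeIndex` to amortize index construction across libraries.
    """
    index = genome if isinstance(genome, GenomeIndex) else \
        GenomeIndex(genome, seed_len)
    records: list[AlignmentRecord] = []
    for read in reads:
        hits: list[tuple[str, int, str]] = []
        for strand, query in (("+", read.seq), ("-", revcomp(read.seq))):
            hits.extend((name, pos, strand)
                        for name, pos in index.exact_hits(query))
        n = len(hits)
        records.extend(
            AlignmentRecord(read.id, name, pos, strand, 0, n, len(read.seq))
            for name, pos, strand in hits
        )
    return records


def unique_only(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep alignments of uniquely mapping reads (n_hits == 1)."""
    return [r for r in records if r.n_hits == 1]


def _validate_disjoint(intervals: Sequence[GenomicInterval]) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping features {prev.name!r} and {cur.name!r} on {chrom}"
                )


def assign_to_features(records: Iterable[AlignmentRecord],
                       intervals: Sequence[GenomicInterval],
                       ) -> dict[str, list[AlignmentRecord]]:
    """Assign alignments to the feature fully containing their span.

    The feature set must be non-overlapping within itself (validated); an
    alignment straddling a feature boundary is not counted.  Returns a map
    feature name -> assigned alignment records (empty lists included for
    features receiving no reads).
    """
    _validate_disjoint(intervals)
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    starts: dict[str, list[int]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        starts[chrom] = [iv.start for iv in ivs]

    assigned: dict[str, list[AlignmentRecord]] = {iv.name: [] for iv in intervals}
    for rec in records:
        ivs = by_chrom.get(rec.target)
        if not ivs:
            continue
        i = bisect_right(starts[rec.target], rec.pos) - 1
        if i >= 0 and ivs[i].contains_span(rec.pos, rec.pos + rec.length):
            assigned[ivs[i].name].append(rec)
    return assigned


def records_to_table(records: Iterable[AlignmentRecord]) -> pd.DataFrame:
    """Tabular dump of alignment records (read, target, pos, strand, mm, n_hits)."""
    return pd.DataFrame(
        [(r.read_id, r.target, r.pos, r.strand, r.mismatches, r.n_hits, r.length)
         for r in records],
        columns=["read", "target", "pos", "strand", "mm", "n_hits", "length"],
    )
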