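"""File formats, coordinates, run configuration and logging.

All genomic coordinates are 0-based half-open internally (BED convention).
Printed spans such as ``X:3833-27378`` are 1-based inclusive; conversion is
centralized in :func:`span_from_display` / :func:`span_to_display` and is
involutive.

Supported formats: FASTA (genome, transposon consensus, miRNA set), FASTQ
(read libraries), BED6 with semicolon-separated ``key=value`` attributes in
column 7 (insertions, clusters, cytolocation bins, compartment map, gene
models), TSV tables, and a flat ``key = value`` run-configuration file.
"""

from __future__ import annotations

import dataclasses
import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pandas as pd

log = logging.getLogger("pirnakit")

_FASTA_ALPHABET = set("ACGTN")
_STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def configure_logging(level: int = logging.INFO) -> None:
    """Route pipeline logging to standard error (idempotent)."""
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(handler)
    log.setLevel(level)


def log_stage(stage: str, library: str, n_in: int, n_out: int) -> None:
    """Standard per-stage survival log line: library, input count, surviving count."""
    log.info("%s | library=%s in=%d out=%d", stage, library, n_in, n_out)


class FormatError(ValueError):
    """Malformed input file; message names the offending line where known."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomicInterval:
    """Half-open interval on a named chromosome with optional attributes.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``strand`` is one of
    ``+``, ``-`` or ``.``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains_span(self, start: int, end: int) -> bool:
        """Full containment of [start, end) within this interval."""
        return self.start <= start and end <= self.end

    def validate_against(self, chrom_lengths: dict[str, int]) -> None:
        if self.chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > chrom_lengths[self.chrom]:
            raise ValueError(
                f"{self.name or self.chrom}: end {self.end} exceeds "
                f"chromosome length {chrom_lengths[self.chrom]}"
            )

    def display(self) -> str:
        return span_to_display(self.chrom, self.start, self.end)


_SPAN_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def span_from_display(span: str) -> tuple[str, int, int]:
    """Parse a 1-based inclusive span like ``X:3833-27378`` to 0-based half-open.

    ``X:3833-27378`` -> ``("X", 3832, 27378)``.  Inverse of
    :func:`span_to_display`.
    """
    m = _SPAN_RE.match(span)
    if m is None:
        raise FormatError(f"cannot parse span {span!r}; expected chrom:first-last")
    chrom, first, last = m.group(1), int(m.group(2)), int(m.group(3))
    if first < 1 or last < first:
        raise FormatError(f"invalid 1-based span {span!r}")
    return chrom, first - 1, last


def span_to_display(chrom: str, start: int, end: int) -> str:
    """Render a 0-based half-open span in 1-based inclusive display form."""
    if start < 0 or end <= start:
        raise ValueError(f"invalid half-open span {chrom}:{start}-{end}")
    return f"{chrom}:{start + 1}-{end}"


@dataclass
class RunConfig:
    """All analysis thresholds with their published defaults.

    Defaults encode the pipeline's operating point: 23-29 nt piRNA size
    window, two mismatches against transposon consensus, zero-mismatch
    unique genome mapping, 10-kb enrichment windows, the >1000-control-read
    cytolocation filter, the >=20-unique-piRNA insertion eligibility filter,
    and the 3-fold / 2.5-fold / 2-fold loss thresholds used by the
    age-stratified, cluster-level and family-level loss summaries.
    """

    pirna_min_len: int = 23
    pirna_max_len: int = 29
    input_min_len: int = 18
    input_max_len: int = 30
    consensus_max_mm: int = 2
    genome_max_mm: int = 0
    window_size: int = 10_000
    cytolocation_min_control_reads: int = 1000
    min_unique_pirnas: int = 20
    insertion_loss_threshold: float = 3.0
    cluster_loss_threshold: float = 2.5
    family_loss_threshold: float = 2.0
    derepression_threshold: float = 2.5
    pseudocount: float = 1.0
    loess_span: float = 0.3
    loess_degree: int = 2
    junction_anchor: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name in ("seed", "genome_max_mm"):  # allowed to be zero
                continue
            if value <= 0:
                raise ValueError(f"config key {f.name} must be strictly positive")
        if self.genome_max_mm < 0:
            raise ValueError("genome_max_mm must be non-negative")
        if self.pirna_min_len > self.pirna_max_len:
            raise ValueError("pirna_min_len > pirna_max_len")
        if self.input_min_len > self.input_max_len:
            raise ValueError("input_min_len > input_max_len")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a flat ``key = value`` text file; unknown keys error."""
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key = value")
            key, _, value = (part.strip() for part in line.partition("="))
            if key not in known:
                raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
            caster = float if "float" in str(known[key]) else int
            kwargs[key] = caster(value)
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


class Read(NamedTuple):
    """A sequencing read: identifier, sequence, quality string."""

    id: str
    seq: str
    qual: str

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(name, sequence)`` in file order.

    Sequences are uppercased; the alphabet is restricted to {A,C,G,T,N}.
    Malformed headers or illegal characters raise :class:`FormatError`
    naming the line.
    """
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name is not None:
                    records.append((name, "".join(chunks)))
                name, chunks = header, []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence before first header"
                    )
                seq = line.upper()
                bad = set(seq) - _FASTA_ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: illegal character(s) "
                        f"{''.join(sorted(bad))!r} in sequence"
                    )
                chunks.append(seq)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream 4-line FASTQ records; truncated or inconsistent records error."""
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FormatError(f"{path}:{lineno}: expected '@' header")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus or not qual and not seq:
                raise FormatError(f"{path}:{lineno}: truncated FASTQ record")
            if not plus.startswith("+"):
                raise FormatError(f"{path}:{lineno + 2}: expected '+' separator")
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}:{lineno}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            lineno += 3
            yield Read(header[1:].rstrip("\n").split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")


# ---------------------------------------------------------------------------
# BED6 + attributes
# ---------------------------------------------------------------------------

def _parse_attributes(text: str, lineno: int, path: str | Path,
                      allowed: set[str] | None) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in filter(None, (p.strip() for p in text.split(";"))):
        if "=" not in item:
            raise FormatError(f"{path}:{lineno}: attribute {item!r} is not key=value")
        key, _, value = item.partition("=")
        if allowed is not None and key not in allowed:
            raise FormatError(f"{path}:{lineno}: unknown attribute key {key!r}")
        attrs[key] = value
    return attrs


def read_bed(path: str | Path, allowed_attributes: set[str] | None = None,
             required_attributes: set[str] | None = None) -> list[GenomicInterval]:
    """Read BED6(+1) intervals; column 7 holds ``key=value;...`` attributes.

    Coordinates are kept 0-based half-open exactly as in the file.  When
    ``allowed_attributes`` is given (strict schema) unknown keys error;
    ``required_attributes`` must be present on every record.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 tab-separated columns")
            chrom, start_s, end_s, name, score_s, strand = cols[:6]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            attrs = (_parse_attributes(cols[6], lineno, path, allowed_attributes)
                     if len(cols) > 6 and cols[6] else {})
            if required_attributes:
                missing = required_attributes - attrs.keys()
                if missing:
                    raise FormatError(
                        f"{path}:{lineno}: missing attribute(s) {sorted(missing)}"
                    )
            intervals.append(GenomicInterval(
                chrom=chrom, start=start, end=end, strand=strand,
                name=name, score=float(score_s), attributes=attrs,
            ))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name,
                    f"{iv.score:g}", iv.strand]
            if iv.attributes:
                cols.append(";".join(f"{k}={v}" for k, v in iv.attributes.items()))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with header, deterministic column order and float format."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
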