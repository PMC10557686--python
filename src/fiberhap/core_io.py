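"""Domain types and plain-text I/O shared by every analysis stage.

All genomic coordinates in this package are 0-based, half-open
(BED-compatible).  Display coordinates from genome browsers (1-based,
fully closed) must be converted before they enter the package.

The on-disk contracts are deliberately simple tab-separated text files:

* **fiber table** — one row per sequenced chromatin fiber with columns
  ``chrom  start  end  fiber_id  haplotype  msps`` where ``msps`` encodes the
  fiber's methyltransferase-sensitive patches (MSPs) as comma-separated
  ``start-end:precision`` triples (empty string for a fiber with no patch).
* **CpG table** — ``chrom  pos  fiber_id  haplotype  methylated`` with
  ``methylated`` as 0/1.
* **transcript table** — ``read_id  gene_id  haplotype``.
* **BED3+** for peaks/regions and **bedGraph** for per-base signal tracks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

HAP1 = "H1"
HAP2 = "H2"
UNASSIGNED = "UNASSIGNED"
HAPLOTYPES = (HAP1, HAP2, UNASSIGNED)

FIBER_COLUMNS = ("chrom", "start", "end", "fiber_id", "haplotype", "msps")
CPG_COLUMNS = ("chrom", "pos", "fiber_id", "haplotype", "methylated")
TRANSCRIPT_COLUMNS = ("read_id", "gene_id", "haplotype")


class FormatError(ValueError):
    """A malformed row or field in one of the tabular inputs."""


def overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """Half-open interval overlap predicate used by every module."""
    return a_start < b_end and b_start < a_end


def contains(outer_start: int, outer_end: int, inner_start: int, inner_end: int) -> bool:
    """True when [inner_start, inner_end) lies entirely within the outer interval."""
    return outer_start <= inner_start and inner_end <= outer_end


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and overlaps(self.start, self.end, other.start, other.end)

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and contains(self.start, self.end, other.start, other.end)


@dataclass(frozen=True, slots=True)
class MspCall:
    """A methyltransferase-sensitive patch on one fiber.

    ``precision`` is the upstream classifier's confidence that the patch is a
    regulatory element (a FIRE) rather than an internucleosomal linker; it is
    an input to this package, never computed here.
    """

    interval: GenomicInterval
    precision: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.precision <= 1.0):
            raise ValueError(f"precision must be in [0, 1], got {self.precision}")


@dataclass(frozen=True, slots=True)
class Fiber:
    """One sequenced chromatin fiber with its MSP calls and haplotype tag."""

    interval: GenomicInterval
    fiber_id: str
    haplotype: str
    msps: tuple[MspCall, ...] = ()

    def __post_init__(self) -> None:
        if self.haplotype not in HAPLOTYPES:
            raise ValueError(f"haplotype must be one of {HAPLOTYPES}, got {self.haplotype!r}")
        prev_end = -1
        for m in self.msps:
            if not self.interval.contains(m.interval):
                raise ValueError(
                    f"MSP {m.interval} outside fiber {self.interval} ({self.fiber_id})"
                )
            if m.interval.start < prev_end:
                raise ValueError(f"MSPs must be sorted and non-overlapping ({self.fiber_id})")
            prev_end = m.interval.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True, slots=True)
class CpGCall:
    """Per-fiber methylation state of one CpG cytosine."""

    chrom: str
    pos: int
    fiber_id: str
    haplotype: str
    methylated: bool

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.haplotype not in HAPLOTYPES:
            raise ValueError(f"haplotype must be one of {HAPLOTYPES}")


@dataclass(frozen=True, slots=True)
class TranscriptRead:
    """One full-length transcript read assigned to a gene and haplotype."""

    read_id: str
    gene_id: str
    haplotype: str

    def __post_init__(self) -> None:
        if self.haplotype not in HAPLOTYPES:
            raise ValueError(f"haplotype must be one of {HAPLOTYPES}")


@dataclass(frozen=True, slots=True)
class Peak:
    """An accessible-chromatin peak interval (called or supplied via BED)."""

    interval: GenomicInterval
    peak_id: str
    max_signal: float | None = None

    def __post_init__(self) -> None:
        if self.max_signal is not None and self.max_signal < 0:
            raise ValueError("max_signal must be >= 0 when present")


# ---------------------------------------------------------------------------
# fiber table


def _parse_msps(text: str, chrom: str, line_no: int) -> tuple[MspCall, ...]:
    if text == "":
        return ()
    calls = []
    for token in text.split(","):
        try:
            span, prec = token.split(":")
            s, e = span.split("-")
            call = MspCall(GenomicInterval(chrom, int(s), int(e)), float(prec))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"line {line_no}: bad MSP token {token!r}: {exc}") from exc
        calls.append(call)
    return tuple(calls)


def read_fiber_table(path) -> list[Fiber]:
    """Read a fiber TSV; raises :class:`FormatError` naming the offending line."""
    fibers: list[Fiber] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != FIBER_COLUMNS:
            raise FormatError(f"bad fiber table header in {path}: {header}")
        for line_no, row in enumerate(reader, start=2):
            if len(row) != len(FIBER_COLUMNS):
                raise FormatError(f"line {line_no}: expected {len(FIBER_COLUMNS)} fields, got {len(row)}")
            chrom, start, end, fiber_id, hap, msps = row
            try:
                fiber = Fiber(
                    GenomicInterval(chrom, int(start), int(end)),
                    fiber_id,
                    hap,
                    _parse_msps(msps, chrom, line_no),
                )
            except FormatError:
                raise
            except ValueError as exc:
                raise FormatError(f"line {line_no}: {exc}") from exc
            if fiber_id in seen:
                raise FormatError(f"line {line_no}: duplicate fiber_id {fiber_id!r}")
            seen.add(fiber_id)
            fibers.append(fiber)
    return fibers


def _format_msps(msps: Sequence[MspCall]) -> str:
    return ",".join(f"{m.interval.start}-{m.interval.end}:{m.precision!r}" for m in msps)


def write_fiber_table(fibers: Iterable[Fiber], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(FIBER_COLUMNS) + "\n")
        for f in fibers:
            fh.write(
                f"{f.interval.chrom}\t{f.interval.start}\t{f.interval.end}\t"
                f"{f.fiber_id}\t{f.haplotype}\t{_format_msps(f.msps)}\n"
            )


# ---------------------------------------------------------------------------
# CpG table


def read_cpg_table(path) -> list[CpGCall]:
    calls: list[CpGCall] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != CPG_COLUMNS:
            raise FormatError(f"bad CpG table header in {path}: {header}")
        for line_no, row in enumerate(reader, start=2):
            if len(row) != len(CPG_COLUMNS):
                raise FormatError(f"line {line_no}: expected {len(CPG_COLUMNS)} fields")
            chrom, pos, fiber_id, hap, meth = row
            if meth not in ("0", "1"):
                raise FormatError(f"line {line_no}: methylated must be 0/1, got {meth!r}")
            try:
                calls.append(CpGCall(chrom, int(pos), fiber_id, hap, meth == "1"))
            except ValueError as exc:
                raise FormatError(f"line {line_no}: {exc}") from exc
    return calls


def write_cpg_table(calls: Iterable[CpGCall], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(CPG_COLUMNS) + "\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.fiber_id}\t{c.haplotype}\t{int(c.methylated)}\n")


# ---------------------------------------------------------------------------
# transcript table


def read_transcript_table(path) -> list[TranscriptRead]:
    reads: list[TranscriptRead] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != TRANSCRIPT_COLUMNS:
            raise FormatError(f"bad transcript table header in {path}: {header}")
        for line_no, row in enumerate(reader, start=2):
            if len(row) != len(TRANSCRIPT_COLUMNS):
                raise FormatError(f"line {line_no}: expected {len(TRANSCRIPT_COLUMNS)} fields")
            read_id, gene_id, hap = row
            if read_id in seen:
                raise FormatError(f"line {line_no}: duplicate read_id {read_id!r}")
            seen.add(read_id)
            try:
                reads.append(TranscriptRead(read_id, gene_id, hap))
            except ValueError as exc:
                raise FormatError(f"line {line_no}: {exc}") from exc
    return reads


def write_transcript_table(reads: Iterable[TranscriptRead], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(TRANSCRIPT_COLUMNS) + "\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.gene_id}\t{r.haplotype}\n")


# ---------------------------------------------------------------------------
# BED / bedGraph


def read_bed(path) -> list[Peak]:
    """Read BED3+ into Peaks. Column 4 is the peak id (auto-generated when
    absent), column 5 the max signal (``.`` or absent -> None)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {line_no}: BED needs >= 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"line {line_no}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{line_no}"
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            peaks.append(Peak(GenomicInterval(chrom, start, end), name, score))
    return peaks


def write_bed(peaks: Iterable[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = "." if p.max_signal is None else f"{p.max_signal!r}"
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.peak_id}\t{score}\n")


def iter_bedgraph_runs(start: int, values: np.ndarray) -> Iterator[tuple[int, int, float]]:
    """Run-length encode a per-base value vector; zero runs are omitted."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return
    change = np.flatnonzero(np.diff(values)) + 1
    bounds = np.concatenate(([0], change, [values.size]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        v = float(values[lo])
        if v != 0.0:
            yield start + int(lo), start + int(hi), v


def write_bedgraph(chrom: str, start: int, values: np.ndarray, path) -> None:
    """Write a per-base track as sorted, non-overlapping bedGraph rows with
    adjacent equal-value runs merged and zero runs omitted."""
    with open(path, "w") as fh:
        for lo, hi, v in iter_bedgraph_runs(start, values):
            fh.write(f"{chrom}\t{lo}\t{hi}\t{v!r}\n")
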