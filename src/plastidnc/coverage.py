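"""Strand-specific per-base depth and read-start tracks.

Reads from a directional (strand-specific) library carry the strand of the
transcript they came from, so a placement's strand is taken directly from
the alignment flag. Up to two placements per read are accepted, mirroring
alignment to both copies of the plastome inverted repeat; by default each
placement contributes full weight to both coverage copies (``multi_weight``
0.5 halves doubly-placed reads instead).

Tracks are 1-based internally: index ``i`` of the numpy arrays stores base
``i + 1``. bedGraph I/O converts to the standard 0-based half-open dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np

from .genome import STRANDS, CoordinateError, check_interval

log = logging.getLogger(__name__)


class PlacementError(ValueError):
    """A read placement violates the input contract."""


@dataclass(frozen=True)
class ReadPlacement:
    """One accepted placement of one sequenced read (1-based inclusive)."""

    read_id: str
    start: int
    stop: int
    strand: str
    n_placements: int = 1

    def __post_init__(self) -> None:
        if self.start > self.stop or self.start < 1:
            raise PlacementError(f"{self.read_id}: bad interval {self.start}-{self.stop}")
        if self.strand not in STRANDS:
            raise PlacementError(f"{self.read_id}: bad strand {self.strand!r}")
        if self.n_placements not in (1, 2):
            raise PlacementError(
                f"{self.read_id}: n_placements must be 1 or 2, got {self.n_placements}"
            )

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


@dataclass
class StrandedCoverage:
    """Per-strand depth and read-start tracks over one genome.

    ``has_starts`` is False when the tracks were ingested from bedGraph
    (depth only); operations needing read starts then refuse.
    """

    genome_length: int
    depth_plus: np.ndarray
    depth_minus: np.ndarray
    starts_plus: np.ndarray | None = None
    starts_minus: np.ndarray | None = None
    n_placements_plus: float = 0.0
    n_placements_minus: float = 0.0

    @property
    def has_starts(self) -> bool:
        return self.starts_plus is not None

    def depth(self, strand: str) -> np.ndarray:
        return self.depth_plus if strand == "+" else self.depth_minus

    def starts(self, strand: str) -> np.ndarray:
        if not self.has_starts:
            raise ValueError(
                "coverage has no read-start tracks (bedGraph input); "
                "re-run from placements to enable start-based operations"
            )
        return self.starts_plus if strand == "+" else self.starts_minus  # type: ignore[return-value]

    @property
    def total_placements(self) -> float:
        return self.n_placements_plus + self.n_placements_minus


# ---------------------------------------------------------------------------
# placement input


def load_placements(stream: IO[str] | str, fmt: str = "auto") -> list[ReadPlacement]:
    """Read placements from SAM (via pysam) or the 5-column tabular format.

    Tabular columns: read_id, start, stop, strand, n_placements. For SAM,
    ``n_placements`` is recomputed from read_id multiplicity; more than two
    placements for one read is an error (the aligner was run with at most
    two hits per read). Unmapped records are skipped and counted.
    """
    if fmt == "auto":
        fmt = _sniff_format(stream)
    if fmt == "sam":
        return _load_sam(stream)
    if fmt == "tabular":
        return _load_tabular(stream)
    raise ValueError(f"unknown placement format {fmt!r}")


def _sniff_format(stream) -> str:
    if isinstance(stream, str):
        return "sam" if stream.endswith((".sam", ".bam")) else "tabular"
    head = stream.read(1)
    try:
        stream.seek(stream.tell() - len(head))
    except (OSError, AttributeError):
        raise ValueError("cannot sniff format on a non-seekable stream; pass fmt=")
    return "sam" if head == "@" else "tabular"


def _load_sam(source) -> list[ReadPlacement]:
    import pysam

    mode = "rb" if isinstance(source, str) and source.endswith(".bam") else "r"
    raw: list[tuple[str, int, int, str]] = []
    n_unmapped = 0
    with pysam.AlignmentFile(source, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            # reference_start is 0-based; reference_end is exclusive.
            raw.append((rec.query_name, rec.reference_start + 1, rec.reference_end, strand))
    if n_unmapped:
        log.info("skipped %d unmapped records", n_unmapped)
    counts: dict[str, int] = {}
    for read_id, *_ in raw:
        counts[read_id] = counts.get(read_id, 0) + 1
    bad = [r for r, c in counts.items() if c > 2]
    if bad:
        raise PlacementError(f"read {bad[0]!r} has {counts[bad[0]]} placements (max 2)")
    return [
        ReadPlacement(read_id, start, stop, strand, counts[read_id])
        for read_id, start, stop, strand in raw
    ]


def _load_tabular(stream) -> list[ReadPlacement]:
    close = False
    if isinstance(stream, str):
        stream = open(stream)
        close = True
    try:
        out: list[ReadPlacement] = []
        for lineno, line in enumerate(stream, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise PlacementError(f"placement line {lineno}: expected 5 columns")
            read_id, start, stop, strand, n = parts
            out.append(ReadPlacement(read_id, int(start), int(stop), strand, int(n)))
    finally:
        if close:
            stream.close()
    counts: dict[str, int] = {}
    for p in out:
        counts[p.read_id] = counts.get(p.read_id, 0) + 1
        if counts[p.read_id] > 2:
            raise PlacementError(f"read {p.read_id!r} has >2 placements")
    return out


def write_placements(placements: Iterable[ReadPlacement], stream: IO[str]) -> None:
    stream.write("#read_id\tstart\tstop\tstrand\tn_placements\n")
    for p in placements:
        stream.write(f"{p.read_id}\t{p.start}\t{p.stop}\t{p.strand}\t{p.n_placements}\n")


# ---------------------------------------------------------------------------
# track construction


def coverage_from_placements(
    placements: Sequence[ReadPlacement],
    genome_length: int,
    multi_weight: float = 1.0,
) -> StrandedCoverage:
    """Accumulate depth and read-start tracks from placements.

    Each placement adds ``w`` to depth over its span and to the start track
    at its start base, where ``w`` is 1 for uniquely placed reads and
    ``multi_weight`` (default 1: full weight at both copies) for doubly
    placed ones. With the default weight the tracks are integer-valued.
    """
    depth = {s: np.zeros(genome_length, dtype=np.float64) for s in STRANDS}
    starts = {s: np.zeros(genome_length, dtype=np.float64) for s in STRANDS}
    n_placed = {s: 0.0 for s in STRANDS}
    # difference-array accumulation: O(reads + genome)
    diff = {s: np.zeros(genome_length + 1, dtype=np.float64) for s in STRANDS}
    for p in placements:
        if p.stop > genome_length or p.start < 1:
            raise PlacementError(
                f"read {p.read_id!r} placement {p.start}-{p.stop} outside genome "
                f"of length {genome_length}"
            )
        w = 1.0 if p.n_placements == 1 else multi_weight
        diff[p.strand][p.start - 1] += w
        diff[p.strand][p.stop] -= w
        starts[p.strand][p.start - 1] += w
        n_placed[p.strand] += w
    for s in STRANDS:
        depth[s] = np.cumsum(diff[s][:-1])
    cov = StrandedCoverage(
        genome_length=genome_length,
        depth_plus=depth["+"],
        depth_minus=depth["-"],
        starts_plus=starts["+"],
        starts_minus=starts["-"],
        n_placements_plus=n_placed["+"],
        n_placements_minus=n_placed["-"],
    )
    return cov


def read_start_count(cov: StrandedCoverage, start: int, stop: int, strand: str) -> float:
    """Number of reads whose start base lies in [start, stop] on ``strand``."""
    check_interval(start, stop, cov.genome_length)
    return float(cov.starts(strand)[start - 1 : stop].sum())


def covered_fraction(cov: StrandedCoverage, strand: str, min_depth: int = 1) -> float:
    """Fraction of the genome with depth >= min_depth on ``strand``."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return float((cov.depth(strand) >= min_depth).sum()) / cov.genome_length


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(cov: StrandedCoverage, strand: str, stream: IO[str]) -> None:
    """Write one strand's depth track as bedGraph (0-based half-open)."""
    d = cov.depth(strand)
    boundaries = np.flatnonzero(np.diff(d)) + 1
    edges = np.concatenate(([0], boundaries, [len(d)]))
    for lo, hi in zip(edges[:-1], edges[1:]):
        v = d[lo]
        if v != 0:
            out = int(v) if float(v).is_integer() else float(v)
            stream.write(f"plastome\t{lo}\t{hi}\t{out}\n")


def load_bedgraph(
    plus_stream: IO[str], minus_stream: IO[str], genome_length: int
) -> StrandedCoverage:
    """Build depth-only coverage from one bedGraph per strand.

    The result has no read-start tracks; start-based operations will refuse.
    """
    tracks = {}
    for strand, stream in (("+", plus_stream), ("-", minus_stream)):
        d = np.zeros(genome_length, dtype=np.float64)
        for lineno, line in enumerate(stream, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"bedGraph line {lineno}: expected 4 columns")
            lo, hi, v = int(parts[1]), int(parts[2]), float(parts[3])
            if not (0 <= lo < hi <= genome_length):
                raise CoordinateError(f"bedGraph line {lineno}: interval outside genome")
            d[lo:hi] += v
        tracks[strand] = d
    return StrandedCoverage(
        genome_length=genome_length, depth_plus=tracks["+"], depth_minus=tracks["-"]
    )
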