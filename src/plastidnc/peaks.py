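"""Threshold-based transcription-peak calling.

The operational unit is the transcription peak: a candidate ncRNA is
triggered wherever depth reaches ``peak_threshold`` (default 50x) at one or
more nucleotides, and its span extends in both directions until depth falls
below ``end_threshold`` (default 10x). Both thresholds are inclusive on the
"in" side: a base belongs to a run iff its depth is >= end_threshold, and a
run qualifies iff its maximum depth is >= peak_threshold.

With several genotypes, overlapping same-strand peaks are unified into one
candidate whose ends come from the highest-priority genotype that triggered
it (wild type before the ribonuclease mutant, mirroring how the published
termini were assigned), while ``trigger_genotypes`` records every genotype
reaching the peak threshold within the final span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .coverage import StrandedCoverage
from .genome import STRANDS


@dataclass(frozen=True)
class CallerConfig:
    peak_threshold: int = 50
    end_threshold: int = 10
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if not (self.peak_threshold >= self.end_threshold >= 1):
            raise ValueError(
                f"need peak_threshold >= end_threshold >= 1, got "
                f"{self.peak_threshold}/{self.end_threshold}"
            )
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass(frozen=True)
class CandidateInterval:
    """A called candidate ncRNA (1-based inclusive coordinates)."""

    id: str
    start: int
    stop: int
    strand: str
    trigger_genotypes: frozenset[str]
    end_source: str
    max_depth: Mapping[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        """Endpoint difference (stop - start), the catalog's size convention."""
        return self.stop - self.start

    @property
    def inclusive_length(self) -> int:
        return self.stop - self.start + 1

    def overlaps(self, start: int, stop: int) -> bool:
        return self.start <= stop and start <= self.stop


def call_strand_candidates(
    depth: np.ndarray | Sequence[float], cfg: CallerConfig = CallerConfig()
) -> list[tuple[int, int, float]]:
    """Qualifying runs on one strand's depth track.

    Returns the maximal runs of consecutive bases with depth >=
    ``end_threshold`` that contain at least one base with depth >=
    ``peak_threshold``, as sorted disjoint ``(start, stop, max_depth)``
    tuples in 1-based inclusive coordinates.
    """
    d = np.asarray(depth, dtype=np.float64)
    if d.size == 0:
        return []
    above = d >= cfg.end_threshold
    edges = np.diff(above.astype(np.int8))
    run_starts = np.flatnonzero(edges == 1) + 1
    run_stops = np.flatnonzero(edges == -1)
    if above[0]:
        run_starts = np.concatenate(([0], run_starts))
    if above[-1]:
        run_stops = np.concatenate((run_stops, [d.size - 1]))
    out: list[tuple[int, int, float]] = []
    for lo, hi in zip(run_starts, run_stops):
        peak = float(d[lo : hi + 1].max())
        if peak >= cfg.peak_threshold:
            out.append((int(lo) + 1, int(hi) + 1, peak))
    return out


def call_candidates(
    coverage_by_genotype: Mapping[str, StrandedCoverage],
    cfg: CallerConfig = CallerConfig(),
    genotype_priority: Sequence[str] | None = None,
) -> list[CandidateInterval]:
    """Call candidates across genotypes with end-assignment precedence.

    Per strand and genotype, qualifying runs are computed; runs from
    different genotypes overlapping by >= 1 nt are grouped, the group's end
    source is the highest-priority genotype present, and one candidate is
    emitted per end-source run in the group. ``max_depth`` records each
    genotype's maximum depth within the candidate span and
    ``trigger_genotypes`` the genotypes at or above the peak threshold
    there. Ids are assigned in genomic order (ncRNA_0001, ...).
    """
    if not coverage_by_genotype:
        return []
    if genotype_priority is None:
        genotype_priority = list(coverage_by_genotype)
    missing = set(coverage_by_genotype) - set(genotype_priority)
    if missing:
        raise ValueError(f"genotypes missing from priority order: {sorted(missing)}")
    lengths = {c.genome_length for c in coverage_by_genotype.values()}
    if len(lengths) > 1:
        raise ValueError(f"genotypes have mismatched genome lengths: {sorted(lengths)}")

    raw: list[CandidateInterval] = []
    for strand in STRANDS:
        runs = {
            g: call_strand_candidates(coverage_by_genotype[g].depth(strand), cfg)
            for g in genotype_priority
            if g in coverage_by_genotype
        }
        for group in _overlap_groups(runs):
            source = next(g for g in genotype_priority if any(r[0] == g for r in group))
            for g, lo, hi, _peak in sorted(group):
                if g != source:
                    continue
                md = {
                    gt: float(np.max(coverage_by_genotype[gt].depth(strand)[lo - 1 : hi]))
                    for gt in runs
                }
                trig = frozenset(gt for gt, v in md.items() if v >= cfg.peak_threshold)
                raw.append(
                    CandidateInterval(
                        id="",
                        start=lo,
                        stop=hi,
                        strand=strand,
                        trigger_genotypes=trig,
                        end_source=source,
                        max_depth=md,
                    )
                )
    raw.sort(key=lambda c: (c.start, c.stop, c.strand))
    out = [replace(c, id=f"ncRNA_{i + 1:04d}") for i, c in enumerate(raw)]
    if cfg.merge_gap > 0:
        out = merge_adjacent(out, cfg.merge_gap)
    return out


def _overlap_groups(
    runs_by_genotype: Mapping[str, list[tuple[int, int, float]]]
) -> list[list[tuple[str, int, int, float]]]:
    """Connected components of same-strand runs under >= 1 nt overlap."""
    items = sorted(
        (lo, hi, g, peak)
        for g, rr in runs_by_genotype.items()
        for lo, hi, peak in rr
    )
    groups: list[list[tuple[str, int, int, float]]] = []
    cur: list[tuple[str, int, int, float]] = []
    cur_hi = -1
    for lo, hi, g, peak in items:
        if cur and lo <= cur_hi:
            cur.append((g, lo, hi, peak))
            cur_hi = max(cur_hi, hi)
        else:
            if cur:
                groups.append(cur)
            cur = [(g, lo, hi, peak)]
            cur_hi = hi
    if cur:
        groups.append(cur)
    return groups


def merge_adjacent(
    candidates: Sequence[CandidateInterval], max_gap: int
) -> list[CandidateInterval]:
    """Merge same-strand candidates separated by 1..max_gap nt.

    ``max_gap = 0`` disables merging (published candidates were reported as
    unmerged coverage fragments). Merging unions the span and the trigger
    sets and takes per-genotype maxima of ``max_depth``; it iterates to a
    fixed point, so chains of nearby candidates collapse.
    """
    if max_gap == 0:
        return list(candidates)
    out: list[CandidateInterval] = []
    for strand in STRANDS:
        chain = sorted(
            (c for c in candidates if c.strand == strand), key=lambda c: (c.start, c.stop)
        )
        merged: list[CandidateInterval] = []
        for c in chain:
            if merged and c.start - merged[-1].stop - 1 <= max_gap:
                prev = merged[-1]
                md = dict(prev.max_depth)
                for g, v in c.max_depth.items():
                    md[g] = max(md.get(g, 0.0), v)
                merged[-1] = replace(
                    prev,
                    stop=max(prev.stop, c.stop),
                    trigger_genotypes=prev.trigger_genotypes | c.trigger_genotypes,
                    max_depth=md,
                )
            else:
                merged.append(c)
        out.extend(merged)
    out.sort(key=lambda c: (c.start, c.stop, c.strand))
    return [replace(c, id=f"ncRNA_{i + 1:04d}") for i, c in enumerate(out)]


def interval_length(c: CandidateInterval) -> int:
    """Candidate size as the endpoint difference (stop - start)."""
    return c.length


# ---------------------------------------------------------------------------
# export


def write_bed6(candidates: Iterable[CandidateInterval], stream: IO[str]) -> None:
    """BED6 export (0-based half-open); score = min over trigger genotypes of
    the candidate's max depth, capped at 1000."""
    for c in candidates:
        trig_depths = [c.max_depth[g] for g in c.trigger_genotypes if g in c.max_depth]
        score = int(min(min(trig_depths, default=0), 1000))
        stream.write(f"plastome\t{c.start - 1}\t{c.stop}\t{c.id}\t{score}\t{c.strand}\n")


def write_candidates_tsv(
    candidates: Iterable[CandidateInterval], stream: IO[str]
) -> None:
    stream.write(
        "id\tstart\tstop\tstrand\tlength\ttrigger_genotypes\tend_source\tmax_depth\n"
    )
    for c in candidates:
        trig = ",".join(sorted(c.trigger_genotypes))
        md = ",".join(f"{g}={c.max_depth[g]:g}" for g in sorted(c.max_depth))
        stream.write(
            f"{c.id}\t{c.start}\t{c.stop}\t{c.strand}\t{c.length}\t{trig}\t"
            f"{c.end_source}\t{md}\n"
        )
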