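"""Genotype comparison: per-candidate abundance, fold change, mutant-only
sets, and validation rate by coverage bin.

Abundance is estimated by binning reads by start position: a candidate's
raw count in a genotype is the number of read starts inside its interval on
its strand. Counts are normalized to counts per million placed reads (cpm)
so libraries of different depth are comparable; per-candidate fold changes
use a pseudocount (default 0.5 cpm) so mutant-only species stay finite. The
pooled antisense ratio is the ratio of summed cpm over all antisense
candidates — a pooled statement, not a mean of per-candidate ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .coverage import StrandedCoverage, read_start_count
from .peaks import CandidateInterval

log = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT_CPM = 0.5


@dataclass(frozen=True)
class AbundanceRecord:
    candidate_id: str
    raw_count: Mapping[str, float]
    cpm: Mapping[str, float]
    fold_change: float


def quantify(
    candidates: Sequence[CandidateInterval],
    coverage_by_genotype: Mapping[str, StrandedCoverage],
    wild_type: str | None = None,
    mutant: str | None = None,
    pseudocount_cpm: float = DEFAULT_PSEUDOCOUNT_CPM,
) -> list[AbundanceRecord]:
    """Per-candidate read-start counts, cpm, and mutant/WT fold change.

    ``wild_type`` and ``mutant`` default to the first and second genotype of
    the mapping. Requires coverage built from placements (start tracks).
    """
    genotypes = list(coverage_by_genotype)
    if wild_type is None:
        wild_type = genotypes[0]
    if mutant is None:
        mutant = genotypes[1] if len(genotypes) > 1 else genotypes[0]
    for g, cov in coverage_by_genotype.items():
        if not cov.has_starts:
            raise ValueError(
                f"genotype {g!r}: coverage lacks read-start tracks; abundance "
                "estimation needs placements, not bedGraph input"
            )
    totals = {g: cov.total_placements for g, cov in coverage_by_genotype.items()}
    out: list[AbundanceRecord] = []
    for c in candidates:
        raw = {
            g: read_start_count(cov, c.start, c.stop, c.strand)
            for g, cov in coverage_by_genotype.items()
        }
        cpm = {g: (raw[g] * 1e6 / totals[g] if totals[g] > 0 else 0.0) for g in raw}
        fc = (cpm[mutant] + pseudocount_cpm) / (cpm[wild_type] + pseudocount_cpm)
        out.append(AbundanceRecord(c.id, raw, cpm, fc))
    return out


def global_antisense_ratio(
    records: Sequence[AbundanceRecord],
    wild_type: str,
    mutant: str,
) -> float:
    """Pooled mutant/WT ratio of cpm summed over (antisense) records.

    Callers should pass records restricted to antisense candidates. A zero
    wild-type total returns +inf with a warning.
    """
    if not records:
        raise ValueError("need at least one abundance record")
    wt = sum(r.cpm[wild_type] for r in records)
    mut = sum(r.cpm[mutant] for r in records)
    if wt == 0:
        log.warning("wild-type antisense total is zero; ratio is +inf")
        return math.inf
    return mut / wt


def genotype_specific(
    candidates: Sequence[CandidateInterval],
    genotype: str,
    known_genotypes: Iterable[str] | None = None,
) -> list[CandidateInterval]:
    """Candidates whose peak threshold was reached only in ``genotype``."""
    known = set(known_genotypes) if known_genotypes is not None else {
        g for c in candidates for g in c.max_depth
    }
    if known and genotype not in known:
        raise ValueError(f"unknown genotype {genotype!r}; have {sorted(known)}")
    return [c for c in candidates if c.trigger_genotypes == {genotype}]


def detection_rate_bins(
    max_coverage: Sequence[float],
    validated: Sequence[bool],
    bin_edges: Sequence[float] = (50, 100, 150),
) -> pd.DataFrame:
    """Validation rate by peak-coverage bin.

    Bins are left-closed right-open over ``bin_edges`` with a final open bin
    ``[last_edge, inf)``; records below the first edge go to an explicit
    ``below-threshold`` bin. Returns a table with ``n`` and
    ``fraction_validated`` per bin.
    """
    if len(max_coverage) != len(validated):
        raise ValueError("max_coverage and validated must have equal length")
    edges = list(bin_edges)
    labels = ["below-threshold"]
    labels += [f"[{int(a)},{int(b)})" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f">={int(edges[-1])}")
    rows = {lab: [0, 0] for lab in labels}
    for cov, ok in zip(max_coverage, validated):
        if cov < edges[0]:
            lab = "below-threshold"
        else:
            lab = labels[-1]
            for a, b, name in zip(edges[:-1], edges[1:], labels[1:-1]):
                if a <= cov < b:
                    lab = name
                    break
        rows[lab][0] += 1
        rows[lab][1] += int(bool(ok))
    df = pd.DataFrame(
        {
            "bin": labels,
            "n": [rows[lab][0] for lab in labels],
            "fraction_validated": [
                rows[lab][1] / rows[lab][0] if rows[lab][0] else float("nan")
                for lab in labels
            ],
        }
    )
    return df.set_index("bin")


def write_abundance_tsv(records: Iterable[AbundanceRecord], stream: IO[str]) -> None:
    records = list(records)
    if not records:
        stream.write("candidate_id\tfold_change\n")
        return
    genotypes = sorted(records[0].raw_count)
    header = ["candidate_id"]
    header += [f"count_{g}" for g in genotypes]
    header += [f"cpm_{g}" for g in genotypes]
    header.append("fold_change")
    stream.write("\t".join(header) + "\n")
    for r in records:
        row = [r.candidate_id]
        row += [f"{r.raw_count[g]:g}" for g in genotypes]
        row += [f"{r.cpm[g]:.4f}" for g in genotypes]
        row.append(f"{r.fold_change:.4f}")
        stream.write("\t".join(row) + "\n")
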