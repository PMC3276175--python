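"""Classify called candidates against the gene annotation.

A candidate overlapping at least one opposite-strand gene or intron is an
antisense RNA (asRNA); a candidate with no opposite-strand overlap that lies
inside the span of an annotated gene cluster, without touching a same-strand
exon, is a strictly noncoding intergenic RNA. Candidates overlapping a
same-strand gene are rejected as probable fragments of the known sense
transcript; everything else is rejected as unassigned. Rejections are data,
not errors.

Pairing-region flags locate the candidate against each target gene's
termini: ``five_prime`` when it overlaps a window around the gene's
(strand-aware) 5' terminal base — the translation-initiation region —
``three_prime`` analogously at the 3' end, and ``internal`` when it touches
the gene body only. The window half-widths default to 25 nt per side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import pandas as pd

from .genome import Annotation, GeneFeature
from .peaks import CandidateInterval

DEFAULT_WINDOW_5P = 25
DEFAULT_WINDOW_3P = 25

REJECT_SAME_STRAND = "same_strand_overlap"
REJECT_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Rejection:
    candidate: CandidateInterval
    reason: str


@dataclass
class ClassifiedNcRNA:
    candidate: CandidateInterval
    ncrna_class: str  # "antisense" | "intergenic"
    target_genes: list[GeneFeature]
    region_flags: frozenset[str] = frozenset()
    name: str = ""

    @property
    def principal_target(self) -> GeneFeature:
        """Opposite-strand feature with the largest overlap (ties: smaller start)."""
        c = self.candidate

        def key(g: GeneFeature) -> tuple[int, int]:
            ov = min(c.stop, g.stop) - max(c.start, g.start) + 1
            return (-ov, g.start)

        return min(self.target_genes, key=key)

    @property
    def target_category(self) -> str:
        return self.principal_target.category


def classify(
    c: CandidateInterval,
    ann: Annotation,
    rrna_mask: bool = False,
) -> ClassifiedNcRNA | Rejection:
    """Classify one candidate; see the module docstring for the rules.

    ``rrna_mask`` optionally rejects candidates whose only opposite-strand
    overlaps are rRNA loci (for rRNA-depleted libraries); off by default —
    the scarcity of rRNA-antisense species is an observation, not a filter.
    """
    opposite = ann.features_overlapping(c.start, c.stop, f"opposite-of:{c.strand}")
    if rrna_mask:
        opposite = [g for g in opposite if g.kind != "rRNA"]
    if opposite:
        cls = ClassifiedNcRNA(candidate=c, ncrna_class="antisense", target_genes=opposite)
        cls.region_flags = frozenset().union(
            *(pairing_region(c, g) for g in opposite)
        )
        return cls
    same = ann.features_overlapping(c.start, c.stop, f"same:{c.strand}")
    for cluster_id, members in ann.clusters().items():
        span_lo = min(g.start for g in members)
        span_hi = max(g.stop for g in members)
        if span_lo <= c.start and c.stop <= span_hi and not same:
            left = [g for g in members if g.stop < c.start]
            right = [g for g in members if g.start > c.stop]
            flank = []
            if left:
                flank.append(max(left, key=lambda g: g.stop))
            if right:
                flank.append(min(right, key=lambda g: g.start))
            return ClassifiedNcRNA(
                candidate=c, ncrna_class="intergenic", target_genes=flank
            )
    if same:
        return Rejection(c, REJECT_SAME_STRAND)
    return Rejection(c, REJECT_UNASSIGNED)


def classify_all(
    candidates: Iterable[CandidateInterval],
    ann: Annotation,
    window_5p: int = DEFAULT_WINDOW_5P,
    window_3p: int = DEFAULT_WINDOW_3P,
    rrna_mask: bool = False,
) -> tuple[list[ClassifiedNcRNA], list[Rejection]]:
    """Classify candidates, recompute flags at the given windows, and name them."""
    kept: list[ClassifiedNcRNA] = []
    rejected: list[Rejection] = []
    for c in candidates:
        res = classify(c, ann, rrna_mask=rrna_mask)
        if isinstance(res, Rejection):
            rejected.append(res)
            continue
        if res.ncrna_class == "antisense":
            res.region_flags = frozenset().union(
                *(pairing_region(c, g, window_5p, window_3p) for g in res.target_genes)
            )
        kept.append(res)
    assign_names(kept)
    return kept, rejected


def pairing_region(
    c: CandidateInterval,
    gene: GeneFeature,
    window_5p: int = DEFAULT_WINDOW_5P,
    window_3p: int = DEFAULT_WINDOW_3P,
) -> frozenset[str]:
    """Region flags for one candidate against one opposite-strand gene."""
    if gene.strand == c.strand:
        raise ValueError(
            f"pairing_region requires an opposite-strand gene "
            f"({gene.name} is on {gene.strand}, candidate on {c.strand})"
        )
    if window_5p < 0 or window_3p < 0:
        raise ValueError("windows must be >= 0")
    t5 = gene.five_prime()
    t3 = gene.three_prime()
    flags = set()
    if c.overlaps(t5 - window_5p, t5 + window_5p):
        flags.add("five_prime")
    if c.overlaps(t3 - window_3p, t3 + window_3p):
        flags.add("three_prime")
    if not flags and c.overlaps(gene.start, gene.stop):
        flags.add("internal")
    return frozenset(flags)


# ---------------------------------------------------------------------------
# systematic names


def base_name(cls: ClassifiedNcRNA) -> str:
    """Systematic name without the duplicate-resolving ordinal.

    Antisense to gene X -> ``as-X``; antisense to X's intron -> ``as-Xi``;
    with exactly one terminus window hit the region suffix ``-5'``/``-3'``
    is appended. Intergenic between X and Y -> ``nc-X-Yint``.
    """
    if cls.ncrna_class == "intergenic":
        names = [g.name for g in sorted(cls.target_genes, key=lambda g: g.start)]
        if len(names) == 2:
            return f"nc-{names[0]}-{names[1]}int"
        if len(names) == 1:
            return f"nc-{names[0]}int"
        return "nc-int"
    g = cls.principal_target
    name = f"as-{g.name}"
    if g.kind == "intron":
        name += "i"
    flags = cls.region_flags
    if flags == {"five_prime"}:
        name += "-5'"
    elif flags == {"three_prime"}:
        name += "-3'"
    return name


def assign_names(classified: Sequence[ClassifiedNcRNA]) -> None:
    """Assign final names in place; shared base names get -1, -2, ... in
    genomic order."""
    ordered = sorted(classified, key=lambda x: (x.candidate.start, x.candidate.stop))
    groups: dict[str, list[ClassifiedNcRNA]] = {}
    for cls in ordered:
        groups.setdefault(base_name(cls), []).append(cls)
    seen: set[str] = set()
    for base, members in groups.items():
        if len(members) == 1:
            members[0].name = base
        else:
            for i, cls in enumerate(members, 1):
                cls.name = f"{base}-{i}"
        for cls in members:
            if cls.name in seen:
                raise RuntimeError(f"name collision after suffixing: {cls.name}")
            seen.add(cls.name)


def assign_name(cls: ClassifiedNcRNA, existing: set[str]) -> str:
    """Name a single classified candidate against an existing name set."""
    base = base_name(cls)
    if base not in existing:
        cls.name = base
        return base
    i = 1
    while f"{base}-{i}" in existing:
        i += 1
    cls.name = f"{base}-{i}"
    return cls.name


# ---------------------------------------------------------------------------
# summaries and export


def category_summary(classified: Iterable[ClassifiedNcRNA]) -> pd.DataFrame:
    """Counts and fractions of antisense candidates by target-gene category."""
    cats = [cls.target_category for cls in classified if cls.ncrna_class == "antisense"]
    if not cats:
        return pd.DataFrame(columns=["count", "fraction"])
    counts = pd.Series(cats).value_counts().sort_index()
    return pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})


def write_classified_gff3(
    classified: Iterable[ClassifiedNcRNA], stream: IO[str], seqid: str = "plastome"
) -> None:
    stream.write("##gff-version 3\n")
    for cls in classified:
        c = cls.candidate
        attrs = [
            f"ID={c.id}",
            f"Name={cls.name}",
            f"class={cls.ncrna_class}",
            "targets=" + ",".join(g.name for g in cls.target_genes),
            "flags=" + ",".join(sorted(cls.region_flags)),
        ]
        stream.write(
            f"{seqid}\tplastidnc\tncRNA\t{c.start}\t{c.stop}\t.\t{c.strand}\t.\t"
            + ";".join(attrs)
            + "\n"
        )


def write_classified_tsv(classified: Iterable[ClassifiedNcRNA], stream: IO[str]) -> None:
    stream.write(
        "name\tclass\tstart\tstop\tstrand\tlength\ttargets\tregion_flags\t"
        "target_category\ttrigger_genotypes\tend_source\n"
    )
    for cls in classified:
        c = cls.candidate
        stream.write(
            "\t".join(
                [
                    cls.name,
                    cls.ncrna_class,
                    str(c.start),
                    str(c.stop),
                    c.strand,
                    str(c.length),
                    ",".join(g.name for g in cls.target_genes),
                    ",".join(sorted(cls.region_flags)),
                    cls.target_category if cls.target_genes else ".",
                    ",".join(sorted(c.trigger_genotypes)),
                    c.end_source,
                ]
            )
            + "\n"
        )
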