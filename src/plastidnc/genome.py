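"""Plastome sequence, gene annotation, and strand-aware interval queries.

Coordinates are 1-based inclusive throughout, matching GenBank and the
published candidate catalog; BED/bedGraph writers convert to 0-based
half-open at the boundary. Strand symbols are ``+`` and ``-``.

Circular genomes are supported as a flag only: features and queries may not
wrap the origin (no catalog interval does), and wrap-around inputs are
rejected with :class:`CoordinateError`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-")

GENE_KINDS = ("tRNA", "rRNA", "protein", "intron", "other")

#: target-gene functional categories used for the antisense class summary
CATEGORIES = ("photosynthesis", "gene_expression", "misc_protein", "ycf", "tRNA", "rRNA")


class AnnotationError(ValueError):
    """Malformed annotation input (bad GFF3 line, out-of-range feature)."""


class CoordinateError(ValueError):
    """Invalid genomic interval (inverted, out of range, or origin-wrapping)."""


@dataclass(frozen=True)
class PlastomeSequence:
    """A (toy or real) chloroplast genome.

    ``residues`` may be ``None`` for coverage-only workflows; operations that
    need sequence (ORF scanning) raise when it is absent. ``inverted_repeat``
    holds the two reverse-complementary repeat intervals when modeled.
    """

    length: int
    residues: str | None = None
    circular: bool = True
    inverted_repeat: tuple[tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise CoordinateError(f"genome length must be positive, got {self.length}")
        if self.residues is not None and len(self.residues) != self.length:
            raise CoordinateError(
                f"residue count {len(self.residues)} != declared length {self.length}"
            )
        if self.inverted_repeat is not None:
            (a1, a2), (b1, b2) = self.inverted_repeat
            for lo, hi in ((a1, a2), (b1, b2)):
                if not (1 <= lo <= hi <= self.length):
                    raise CoordinateError(f"inverted repeat copy ({lo},{hi}) outside genome")
            if not (a2 < b1 or b2 < a1):
                raise CoordinateError("inverted repeat copies overlap")

    def subsequence(self, start: int, stop: int) -> str:
        """Residues on the forward strand over [start, stop], 1-based inclusive."""
        if self.residues is None:
            raise ValueError("genome has no residues (coverage-only genome)")
        check_interval(start, stop, self.length)
        return self.residues[start - 1 : stop]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature: gene, tRNA, rRNA, or intron."""

    name: str
    start: int
    stop: int
    strand: str
    kind: str = "other"
    category: str = "misc_protein"
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise AnnotationError(f"{self.name}: bad strand {self.strand!r}")
        if self.start > self.stop or self.start < 1:
            raise AnnotationError(f"{self.name}: bad coordinates {self.start}-{self.stop}")
        if self.kind not in GENE_KINDS:
            raise AnnotationError(f"{self.name}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    def five_prime(self) -> int:
        """Coordinate of the 5'-terminal base (strand-aware)."""
        return self.start if self.strand == "+" else self.stop

    def three_prime(self) -> int:
        """Coordinate of the 3'-terminal base (strand-aware)."""
        return self.stop if self.strand == "+" else self.start

    def overlaps(self, start: int, stop: int) -> bool:
        return self.start <= stop and start <= self.stop


def check_interval(start: int, stop: int, genome_length: int | None = None) -> None:
    if start > stop:
        raise CoordinateError(f"inverted interval ({start} > {stop})")
    if start < 1:
        raise CoordinateError(f"interval start {start} < 1")
    if genome_length is not None and stop > genome_length:
        raise CoordinateError(f"interval stop {stop} > genome length {genome_length}")


class Annotation:
    """Sorted gene features over one genome, with strand-aware overlap queries."""

    def __init__(self, genome_length: int, features: Iterable[GeneFeature]):
        self.genome_length = int(genome_length)
        self.features: list[GeneFeature] = sorted(features, key=lambda f: (f.start, f.stop))
        self._tree = IntervalTree()
        for i, f in enumerate(self.features):
            if f.stop > self.genome_length:
                raise AnnotationError(
                    f"{f.name}: stop {f.stop} exceeds genome length {self.genome_length}"
                )
            # half-open for the tree; +1 restores inclusive stop
            self._tree.addi(f.start, f.stop + 1, i)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def features_overlapping(
        self, start: int, stop: int, strand_mode: str = "both"
    ) -> list[GeneFeature]:
        """Features intersecting [start, stop] by >= 1 nt, filtered by strand.

        ``strand_mode`` is ``both``, ``same:+``, ``same:-``, ``opposite-of:+``
        or ``opposite-of:-``; results are ordered by start coordinate.
        """
        check_interval(start, stop, self.genome_length)
        want = _strand_filter(strand_mode)
        hits = [self.features[iv.data] for iv in self._tree.overlap(start, stop + 1)]
        hits = [f for f in hits if want is None or f.strand == want]
        return sorted(hits, key=lambda f: (f.start, f.stop))

    def clusters(self) -> dict[str, list[GeneFeature]]:
        """Features grouped by cluster_id (operon / transcription unit)."""
        out: dict[str, list[GeneFeature]] = {}
        for f in self.features:
            if f.cluster_id is not None:
                out.setdefault(f.cluster_id, []).append(f)
        return out


def _strand_filter(mode: str) -> str | None:
    if mode == "both":
        return None
    try:
        rel, strand = mode.split(":")
    except ValueError:
        raise ValueError(f"bad strand_mode {mode!r}") from None
    if strand not in STRANDS or rel not in ("same", "opposite-of"):
        raise ValueError(f"bad strand_mode {mode!r}")
    if rel == "same":
        return strand
    return "-" if strand == "+" else "+"


# ---------------------------------------------------------------------------
# category map

_DEFAULT_CATEGORY_RESOURCE = "gene_categories.tsv"


def load_category_map(stream: IO[str] | None = None) -> dict[str, str]:
    """Gene name -> functional category, from a 2-column TSV.

    With no argument, the packaged default map (chloroplast gene classes) is
    used. Unlisted genes fall back by kind: tRNA/rRNA by their kind,
    everything else ``misc_protein``.
    """
    if stream is None:
        ref = importlib.resources.files("plastidnc.data") / _DEFAULT_CATEGORY_RESOURCE
        text = ref.read_text()
    else:
        text = stream.read()
    out: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise AnnotationError(f"category map line {lineno}: expected 2 columns")
        name, cat = parts
        if cat not in CATEGORIES:
            raise AnnotationError(f"category map line {lineno}: unknown category {cat!r}")
        out[name] = cat
    return out


def categorize(name: str, kind: str, category_map: dict[str, str] | None = None) -> str:
    cmap = category_map if category_map is not None else {}
    if name in cmap:
        return cmap[name]
    base = name.split(".")[0].rstrip("0123456789")
    if base in cmap:
        return cmap[base]
    if kind == "tRNA":
        return "tRNA"
    if kind == "rRNA":
        return "rRNA"
    if name.startswith("ycf"):
        return "ycf"
    return "misc_protein"


# ---------------------------------------------------------------------------
# GFF3

_GFF_KIND = {
    "gene": "protein",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "intron": "intron",
}


def load_annotation(
    stream: IO[str] | Iterable[str],
    genome_length: int | None = None,
    category_map: dict[str, str] | None = None,
) -> Annotation:
    """Parse GFF3 into an :class:`Annotation`.

    One :class:`GeneFeature` is produced per gene/tRNA/rRNA/intron record;
    other feature types (exon, CDS, region, ...) are skipped. The declared
    ``##sequence-region`` length is used unless ``genome_length`` overrides
    it. Attributes ``ID``/``Name`` give the feature name, ``cluster_id`` (or
    ``Parent``) the transcription-unit label.
    """
    if category_map is None:
        category_map = load_category_map()
    declared = genome_length
    feats: list[GeneFeature] = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4 and declared is None:
                declared = int(parts[3])
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AnnotationError(f"GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
        _, _, ftype, start_s, stop_s, _, strand, _, attrs = cols
        if ftype not in _GFF_KIND:
            continue
        try:
            start, stop = int(start_s), int(stop_s)
        except ValueError:
            raise AnnotationError(f"GFF3 line {lineno}: non-integer coordinates") from None
        if strand not in STRANDS:
            raise AnnotationError(f"GFF3 line {lineno}: bad strand {strand!r}")
        attr = _parse_attributes(attrs, lineno)
        name = attr.get("Name") or attr.get("ID")
        if name is None:
            raise AnnotationError(f"GFF3 line {lineno}: feature has no ID or Name")
        cluster = attr.get("cluster_id") or attr.get("Parent")
        kind = _GFF_KIND[ftype]
        if declared is not None and stop > declared:
            raise AnnotationError(
                f"GFF3 line {lineno}: {name} stop {stop} exceeds region length {declared}"
            )
        feats.append(
            GeneFeature(
                name=name,
                start=start,
                stop=stop,
                strand=strand,
                kind=kind,
                category=categorize(name, kind, category_map),
                cluster_id=cluster,
            )
        )
    if declared is None:
        declared = max((f.stop for f in feats), default=1)
    return Annotation(declared, feats)


def _parse_attributes(attrs: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise AnnotationError(f"GFF3 line {lineno}: malformed attribute {item!r}")
        k, v = item.split("=", 1)
        out[k] = v
    return out


_KIND_GFF = {v: k for k, v in _GFF_KIND.items()}


def write_gff3(ann: Annotation, stream: IO[str], seqid: str = "plastome") -> None:
    """Write an annotation back to GFF3 (round-trips with load_annotation)."""
    stream.write("##gff-version 3\n")
    stream.write(f"##sequence-region {seqid} 1 {ann.genome_length}\n")
    for f in ann.features:
        attrs = [f"ID={f.name}"]
        if f.cluster_id is not None:
            attrs.append(f"cluster_id={f.cluster_id}")
        stream.write(
            "\t".join(
                [
                    seqid,
                    "plastidnc",
                    _KIND_GFF[f.kind],
                    str(f.start),
                    str(f.stop),
                    ".",
                    f.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
            + "\n"
        )


def load_fasta(stream: IO[str], circular: bool = True) -> PlastomeSequence:
    """Read the first record of a FASTA stream as a plastome sequence."""
    from Bio import SeqIO

    record = next(SeqIO.parse(stream, "fasta"))
    seq = str(record.seq).upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise AnnotationError(f"non-nucleotide characters in FASTA: {sorted(bad)}")
    return PlastomeSequence(length=len(seq), residues=seq, circular=circular)


def write_fasta(genome: PlastomeSequence, stream: IO[str], name: str = "plastome") -> None:
    if genome.residues is None:
        raise ValueError("genome has no residues to write")
    stream.write(f">{name}\n")
    for i in range(0, genome.length, 70):
        stream.write(genome.residues[i : i + 70] + "\n")
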