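"""The published candidate catalog: 107 chloroplast ncRNAs with coordinates,
strand, and RT-PCR / RNA gel blot validation results.

The packaged fixture ``data/ncrna_catalog.tsv`` transcribes the published
table. Designation conventions: a plain gene name means antisense to that
gene; an ``int`` suffix marks an ncRNA between two coding regions
(intergenic within a cluster); an ``i`` suffix marks antisense to an
intron; ``-5'``/``-3'`` say which part of the coding region is
complementary; trailing ``-1``, ``-2`` ... distinguish multiple candidates
at one locus. Candidate sizes follow the endpoint-difference convention
(stop - start), under which the catalog's minimum is 48 nt and its mean
217 nt.

Blot band entries are kept as printed: a band list is comma-separated
sizes in kb, ``.`` means tested with no visible signal, ``NT`` not tested;
one entry is a smear annotation rather than a discrete size and is
retained verbatim (it still counts as a detected signal).
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from statistics import mean
from typing import IO, Iterable, Sequence

RTPCR_POSITIVE = "positive"
RTPCR_NEGATIVE = "negative"
NOT_TESTED = "not_tested"

_RTPCR_CODES = {"+": RTPCR_POSITIVE, "-": RTPCR_NEGATIVE, "NT": NOT_TESTED}
_RTPCR_SYMBOLS = {v: k for k, v in _RTPCR_CODES.items()}

_CATALOG_RESOURCE = "ncrna_catalog.tsv"
_HEADER = ["ordinal", "designation", "start", "stop", "strand", "rt_pcr", "wt_bands", "pnp_bands"]

_INTRON_RE = re.compile(r"i(-\d+)?$")
_FLOAT_RE = re.compile(r"^\d+(\.\d+)?$")


class CatalogError(ValueError):
    """Malformed catalog input."""


@dataclass(frozen=True)
class CatalogRecord:
    """One catalog row. ``wt_bands``/``pnp_bands`` are ``None`` when the
    candidate was not taken to the blot stage."""

    ordinal: int
    designation: str
    start: int
    stop: int
    strand: str
    rtpcr: str
    wt_bands: tuple[str, ...] | None
    pnp_bands: tuple[str, ...] | None

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise CatalogError(f"row {self.ordinal}: start must be < stop")
        if self.strand not in ("+", "-"):
            raise CatalogError(f"row {self.ordinal}: bad strand {self.strand!r}")
        if self.rtpcr not in _RTPCR_SYMBOLS:
            raise CatalogError(f"row {self.ordinal}: bad RT-PCR value {self.rtpcr!r}")
        if self.rtpcr == NOT_TESTED and (self.wt_bands is not None or self.pnp_bands is not None):
            raise CatalogError(f"row {self.ordinal}: untested candidate cannot have bands")

    @property
    def length(self) -> int:
        """Endpoint difference, the published size convention."""
        return self.stop - self.start

    @property
    def inclusive_length(self) -> int:
        return self.stop - self.start + 1

    @property
    def ncrna_class(self) -> str:
        return "intergenic" if "int" in self.designation else "antisense"

    @property
    def is_intronic(self) -> bool:
        """Antisense to an intron (``i`` suffix, before any ordinal)."""
        return self.ncrna_class == "antisense" and bool(_INTRON_RE.search(self.designation))

    @property
    def blot_detected(self) -> bool:
        return bool(self.wt_bands) or bool(self.pnp_bands)

    def band_sizes(self, genotype: str = "WT") -> list[float]:
        """Numeric band sizes (kb); non-numeric annotations are skipped."""
        bands = self.wt_bands if genotype == "WT" else self.pnp_bands
        if not bands:
            return []
        return [float(b) for b in bands if _FLOAT_RE.match(b)]


@dataclass(frozen=True)
class CatalogStats:
    n_total: int
    n_antisense: int
    n_intergenic: int
    n_intronic: int
    min_len: int
    max_len: int
    mean_len: float
    mean_inclusive_len: float
    n_rtpcr_tested: int
    n_rtpcr_positive: int
    n_blot_detected: int


def _parse_bands(cell: str, ordinal: int) -> tuple[str, ...] | None:
    cell = cell.strip()
    if cell == "NT":
        return None
    if cell in (".", ""):
        return ()
    return tuple(tok.strip() for tok in cell.split(",") if tok.strip())


def load_catalog(stream: IO[str] | None = None) -> list[CatalogRecord]:
    """Read a catalog TSV; with no argument, the packaged fixture."""
    if stream is None:
        ref = importlib.resources.files("plastidnc.data") / _CATALOG_RESOURCE
        lines = ref.read_text().splitlines()
    else:
        lines = stream.read().splitlines()
    if not lines:
        raise CatalogError("empty catalog stream (missing header)")
    header = lines[0].rstrip("\n").split("\t")
    if header != _HEADER:
        raise CatalogError(f"unexpected catalog header {header!r}")
    records: list[CatalogRecord] = []
    seen: set[int] = set()
    for raw in lines[1:]:
        if not raw.strip():
            continue
        cols = raw.split("\t")
        if len(cols) != len(_HEADER):
            raise CatalogError(f"catalog row {raw!r}: expected {len(_HEADER)} columns")
        try:
            ordinal = int(cols[0])
        except ValueError:
            raise CatalogError(f"catalog row with non-integer ordinal {cols[0]!r}") from None
        if ordinal in seen:
            raise CatalogError(f"duplicate ordinal {ordinal}")
        seen.add(ordinal)
        try:
            rec = CatalogRecord(
                ordinal=ordinal,
                designation=cols[1],
                start=int(cols[2]),
                stop=int(cols[3]),
                strand=cols[4],
                rtpcr=_RTPCR_CODES.get(cols[5], cols[5]),
                wt_bands=_parse_bands(cols[6], ordinal),
                pnp_bands=_parse_bands(cols[7], ordinal),
            )
        except (ValueError, CatalogError) as exc:
            raise CatalogError(f"row {ordinal}: {exc}") from None
        records.append(rec)
    return records


def write_catalog(records: Iterable[CatalogRecord], stream: IO[str]) -> None:
    stream.write("\t".join(_HEADER) + "\n")
    for r in records:

        def cell(bands):
            if bands is None:
                return "NT"
            return ",".join(bands) if bands else "."

        stream.write(
            "\t".join(
                [
                    str(r.ordinal),
                    r.designation,
                    str(r.start),
                    str(r.stop),
                    r.strand,
                    _RTPCR_SYMBOLS[r.rtpcr],
                    cell(r.wt_bands),
                    cell(r.pnp_bands),
                ]
            )
            + "\n"
        )


def catalog_statistics(records: Sequence[CatalogRecord]) -> CatalogStats:
    """Summary statistics over catalog rows (class split, size range,
    validation tallies)."""
    if not records:
        raise CatalogError("need at least one catalog record")
    lengths = [r.length for r in records]
    tested = [r for r in records if r.rtpcr != NOT_TESTED]
    return CatalogStats(
        n_total=len(records),
        n_antisense=sum(1 for r in records if r.ncrna_class == "antisense"),
        n_intergenic=sum(1 for r in records if r.ncrna_class == "intergenic"),
        n_intronic=sum(1 for r in records if r.is_intronic),
        min_len=min(lengths),
        max_len=max(lengths),
        mean_len=mean(lengths),
        mean_inclusive_len=mean(r.inclusive_length for r in records),
        n_rtpcr_tested=len(tested),
        n_rtpcr_positive=sum(1 for r in tested if r.rtpcr == RTPCR_POSITIVE),
        n_blot_detected=sum(1 for r in tested if r.blot_detected),
    )
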