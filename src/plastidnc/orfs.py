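"""Open-reading-frame scanning inside candidate ncRNAs.

Some ncRNAs inevitably contain small ORFs, fortuitous or functional, and in
the chloroplast two antisense species carry conserved ones; the scanner
reports them so candidates can be screened for coding potential. Scanning
is single-stranded: ORFs are found on the provided sequence only, and the
caller supplies the reverse complement for minus-strand candidates. Start
codon is ATG (alternative starts are configurable), stops are TAA/TAG/TGA
under the standard code, and codons containing N never match either.

``aa_length`` counts residues from the initial Met through the residue
before the stop, so a "49 amino acid ORF" spans 150 nt including its stop
codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from Bio.Seq import Seq

from .genome import PlastomeSequence
from .peaks import CandidateInterval

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = frozenset({"ATG"})
DEFAULT_MIN_AA = 20

_VALID = set("ACGTN")


@dataclass(frozen=True)
class OrfRecord:
    """One ORF, positioned 1-based within the scanned sequence.

    ``offset_start`` is the first base of the start codon, ``offset_stop``
    the last base of the stop codon; hence
    ``offset_stop - offset_start + 1 == 3 * (aa_length + 1)``.
    """

    offset_start: int
    offset_stop: int
    aa_length: int
    frame: int

    def __post_init__(self) -> None:
        assert self.offset_stop - self.offset_start + 1 == 3 * (self.aa_length + 1)
        assert self.aa_length >= 1
        assert self.frame in (1, 2, 3)


def find_orfs(
    seq: str,
    min_aa: int = DEFAULT_MIN_AA,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
) -> list[OrfRecord]:
    """All qualifying ORFs on the given strand of ``seq``.

    Per frame, each stop-delimited segment contributes at most one ORF, from
    its first start codon to the stop (non-nested); ORFs lacking an in-frame
    stop within the sequence are not reported. Results are sorted by
    ``offset_start``.
    """
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    out: list[OrfRecord] = []
    for frame in (1, 2, 3):
        start_pos: int | None = None  # 0-based codon start of the pending ORF
        for i in range(frame - 1, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                continue
            if codon in STOP_CODONS:
                if start_pos is not None:
                    aa = (i - start_pos) // 3
                    if aa >= min_aa:
                        out.append(
                            OrfRecord(
                                offset_start=start_pos + 1,
                                offset_stop=i + 3,
                                aa_length=aa,
                                frame=frame,
                            )
                        )
                start_pos = None
            elif start_pos is None and codon in start_codons:
                start_pos = i
    out.sort(key=lambda o: (o.offset_start, o.frame))
    return out


def translate_orf(seq: str, orf: OrfRecord) -> str:
    """Peptide of an ORF (without the stop), via the standard code."""
    nt = seq[orf.offset_start - 1 : orf.offset_stop - 3]
    return str(Seq(nt).translate())


def longest_orf_in_candidate(
    genome: PlastomeSequence,
    c: CandidateInterval,
    min_aa: int = DEFAULT_MIN_AA,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
) -> OrfRecord | None:
    """Longest ORF on the candidate's own strand, or None.

    The genomic interval is extracted 1-based inclusive and reverse
    complemented for minus-strand candidates, so offsets are positions
    within the candidate RNA (5' -> 3'). Ties break toward the smaller
    ``offset_start``.
    """
    if genome.residues is None:
        raise ValueError("ORF scanning needs genome residues")
    seq = genome.subsequence(c.start, c.stop)
    if c.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    orfs = find_orfs(seq, min_aa=min_aa, start_codons=start_codons)
    if not orfs:
        return None
    return min(orfs, key=lambda o: (-o.aa_length, o.offset_start))


def candidate_rna_sequence(genome: PlastomeSequence, c: CandidateInterval) -> str:
    """The candidate's RNA-equivalent DNA sequence, 5' -> 3'."""
    seq = genome.subsequence(c.start, c.stop)
    if c.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def write_orf_report(
    rows: Iterable[tuple[CandidateInterval, OrfRecord | None]], stream: IO[str]
) -> None:
    stream.write("candidate_id\tstrand\toffset_start\toffset_stop\taa_length\tframe\n")
    for c, orf in rows:
        if orf is None:
            stream.write(f"{c.id}\t{c.strand}\t.\t.\t.\t.\n")
        else:
            stream.write(
                f"{c.id}\t{c.strand}\t{orf.offset_start}\t{orf.offset_stop}\t"
                f"{orf.aa_length}\t{orf.frame}\n"
            )


def write_orf_peptides(
    rows: Iterable[tuple[CandidateInterval, OrfRecord]],
    genome: PlastomeSequence,
    stream: IO[str],
) -> None:
    for c, orf in rows:
        pep = translate_orf(candidate_rna_sequence(genome, c), orf)
        stream.write(f">{c.id}_orf{orf.offset_start} aa={orf.aa_length}\n{pep}\n")
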