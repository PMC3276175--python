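"""Synthetic plastome transcriptomes with known ground truth.

The generator emulates the transcriptional phenomena the pipeline must
cope with on a small (default 50 kb) circular toy plastome:

* gene clusters on both strands plus an inverted repeat whose two copies
  are reverse complements (reads falling inside one copy are placed in
  both, ``n_placements = 2``);
* sense transcription with inefficient termination: a fraction of sense
  molecules read through their terminator by a geometric 3' overhang;
* dedicated antisense transcription units, amplified ~4-fold in the
  ribonuclease (PNPase-null) mutant genotype, whose molecules also gain
  geometric 3' extensions;
* library construction: molecules are hydrolysed into fragments with a
  retention floor (~80 nt), sequenced as fixed-length (85 nt) reads;
* the ligation end-bias artifact: structured regions of a transcript are
  depleted from the library. Each planted unit draws structured spans at
  its termini and (for longer units) in its interior, each active with
  ``prob_structured_end``; reads overlapping an active span are dropped.
  Interior spans are what splits one transcript into several coverage
  peaks, the fragmentation artifact seen in the published data.

All randomness flows from a single ``numpy`` Generator per call, so a
fixed seed gives bit-identical placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .coverage import ReadPlacement, StrandedCoverage
from .genome import Annotation, GeneFeature, PlastomeSequence, categorize, load_category_map
from .peaks import CandidateInterval

WT = "WT"
MUTANT = "pnp1-1"

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class AntisenseUnit:
    """A planted noncoding transcription unit with its own promoter."""

    start: int
    stop: int
    strand: str
    mean_copies: float = 80.0
    has_own_promoter: bool = True
    #: absolute per-genotype copies; overrides mean_copies x amplification
    genotype_copies: Mapping[str, float] | None = None


@dataclass(frozen=True)
class GenotypeEffect:
    antisense_amplification: float = 1.0
    three_prime_extension: float = 0.0  # mean nt, geometric


@dataclass(frozen=True)
class EndSuppression:
    prob_structured_end: float = 0.3
    suppressed_span: int = 40
    #: one potential interior structured site per this many nt of transcript
    interior_spacing: int = 250


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 50_000
    gene_layout: tuple[GeneFeature, ...] = ()
    sense_expression: Mapping[str, float] = field(default_factory=dict)
    read_through_prob: float = 0.3
    read_through_mean: int = 150  # mean nt of terminator read-through
    antisense_units: tuple[AntisenseUnit, ...] = ()
    genotype_effects: Mapping[str, GenotypeEffect] = field(
        default_factory=lambda: {
            WT: GenotypeEffect(1.0, 0.0),
            MUTANT: GenotypeEffect(4.0, 60.0),
        }
    )
    read_length: int = 85
    min_fragment: int = 80
    target_fragment: int = 150  # mean hydrolysis fragment length
    end_suppression: EndSuppression = EndSuppression()
    inverted_repeat: tuple[tuple[int, int], tuple[int, int]] | None = None
    depth_target: int | None = None  # total reads; None = natural depth
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.read_through_prob, self.end_suppression.prob_structured_end):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.min_fragment < 1 or self.read_length < 1:
            raise ValueError("min_fragment and read_length must be positive")


@dataclass(frozen=True)
class PlantedUnit:
    """One transcription unit the simulator emits, with expected copies."""

    name: str
    start: int
    stop: int
    strand: str
    unit_class: str  # sense | antisense | intergenic
    copies: Mapping[str, float]
    read_through: bool = False  # sense units terminate inefficiently

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


@dataclass(frozen=True)
class GroundTruth:
    genome_length: int
    planted: tuple[PlantedUnit, ...]

    def of_class(self, unit_class: str) -> list[PlantedUnit]:
        return [u for u in self.planted if u.unit_class == unit_class]


# ---------------------------------------------------------------------------
# default study conditions


def default_gene_layout() -> tuple[GeneFeature, ...]:
    """A 50 kb toy plastome: 15 features in clusters on both strands, one
    intron, and an rRNA gene mirrored into the second inverted-repeat copy."""
    cmap = load_category_map()

    def g(name, start, stop, strand, kind, cluster):
        return GeneFeature(
            name, start, stop, strand, kind, categorize(name, kind, cmap), cluster
        )

    return (
        g("psbA", 1001, 2500, "+", "protein", "psbA"),
        g("trnK", 3201, 3290, "+", "tRNA", "trnK"),
        g("rps16", 4001, 4900, "+", "protein", "rps16"),
        g("ndhB", 5601, 7100, "+", "protein", "ndhB"),
        g("ndhB_intron", 6201, 6800, "+", "intron", "ndhB"),
        g("psaA", 9001, 11000, "-", "protein", "psaA-psaB"),
        g("psaB", 11501, 13500, "-", "protein", "psaA-psaB"),
        g("rbcL", 15001, 16400, "+", "protein", "rbcL"),
        g("accD", 17401, 18800, "+", "protein", "accD"),
        g("petA", 20001, 21000, "+", "protein", "petA-psbJ"),
        g("psbJ", 21801, 22300, "+", "protein", "petA-psbJ"),
        g("trnS", 24001, 24088, "+", "tRNA", "trnS"),
        g("ndhF", 26001, 28200, "-", "protein", "ndhF"),
        g("rpoB", 30001, 33000, "+", "protein", "rpoB"),
        g("clpP", 35001, 36000, "-", "protein", "clpP"),
        g("rrn16", 40501, 41990, "+", "rRNA", "rrnA"),
        # mirror of rrn16 in the second IR copy
        g("rrn16_b", 48011, 49500, "-", "rRNA", "rrnB"),
    )


DEFAULT_IR = ((40001, 44000), (46001, 50000))

#: mean transcript copies per sense gene in the default conditions;
#: rRNA is modest because the library is rRNA-depleted
DEFAULT_SENSE_COPIES = {"protein": 300.0, "tRNA": 200.0, "rRNA": 100.0}

DEFAULT_ANTISENSE_COPIES = 80.0


def _default_sense_expression(layout: Sequence[GeneFeature]) -> dict[str, float]:
    return {
        f.name: DEFAULT_SENSE_COPIES[f.kind]
        for f in layout
        if f.kind in DEFAULT_SENSE_COPIES
    }


def default_config(**overrides) -> SimulationConfig:
    """The default study conditions: 8 antisense units (one per major gene)
    and one intergenic unit inside the petA-psbJ cluster gap."""
    layout = default_gene_layout()
    units = (
        AntisenseUnit(1301, 1600, "-"),  # opposite psbA
        AntisenseUnit(5801, 6100, "-"),  # opposite ndhB (spans intron 5' part)
        AntisenseUnit(9501, 9800, "+"),  # opposite psaA
        AntisenseUnit(15201, 15500, "-"),  # opposite rbcL
        AntisenseUnit(23990, 24140, "-"),  # opposite trnS
        AntisenseUnit(26501, 26800, "+"),  # opposite ndhF
        AntisenseUnit(30501, 30800, "-"),  # opposite rpoB
        AntisenseUnit(35201, 35500, "+"),  # opposite clpP
        AntisenseUnit(21201, 21500, "-"),  # petA-psbJ intergenic gap
    )
    cfg = SimulationConfig(
        gene_layout=layout,
        sense_expression=_default_sense_expression(layout),
        antisense_units=units,
        inverted_repeat=DEFAULT_IR,
    )
    return replace(cfg, **overrides) if overrides else cfg


def recovery_scenario_config(**overrides) -> SimulationConfig:
    """Recovery benchmark: 20 antisense units (300 nt, mean 80 copies)
    planted opposite the long genes, end suppression off, modest sense
    expression. Used to score caller recall/precision against truth."""
    layout = default_gene_layout()
    hosts = {  # gene -> number of units planted opposite it
        "psbA": 2, "ndhB": 2, "psaA": 2, "psaB": 2, "rbcL": 2, "accD": 2,
        "ndhF": 2, "rpoB": 3, "clpP": 1, "petA": 1, "rps16": 1,
    }
    units = []
    for f in layout:
        k = hosts.get(f.name, 0)
        if not k:
            continue
        anti = "-" if f.strand == "+" else "+"
        # place k units of 300 nt evenly inside the gene
        span = f.stop - f.start + 1
        step = span // k
        for i in range(k):
            lo = f.start + i * step + (step - 300) // 2
            units.append(AntisenseUnit(lo, lo + 299, anti))
    sense = {name: 150.0 for name in _default_sense_expression(layout)}
    cfg = SimulationConfig(
        gene_layout=layout,
        sense_expression=sense,
        antisense_units=tuple(units),
        inverted_repeat=DEFAULT_IR,
        end_suppression=EndSuppression(prob_structured_end=0.0),
    )
    return replace(cfg, **overrides) if overrides else cfg


def mutant_only_scenario_config(**overrides) -> SimulationConfig:
    """Default conditions plus one unit below the peak threshold in the wild
    type (30 expected copies) but above it in the mutant (80)."""
    cfg = default_config()
    extra = AntisenseUnit(
        17601, 17900, "-", genotype_copies={WT: 30.0, MUTANT: 80.0}
    )  # opposite accD
    cfg = replace(cfg, antisense_units=cfg.antisense_units + (extra,))
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# genome + truth construction


def build_toy_plastome(
    cfg: SimulationConfig, seed: int
) -> tuple[PlastomeSequence, Annotation, GroundTruth]:
    """Random residues (IR copies reverse-complementary), annotation from
    the layout, and the planted-unit ground truth. Deterministic per seed."""
    _validate_layout(cfg)
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(list("ACGT"), size=cfg.genome_length))
    if cfg.inverted_repeat is not None:
        (a1, a2), (b1, b2) = cfg.inverted_repeat
        if (a2 - a1) != (b2 - b1):
            raise ValueError("inverted repeat copies differ in length")
        res = list(residues)
        res[b1 - 1 : b2] = _revcomp(residues[a1 - 1 : a2])
        residues = "".join(res)
    genome = PlastomeSequence(
        length=cfg.genome_length,
        residues=residues,
        circular=True,
        inverted_repeat=cfg.inverted_repeat,
    )
    ann = Annotation(cfg.genome_length, cfg.gene_layout)
    planted: list[PlantedUnit] = []
    for f in cfg.gene_layout:
        mean = cfg.sense_expression.get(f.name, 0.0)
        if mean <= 0 or f.kind == "intron":
            continue
        planted.append(
            PlantedUnit(
                name=f.name,
                start=f.start,
                stop=f.stop,
                strand=f.strand,
                unit_class="sense",
                copies={g: mean for g in cfg.genotype_effects},
                read_through=True,
            )
        )
    for i, u in enumerate(cfg.antisense_units):
        if not (1 <= u.start <= u.stop <= cfg.genome_length):
            raise ValueError(f"antisense unit {i} outside genome")
        opposite = ann.features_overlapping(u.start, u.stop, f"opposite-of:{u.strand}")
        cls = "antisense" if opposite else "intergenic"
        copies = {}
        for g, eff in cfg.genotype_effects.items():
            if u.genotype_copies is not None:
                copies[g] = float(u.genotype_copies[g])
            else:
                copies[g] = u.mean_copies * eff.antisense_amplification
        planted.append(
            PlantedUnit(
                name=f"unit_{i + 1:02d}",
                start=u.start,
                stop=u.stop,
                strand=u.strand,
                unit_class=cls,
                copies=copies,
            )
        )
    return genome, ann, GroundTruth(cfg.genome_length, tuple(planted))


def _validate_layout(cfg: SimulationConfig) -> None:
    by_strand: dict[str, list[GeneFeature]] = {"+": [], "-": []}
    for f in cfg.gene_layout:
        if f.stop > cfg.genome_length:
            raise ValueError(f"gene {f.name} outside genome")
        if f.kind != "intron":
            by_strand[f.strand].append(f)
    for strand, feats in by_strand.items():
        feats.sort(key=lambda f: f.start)
        for a, b in zip(feats[:-1], feats[1:]):
            if b.start <= a.stop:
                raise ValueError(
                    f"same-strand genes overlap: {a.name} and {b.name} on {strand}"
                )


# ---------------------------------------------------------------------------
# read simulation


def _geometric0(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Geometric on {0, 1, 2, ...} with the given mean."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    return rng.geometric(1.0 / (mean + 1.0), size=size) - 1


def _structured_spans(
    unit: PlantedUnit, cfg: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Genomic spans of this unit depleted by the ligation end-bias.

    Termini first (5' then 3', strand-aware), then interior sites at one
    potential site per ``interior_spacing`` nt of transcript. The caller
    passes a generator seeded from ``cfg.seed`` so that structure — a
    property of the transcript sequence — is shared across genotypes.
    """
    es = cfg.end_suppression
    p, s = es.prob_structured_end, es.suppressed_span
    if p <= 0:
        return []
    spans: list[tuple[int, int]] = []
    five = unit.start if unit.strand == "+" else unit.stop
    three = unit.stop if unit.strand == "+" else unit.start
    for t in (five, three):
        if rng.random() < p:
            if t == unit.start:
                spans.append((unit.start, min(unit.stop, unit.start + s - 1)))
            else:
                spans.append((max(unit.start, unit.stop - s + 1), unit.stop))
    n_interior = int(round(unit.length / es.interior_spacing))
    lo_min = unit.start + s
    hi_max = unit.stop - 2 * s
    for _ in range(n_interior):
        if hi_max <= lo_min:
            break
        a = int(rng.integers(lo_min, hi_max + 1))
        if rng.random() < p:
            spans.append((a, a + s - 1))
    return spans


def _simulate_read_arrays(
    truth: GroundTruth,
    cfg: SimulationConfig,
    genotype: str,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core sampler: (starts, stops, strand_is_plus) at the read level,
    before inverted-repeat mirroring and depth-target resampling."""
    if genotype not in cfg.genotype_effects:
        raise ValueError(f"unknown genotype {genotype!r}")
    eff = cfg.genotype_effects[genotype]
    rng = np.random.default_rng(seed)
    # secondary structure belongs to the RNA, not the library prep: draw it
    # from the config seed so both genotypes share the same blocked spans
    rng_struct = np.random.default_rng((int(cfg.seed), 0xC0FFEE))
    rl = cfg.read_length
    glen = cfg.genome_length
    starts: list[np.ndarray] = []
    stops: list[np.ndarray] = []
    strands: list[np.ndarray] = []
    for unit in truth.planted:
        blocked = _structured_spans(unit, cfg, rng_struct)
        n_mol = int(rng.poisson(unit.copies.get(genotype, 0.0)))
        if n_mol == 0:
            continue
        ext = _geometric0(rng, eff.three_prime_extension, n_mol)
        if unit.read_through and cfg.read_through_prob > 0:
            rt = rng.random(n_mol) < cfg.read_through_prob
            ext = ext + np.where(rt, _geometric0(rng, cfg.read_through_mean, n_mol), 0)
        u_starts: list[int] = []
        u_stops: list[int] = []
        for e in ext:
            if unit.strand == "+":
                mlo, mhi = unit.start, min(glen, unit.stop + int(e))
            else:
                mlo, mhi = max(1, unit.start - int(e)), unit.stop
            mlen = mhi - mlo + 1
            if mlen < cfg.min_fragment:
                continue
            k = max(1, round(mlen / cfg.target_fragment))
            k = min(k, mlen // cfg.min_fragment)
            extra = mlen - k * cfg.min_fragment
            if k == 1:
                flens = np.array([mlen], dtype=np.int64)
            else:
                # uniform breakpoints with a min_fragment floor: distribute the
                # slack by a uniform composition (sorted uniform cuts)
                cuts = np.sort(rng.integers(0, extra + 1, size=k - 1))
                parts = np.diff(np.concatenate(([0], cuts, [extra])))
                flens = parts + cfg.min_fragment
            fstarts = mlo + np.concatenate(([0], np.cumsum(flens[:-1])))
            for fs, fl in zip(fstarts, flens):
                n_r = max(1, round(fl / rl))
                if fl <= rl:
                    offs = np.zeros(n_r, dtype=np.int64)
                    r_len = fl
                else:
                    offs = rng.integers(0, fl - rl + 1, size=n_r)
                    r_len = rl
                for off in offs:
                    r0 = int(fs + off)
                    r1 = r0 + int(r_len) - 1
                    if any(r0 <= hi and lo <= r1 for lo, hi in blocked):
                        continue
                    u_starts.append(r0)
                    u_stops.append(r1)
        if u_starts:
            starts.append(np.array(u_starts, dtype=np.int64))
            stops.append(np.array(u_stops, dtype=np.int64))
            strands.append(np.full(len(u_starts), unit.strand == "+"))
    if not starts:
        empty = np.array([], dtype=np.int64)
        return empty, empty.copy(), np.array([], dtype=bool)
    s0 = np.concatenate(starts)
    s1 = np.concatenate(stops)
    pl = np.concatenate(strands)
    if cfg.depth_target is not None:
        n = len(s0)
        if cfg.depth_target == 0:
            return s0[:0], s1[:0], pl[:0]
        idx = rng.choice(n, size=cfg.depth_target, replace=cfg.depth_target > n)
        idx.sort()
        s0, s1, pl = s0[idx], s1[idx], pl[idx]
    return s0, s1, pl


def _mirror_ir(
    starts: np.ndarray,
    stops: np.ndarray,
    plus: np.ndarray,
    ir: tuple[tuple[int, int], tuple[int, int]] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Add the second placement for reads wholly inside one IR copy.

    Returns (starts, stops, plus, n_placements, origin) with mirrored
    placements appended; ``origin[j]`` is the read index each placement
    belongs to. The mirror of a read at offset d from one copy's end sits
    at offset d from the other copy's start, on the opposite strand.
    """
    n = len(starts)
    npl = np.ones(n, dtype=np.int64)
    origin = np.arange(n, dtype=np.int64)
    if ir is None or n == 0:
        return starts, stops, plus, npl, origin
    (a1, a2), (b1, b2) = ir
    add_s, add_e, add_p, mirrored = [], [], [], []
    for (lo, hi), (olo, _ohi) in (((a1, a2), (b1, b2)), ((b1, b2), (a1, a2))):
        inside = np.flatnonzero((starts >= lo) & (stops <= hi))
        for i in inside:
            add_s.append(olo + (hi - stops[i]))
            add_e.append(olo + (hi - starts[i]))
            add_p.append(not plus[i])
            mirrored.append(int(i))
    if not mirrored:
        return starts, stops, plus, npl, origin
    npl[np.array(mirrored)] = 2
    starts = np.concatenate([starts, np.array(add_s, dtype=np.int64)])
    stops = np.concatenate([stops, np.array(add_e, dtype=np.int64)])
    plus = np.concatenate([plus, np.array(add_p, dtype=bool)])
    npl = np.concatenate([npl, np.full(len(add_s), 2, dtype=np.int64)])
    origin = np.concatenate([origin, np.array(mirrored, dtype=np.int64)])
    return starts, stops, plus, npl, origin


def simulate_placements(
    genome: PlastomeSequence,
    truth: GroundTruth,
    cfg: SimulationConfig,
    genotype: str,
    seed: int,
) -> list[ReadPlacement]:
    """Simulate one genotype's library as accepted read placements."""
    s0, s1, pl = _simulate_read_arrays(truth, cfg, genotype, seed)
    s0, s1, pl, npl, origin = _mirror_ir(s0, s1, pl, cfg.inverted_repeat)
    return [
        ReadPlacement(
            read_id=f"{genotype}_r{int(origin[i]):07d}",
            start=int(s0[i]),
            stop=int(s1[i]),
            strand="+" if pl[i] else "-",
            n_placements=int(npl[i]),
        )
        for i in range(len(s0))
    ]


def simulate_coverage(
    genome: PlastomeSequence,
    truth: GroundTruth,
    cfg: SimulationConfig,
    genotype: str,
    seed: int,
) -> StrandedCoverage:
    """Fast path: coverage tracks directly from the simulated read arrays.

    Equivalent to building coverage from :func:`simulate_placements` with
    full multi-placement weight.
    """
    s0, s1, pl = _simulate_read_arrays(truth, cfg, genotype, seed)
    s0, s1, pl, _npl, _origin = _mirror_ir(s0, s1, pl, cfg.inverted_repeat)
    glen = cfg.genome_length
    tracks = {}
    starts_tracks = {}
    n_placed = {}
    for strand, mask in (("+", pl), ("-", ~pl)):
        sel0, sel1 = s0[mask], s1[mask]
        diff = np.zeros(glen + 1, dtype=np.float64)
        np.add.at(diff, sel0 - 1, 1.0)
        np.add.at(diff, sel1, -1.0)
        tracks[strand] = np.cumsum(diff[:-1])
        st = np.zeros(glen, dtype=np.float64)
        np.add.at(st, sel0 - 1, 1.0)
        starts_tracks[strand] = st
        n_placed[strand] = float(mask.sum())
    return StrandedCoverage(
        genome_length=glen,
        depth_plus=tracks["+"],
        depth_minus=tracks["-"],
        starts_plus=starts_tracks["+"],
        starts_minus=starts_tracks["-"],
        n_placements_plus=n_placed["+"],
        n_placements_minus=n_placed["-"],
    )


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass(frozen=True)
class RecoveryResult:
    precision: float
    recall: float
    fragmentation_ratio: float
    n_candidates: int
    n_units: int
    no_candidates: bool = False


def _jaccard(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> float:
    inter = min(a_hi, b_hi) - max(a_lo, b_lo) + 1
    if inter <= 0:
        return 0.0
    union = max(a_hi, b_hi) - min(a_lo, b_lo) + 1
    return inter / union


def evaluate_recovery(
    candidates: Sequence[CandidateInterval],
    units: Sequence[PlantedUnit],
    min_jaccard: float = 0.5,
) -> RecoveryResult:
    """Score called candidates against planted units.

    A unit is recovered when >= 1 same-strand candidate matches it at
    Jaccard >= ``min_jaccard``; precision is the fraction of candidates
    matching some unit; the fragmentation ratio is (candidates overlapping
    any unit by >= 1 nt, same strand) / (recovered units) and exceeds 1
    when transcripts are split into several peaks. With no candidates,
    precision is reported as 1.0 with ``no_candidates`` set; with no
    recovered units the ratio is NaN.
    """
    n_units = len(units)
    if not candidates:
        return RecoveryResult(1.0, 0.0 if n_units else 1.0, float("nan"), 0, n_units, True)
    recovered = 0
    for u in units:
        if any(
            c.strand == u.strand
            and _jaccard(c.start, c.stop, u.start, u.stop) >= min_jaccard
            for c in candidates
        ):
            recovered += 1
    matched = sum(
        1
        for c in candidates
        if any(
            c.strand == u.strand
            and _jaccard(c.start, c.stop, u.start, u.stop) >= min_jaccard
            for u in units
        )
    )
    overlapping = sum(
        1
        for c in candidates
        if any(c.strand == u.strand and c.overlaps(u.start, u.stop) for u in units)
    )
    precision = matched / len(candidates)
    recall = recovered / n_units if n_units else 1.0
    ratio = overlapping / recovered if recovered else float("nan")
    return RecoveryResult(precision, recall, ratio, len(candidates), n_units)
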