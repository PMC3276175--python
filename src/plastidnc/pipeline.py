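"""End-to-end orchestration: coverage -> call -> classify -> quantify -> report.

The pipeline is configured by a flat key=value text file (or an equivalent
dict). Recognised keys:

    genotype.<NAME>     path to that genotype's placements (tabular or SAM)
    annotation          path to the GFF3 annotation
    genome_length       genome length in nt (optional if the GFF3 declares it)
    genome_fasta        optional FASTA (enables ORF scanning)
    priority            comma-separated genotype order for end assignment
    wild_type, mutant   genotype names for fold changes (default: priority order)
    peak_threshold, end_threshold, merge_gap   caller thresholds
    window_5p, window_3p                        pairing-region windows
    min_orf_aa          minimum ORF length in amino acids (default 20)
    out_dir             output directory

Outputs: candidates.bed, candidates.tsv, classified.tsv, classified.gff3,
abundance.tsv, orfs.tsv (when a FASTA is given), and summary.txt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import plastidnc.classify as _classify

from . import compare, coverage, orfs, peaks
from .genome import Annotation, PlastomeSequence, load_annotation, load_fasta
from .simulate import RecoveryResult

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict[str, str]:
    """Parse the flat key=value config format (# comments, blank lines ok)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"config line {lineno}: expected key=value")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


@dataclass
class ReportBundle:
    out_dir: Path
    candidates: list[peaks.CandidateInterval]
    classified: list[_classify.ClassifiedNcRNA]
    rejected: list[_classify.Rejection]
    abundance: list[compare.AbundanceRecord]
    summary: dict[str, float | int | str]
    files: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: Mapping[str, str] | str | Path) -> ReportBundle:
    """Execute the full discovery pipeline from a config mapping or file."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    cfg = dict(config)

    genotype_paths = {
        k.split(".", 1)[1]: v for k, v in cfg.items() if k.startswith("genotype.")
    }
    if not genotype_paths:
        raise ConfigError("no genotype.<NAME>=path entries in config")
    ann_path = cfg.get("annotation")
    if ann_path is None:
        raise ConfigError("config needs annotation=<gff3 path>")
    for p in list(genotype_paths.values()) + [ann_path]:
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")

    glen = int(cfg["genome_length"]) if "genome_length" in cfg else None
    with open(ann_path) as fh:
        ann = load_annotation(fh, genome_length=glen)
    glen = ann.genome_length

    priority = (
        [g.strip() for g in cfg["priority"].split(",")]
        if "priority" in cfg
        else list(genotype_paths)
    )
    caller_cfg = peaks.CallerConfig(
        peak_threshold=int(cfg.get("peak_threshold", 50)),
        end_threshold=int(cfg.get("end_threshold", 10)),
        merge_gap=int(cfg.get("merge_gap", 0)),
    )

    cov_by_genotype: dict[str, coverage.StrandedCoverage] = {}
    for g in priority:
        placements = coverage.load_placements(genotype_paths[g])
        cov = coverage.coverage_from_placements(placements, glen)
        if cov.genome_length != glen:
            raise ConfigError(f"genotype {g}: genome length mismatch")
        cov_by_genotype[g] = cov
        log.info("genotype %s: %d placements", g, len(placements))

    candidates = peaks.call_candidates(cov_by_genotype, caller_cfg, priority)
    classified, rejected = _classify.classify_all(
        candidates,
        ann,
        window_5p=int(cfg.get("window_5p", _classify.DEFAULT_WINDOW_5P)),
        window_3p=int(cfg.get("window_3p", _classify.DEFAULT_WINDOW_3P)),
    )
    log.info(
        "called %d candidates; %d kept (%d rejected)",
        len(candidates),
        len(classified),
        len(rejected),
    )
    kept = [cls.candidate for cls in classified]

    wild_type = cfg.get("wild_type", priority[0])
    mutant = cfg.get("mutant", priority[-1])
    abundance = compare.quantify(kept, cov_by_genotype, wild_type, mutant)

    antisense_ids = {
        cls.candidate.id for cls in classified if cls.ncrna_class == "antisense"
    }
    as_records = [r for r in abundance if r.candidate_id in antisense_ids]
    ratio = (
        compare.global_antisense_ratio(as_records, wild_type, mutant)
        if as_records and len(cov_by_genotype) > 1
        else float("nan")
    )
    mutant_only = compare.genotype_specific(kept, mutant) if mutant in cov_by_genotype else []

    lengths = [c.length for c in kept]
    summary: dict[str, float | int | str] = {
        "n_candidates": len(kept),
        "n_antisense": sum(1 for c in classified if c.ncrna_class == "antisense"),
        "n_intergenic": sum(1 for c in classified if c.ncrna_class == "intergenic"),
        "n_rejected": len(rejected),
        "min_length": min(lengths) if lengths else 0,
        "max_length": max(lengths) if lengths else 0,
        "mean_length": sum(lengths) / len(lengths) if lengths else 0.0,
        "n_mutant_only": len(mutant_only),
        "global_antisense_ratio": ratio,
        "wild_type": wild_type,
        "mutant": mutant,
    }

    out_dir = Path(cfg.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def _write(name: str, writer) -> None:
        path = out_dir / name
        with open(path, "w") as fh:
            writer(fh)
        files[name] = path

    _write("candidates.bed", lambda fh: peaks.write_bed6(candidates, fh))
    _write("candidates.tsv", lambda fh: peaks.write_candidates_tsv(candidates, fh))
    _write("classified.tsv", lambda fh: _classify.write_classified_tsv(classified, fh))
    _write("classified.gff3", lambda fh: _classify.write_classified_gff3(classified, fh))
    _write("abundance.tsv", lambda fh: compare.write_abundance_tsv(abundance, fh))

    if "genome_fasta" in cfg:
        with open(cfg["genome_fasta"]) as fh:
            genome = load_fasta(fh)
        min_aa = int(cfg.get("min_orf_aa", orfs.DEFAULT_MIN_AA))
        rows = [(c, orfs.longest_orf_in_candidate(genome, c, min_aa)) for c in kept]
        _write("orfs.tsv", lambda fh: orfs.write_orf_report(rows, fh))

    _write("summary.txt", lambda fh: _write_summary(summary, fh))
    return ReportBundle(
        out_dir=out_dir,
        candidates=candidates,
        classified=classified,
        rejected=rejected,
        abundance=abundance,
        summary=summary,
        files=files,
    )


def _write_summary(summary: Mapping[str, object], fh) -> None:
    for k, v in summary.items():
        if isinstance(v, float):
            fh.write(f"{k}\t{v:.4f}\n")
        else:
            fh.write(f"{k}\t{v}\n")
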