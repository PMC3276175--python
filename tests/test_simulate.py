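import numpy as np
import pytest

from plastidnc.coverage import coverage_from_placements
from plastidnc.peaks import CallerConfig, CandidateInterval, call_candidates
from plastidnc.simulate import (
    MUTANT,
    WT,
    AntisenseUnit,
    EndSuppression,
    GeneFeature,
    PlantedUnit,
    SimulationConfig,
    build_toy_plastome,
    default_config,
    evaluate_recovery,
    mutant_only_scenario_config,
    recovery_scenario_config,
    simulate_coverage,
    simulate_placements,
)


def minimal_config(**kw):
    layout = (GeneFeature("gA", 1001, 2500, "+", "protein", "photosynthesis", "opA"),)
    base = dict(
        genome_length=10_000,
        gene_layout=layout,
        sense_expression={"gA": 100.0},
        antisense_units=(),
        read_through_prob=0.0,
        end_suppression=EndSuppression(prob_structured_end=0.0),
        inverted_repeat=None,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestBuildToyPlastome:
    def test_deterministic_for_fixed_seed(self):
        cfg = default_config()
        a = build_toy_plastome(cfg, 7)
        b = build_toy_plastome(cfg, 7)
        assert a[0].residues == b[0].residues
        assert a[2] == b[2]

    def test_no_antisense_units_gives_sense_only_truth(self):
        cfg = minimal_config()
        _, _, truth = build_toy_plastome(cfg, 1)
        assert {u.unit_class for u in truth.planted} == {"sense"}

    def test_planted_units_within_genome(self, rng):
        for i in range(10):
            n_units = int(rng.integers(0, 6))
            units = []
            for _ in range(n_units):
                lo = int(rng.integers(1, 9500))
                units.append(AntisenseUnit(lo, min(10_000, lo + 300), "-"))
            cfg = minimal_config(antisense_units=tuple(units))
            _, _, truth = build_toy_plastome(cfg, i)
            for u in truth.planted:
                assert 1 <= u.start <= u.stop <= cfg.genome_length

    def test_inverted_repeat_copies_are_reverse_complementary(self):
        cfg = default_config()
        genome, _, _ = build_toy_plastome(cfg, 7)
        (a1, a2), (b1, b2) = cfg.inverted_repeat
        comp = str.maketrans("ACGT", "TGCA")
        copy_a = genome.residues[a1 - 1 : a2]
        copy_b = genome.residues[b1 - 1 : b2]
        assert copy_b == copy_a.translate(comp)[::-1]

    def test_overlapping_same_strand_genes_rejected(self):
        layout = (
            GeneFeature("gA", 100, 500, "+", "protein"),
            GeneFeature("gB", 400, 900, "+", "protein"),
        )
        cfg = minimal_config(gene_layout=layout, sense_expression={"gA": 10, "gB": 10})
        with pytest.raises(ValueError, match="overlap"):
            build_toy_plastome(cfg, 0)

    def test_antisense_vs_intergenic_truth_classes(self):
        layout = (
            GeneFeature("gA", 1001, 2000, "+", "protein", "photosynthesis", "op"),
            GeneFeature("gB", 2501, 3500, "+", "protein", "photosynthesis", "op"),
        )
        units = (
            AntisenseUnit(1201, 1500, "-"),  # opposite gA
            AntisenseUnit(2101, 2400, "-"),  # in the gap
        )
        cfg = minimal_config(
            gene_layout=layout,
            sense_expression={"gA": 10, "gB": 10},
            antisense_units=units,
        )
        _, _, truth = build_toy_plastome(cfg, 0)
        classes = [u.unit_class for u in truth.planted if u.unit_class != "sense"]
        assert classes == ["antisense", "intergenic"]


class TestSimulatePlacements:
    def test_deterministic_placements(self):
        cfg = default_config()
        genome, _, truth = build_toy_plastome(cfg, 7)
        a = simulate_placements(genome, truth, cfg, WT, 3)
        b = simulate_placements(genome, truth, cfg, WT, 3)
        assert a == b

    def test_depth_target_zero_is_empty(self):
        cfg = minimal_config(depth_target=0)
        genome, _, truth = build_toy_plastome(cfg, 1)
        assert simulate_placements(genome, truth, cfg, WT, 1) == []

    def test_depth_target_sets_read_count(self):
        cfg = minimal_config(depth_target=500, inverted_repeat=None)
        genome, _, truth = build_toy_plastome(cfg, 1)
        pl = simulate_placements(genome, truth, cfg, WT, 1)
        assert len(pl) == 500

    def test_single_gene_no_read_through_stays_in_span(self):
        cfg = minimal_config()
        genome, _, truth = build_toy_plastome(cfg, 1)
        pl = simulate_placements(genome, truth, cfg, WT, 2)
        assert pl
        for p in pl:
            assert p.strand == "+"
            assert 1001 <= p.start <= p.stop <= 2500

    def test_mutant_extensions_go_past_three_prime_end(self):
        cfg = minimal_config()
        genome, _, truth = build_toy_plastome(cfg, 1)
        pl = simulate_placements(genome, truth, cfg, MUTANT, 2)
        assert max(p.stop for p in pl) > 2500
        assert min(p.start for p in pl) >= 1001  # 5' end untouched

    def test_unknown_genotype_rejected(self):
        cfg = minimal_config()
        genome, _, truth = build_toy_plastome(cfg, 1)
        with pytest.raises(ValueError, match="genotype"):
            simulate_placements(genome, truth, cfg, "nonesuch", 1)

    def test_inverted_repeat_reads_doubly_placed(self):
        cfg = default_config()
        genome, _, truth = build_toy_plastome(cfg, 7)
        pl = simulate_placements(genome, truth, cfg, WT, 5)
        doubles = [p for p in pl if p.n_placements == 2]
        assert doubles
        (a1, a2), (b1, b2) = cfg.inverted_repeat
        by_id = {}
        for p in doubles:
            by_id.setdefault(p.read_id, []).append(p)
        for pair in by_id.values():
            assert len(pair) == 2
            p, q = sorted(pair, key=lambda x: x.start)
            assert a1 <= p.start <= p.stop <= a2
            assert b1 <= q.start <= q.stop <= b2
            assert p.strand != q.strand
            # mirrored offsets match
            assert p.start - a1 == b2 - q.stop

    def test_simulate_coverage_equals_placement_coverage(self):
        cfg = default_config()
        genome, _, truth = build_toy_plastome(cfg, 7)
        pl = simulate_placements(genome, truth, cfg, WT, 9)
        via_placements = coverage_from_placements(pl, cfg.genome_length)
        direct = simulate_coverage(genome, truth, cfg, WT, 9)
        np.testing.assert_array_equal(direct.depth_plus, via_placements.depth_plus)
        np.testing.assert_array_equal(direct.depth_minus, via_placements.depth_minus)
        np.testing.assert_array_equal(direct.starts_plus, via_placements.starts_plus)
        np.testing.assert_array_equal(direct.starts_minus, via_placements.starts_minus)


def unit(lo, hi, strand="+", cls="antisense"):
    return PlantedUnit("u", lo, hi, strand, cls, {WT: 80.0})


def cand(lo, hi, strand="+", cid="c"):
    return CandidateInterval(
        id=cid, start=lo, stop=hi, strand=strand,
        trigger_genotypes=frozenset({WT}), end_source=WT, max_depth={WT: 80.0},
    )


class TestEvaluateRecovery:
    def test_perfect_match(self):
        units = [unit(100, 400), unit(600, 900)]
        cands = [cand(100, 400, cid="a"), cand(600, 900, cid="b")]
        res = evaluate_recovery(cands, units)
        assert (res.precision, res.recall, res.fragmentation_ratio) == (1.0, 1.0, 1.0)

    def test_no_candidates_convention(self):
        res = evaluate_recovery([], [unit(100, 400)])
        assert res.no_candidates
        assert res.precision == 1.0
        assert res.recall == 0.0

    def test_strand_must_match(self):
        res = evaluate_recovery([cand(100, 400, strand="-")], [unit(100, 400, "+")])
        assert res.recall == 0.0

    @pytest.mark.parametrize(
        "left,right,expect_recovered",
        [
            # unit 1..300 split into two pieces; hand-computed Jaccards
            ((1, 150), (151, 300), True),   # 150/300 = 0.5 exactly, >= holds
            ((1, 200), (201, 300), True),   # 200/300
            ((1, 140), (161, 300), False),  # 140/300 and 140/300, both < 0.5
            ((1, 90), (121, 300), True),    # right piece 180/300
            ((1, 40), (81, 300), True),     # right piece 220/300
        ],
    )
    def test_split_units_hand_computed_jaccard(self, left, right, expect_recovered):
        u = unit(1, 300)
        pieces = [cand(*left, cid="a"), cand(*right, cid="b")]
        res = evaluate_recovery(pieces, [u])

        def jac(p):
            inter = min(p[1], 300) - max(p[0], 1) + 1
            union = max(p[1], 300) - min(p[0], 1) + 1
            return inter / union

        assert (max(jac(left), jac(right)) >= 0.5) == expect_recovered
        assert (res.recall == 1.0) == expect_recovered
        if expect_recovered:
            assert res.fragmentation_ratio == 2.0  # both pieces overlap the unit

    def test_exact_half_jaccard_counts(self):
        # Jaccard exactly 0.5 satisfies the >= threshold
        u = unit(1, 300)
        res = evaluate_recovery([cand(1, 150, cid="a")], [u])
        assert res.recall == 1.0


class TestScenarioConfigs:
    def test_recovery_config_has_20_antisense_units(self):
        cfg = recovery_scenario_config()
        _, _, truth = build_toy_plastome(cfg, 7)
        assert len(truth.of_class("antisense")) == 20
        assert cfg.end_suppression.prob_structured_end == 0.0
        for u in truth.of_class("antisense"):
            assert u.copies[WT] >= 60.0

    def test_mutant_only_config_plants_asymmetric_unit(self):
        cfg = mutant_only_scenario_config()
        _, _, truth = build_toy_plastome(cfg, 7)
        asym = [
            u for u in truth.planted
            if u.unit_class != "sense" and u.copies[WT] != u.copies[MUTANT] / 4.0
        ]
        target = [u for u in asym if u.copies[WT] == 30.0 and u.copies[MUTANT] == 80.0]
        assert len(target) == 1

    def test_default_config_amplification_is_fourfold(self):
        cfg = default_config()
        assert cfg.genotype_effects[MUTANT].antisense_amplification == 4.0
        assert cfg.genotype_effects[WT].antisense_amplification == 1.0
        _, _, truth = build_toy_plastome(cfg, 7)
        for u in truth.planted:
            if u.unit_class != "sense":
                assert u.copies[MUTANT] == 4.0 * u.copies[WT]
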