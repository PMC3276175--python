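import numpy as np
import pytest

from plastidnc.coverage import StrandedCoverage
from plastidnc.peaks import (
    CallerConfig,
    CandidateInterval,
    call_candidates,
    call_strand_candidates,
    interval_length,
    merge_adjacent,
)


def brute_force_runs(depth, peak=50, end=10):
    """Independent oracle: enumerate maximal >=end runs containing a >=peak base."""
    runs = []
    i = 0
    n = len(depth)
    while i < n:
        if depth[i] >= end:
            j = i
            while j + 1 < n and depth[j + 1] >= end:
                j += 1
            peak_depth = max(depth[i : j + 1])
            if peak_depth >= peak:
                runs.append((i + 1, j + 1, float(peak_depth)))
            i = j + 1
        else:
            i += 1
    return runs


def make_cov(depth_plus, depth_minus=None, genome_length=None):
    dp = np.asarray(depth_plus, dtype=float)
    n = genome_length or len(dp)
    dm = np.zeros(n) if depth_minus is None else np.asarray(depth_minus, dtype=float)
    return StrandedCoverage(n, dp, dm)


class TestCallStrandCandidates:
    def test_all_zero_is_empty(self):
        assert call_strand_candidates(np.zeros(500)) == []

    def test_plateau_run(self):
        d = np.zeros(300)
        d[99:199] = 60
        assert call_strand_candidates(d) == [(100, 199, 60.0)]

    def test_specified_composite_track(self):
        d = np.zeros(200)
        d[0:50] = 20
        d[50:60] = 55
        d[60:120] = 12
        d[120] = 5
        d[121:200] = 60
        got = call_strand_candidates(d)
        assert got == [(1, 120, 55.0), (122, 200, 60.0)]
        assert got == brute_force_runs(d)

    def test_thresholds_are_inclusive(self):
        # depth exactly 50 triggers; depth exactly 10 belongs to a run;
        # depth 9 terminates it
        d = np.array([9.0, 10.0, 50.0, 10.0, 9.0])
        assert call_strand_candidates(d) == [(2, 4, 50.0)]

    def test_matches_brute_force_on_random_tracks(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 2000))
            d = rng.integers(0, 101, size=n).astype(float)
            assert call_strand_candidates(d) == brute_force_runs(d)

    def test_threshold_monotonicity(self, rng):
        for _ in range(30):
            d = rng.integers(0, 101, size=500).astype(float)
            base = call_strand_candidates(d, CallerConfig(50, 10))
            higher = call_strand_candidates(d, CallerConfig(70, 10))
            assert len(higher) <= len(base)
            # lowering the end threshold only widens spans
            wider = call_strand_candidates(d, CallerConfig(50, 5))
            for lo, hi, _ in base:
                assert any(wlo <= lo and hi <= whi for wlo, whi, _ in wider)


def brute_force_two_genotype(cov_by_g, priority, peak=50, end=10):
    """Direct restatement of the multi-genotype rule, per strand."""
    out = []
    for strand in "+-":
        runs = {
            g: brute_force_runs(cov_by_g[g].depth(strand), peak, end)
            for g in priority
        }
        flat = sorted(
            (lo, hi, g) for g, rr in runs.items() for lo, hi, _ in rr
        )
        # group by transitive >=1nt overlap
        groups = []
        for lo, hi, g in flat:
            if groups and lo <= groups[-1]["hi"]:
                groups[-1]["items"].append((g, lo, hi))
                groups[-1]["hi"] = max(groups[-1]["hi"], hi)
            else:
                groups.append({"hi": hi, "items": [(g, lo, hi)]})
        for grp in groups:
            present = {g for g, *_ in grp["items"]}
            source = next(g for g in priority if g in present)
            for g, lo, hi in sorted(grp["items"], key=lambda t: (t[1], t[2])):
                if g != source:
                    continue
                md = {
                    gt: float(cov_by_g[gt].depth(strand)[lo - 1 : hi].max())
                    for gt in priority
                }
                out.append(
                    (
                        strand,
                        lo,
                        hi,
                        source,
                        frozenset(gt for gt, v in md.items() if v >= peak),
                    )
                )
    return sorted(out, key=lambda t: (t[1], t[2], t[0]))


class TestCallCandidates:
    def test_single_genotype_lifts_strand_calls(self, rng):
        d = rng.integers(0, 101, size=800).astype(float)
        cov = make_cov(d)
        got = call_candidates({"WT": cov})
        runs = call_strand_candidates(d)
        assert [(c.start, c.stop) for c in got if c.strand == "+"] == [
            (lo, hi) for lo, hi, _ in runs
        ]
        assert all(c.end_source == "WT" for c in got)
        assert all(c.trigger_genotypes == {"WT"} for c in got)

    def test_wild_type_end_precedence(self):
        wt = np.zeros(400)
        wt[99:200] = 60
        mut = np.zeros(400)
        mut[94:230] = 80
        cov = {"WT": make_cov(wt), "pnp1-1": make_cov(mut)}
        (c,) = call_candidates(cov, genotype_priority=["WT", "pnp1-1"])
        assert (c.start, c.stop) == (100, 200)
        assert c.end_source == "WT"
        assert "WT" in c.trigger_genotypes

    def test_mutant_only_peak(self):
        wt = np.zeros(400)
        wt[99:200] = 30  # visible but below the trigger
        mut = np.zeros(400)
        mut[99:200] = 80
        cov = {"WT": make_cov(wt), "pnp1-1": make_cov(mut)}
        (c,) = call_candidates(cov, genotype_priority=["WT", "pnp1-1"])
        assert c.trigger_genotypes == {"pnp1-1"}
        assert c.end_source == "pnp1-1"

    def test_matches_two_genotype_brute_force(self, rng):
        priority = ["WT", "pnp1-1"]
        for _ in range(100):
            n = int(rng.integers(50, 600))
            cov = {
                g: make_cov(
                    rng.integers(0, 101, size=n).astype(float),
                    rng.integers(0, 101, size=n).astype(float),
                )
                for g in priority
            }
            got = call_candidates(cov, genotype_priority=priority)
            got_t = sorted(
                (c.strand, c.start, c.stop, c.end_source, c.trigger_genotypes)
                for c in got
            )
            oracle = sorted(brute_force_two_genotype(cov, priority))
            assert got_t == oracle

    def test_candidate_invariants_post_hoc(self, rng):
        priority = ["WT", "pnp1-1"]
        cfg = CallerConfig()
        for _ in range(20):
            n = 500
            cov = {
                g: make_cov(rng.integers(0, 101, size=n).astype(float))
                for g in priority
            }
            for c in call_candidates(cov, cfg, priority):
                track = cov[c.end_source].depth(c.strand)
                assert (track[c.start - 1 : c.stop] >= cfg.end_threshold).all()
                if c.start > 1:
                    assert track[c.start - 2] < cfg.end_threshold
                if c.stop < n:
                    assert track[c.stop] < cfg.end_threshold
                for g in c.trigger_genotypes:
                    assert c.max_depth[g] >= cfg.peak_threshold

    def test_per_strand_per_source_disjoint(self, rng):
        priority = ["WT", "pnp1-1"]
        cov = {
            g: make_cov(rng.integers(0, 101, size=1000).astype(float))
            for g in priority
        }
        got = call_candidates(cov, genotype_priority=priority)
        for strand in "+-":
            for src in priority:
                sel = sorted(
                    (c.start, c.stop)
                    for c in got
                    if c.strand == strand and c.end_source == src
                )
                for (a, b), (c2, d2) in zip(sel[:-1], sel[1:]):
                    assert b < c2

    def test_mismatched_genome_lengths_rejected(self):
        cov = {"WT": make_cov(np.zeros(100)), "pnp1-1": make_cov(np.zeros(200))}
        with pytest.raises(ValueError, match="length"):
            call_candidates(cov, genotype_priority=["WT", "pnp1-1"])


def make_candidate(lo, hi, strand="+", cid="c", trig=("WT",), depth=60.0):
    return CandidateInterval(
        id=cid,
        start=lo,
        stop=hi,
        strand=strand,
        trigger_genotypes=frozenset(trig),
        end_source="WT",
        max_depth={g: depth for g in trig},
    )


class TestMergeAdjacent:
    def test_zero_gap_is_identity(self):
        cands = [make_candidate(100, 200), make_candidate(203, 300)]
        assert merge_adjacent(cands, 0) == cands

    def test_small_gap_merges(self):
        cands = [make_candidate(100, 200, cid="a"), make_candidate(203, 300, cid="b")]
        (m,) = merge_adjacent(cands, 5)
        assert (m.start, m.stop) == (100, 300)

    def test_count_monotone_and_fixpoint_oracle(self, rng):
        for _ in range(30):
            spans = []
            pos = 1
            for _ in range(int(rng.integers(1, 15))):
                pos += int(rng.integers(1, 60))
                length = int(rng.integers(1, 80))
                spans.append((pos, pos + length))
                pos += length
            cands = [make_candidate(lo, hi, cid=f"c{i}") for i, (lo, hi) in enumerate(spans)]
            counts = []
            for gap in (0, 10, 50):
                merged = merge_adjacent(cands, gap)
                counts.append(len(merged))
                # iterative pairwise-merge oracle
                oracle = [list(s) for s in spans]
                changed = gap > 0
                while changed:
                    changed = False
                    for i in range(len(oracle) - 1):
                        if oracle[i + 1][0] - oracle[i][1] - 1 <= gap:
                            oracle[i][1] = max(oracle[i][1], oracle[i + 1][1])
                            del oracle[i + 1]
                            changed = True
                            break
                assert [(c.start, c.stop) for c in merged] == [tuple(s) for s in oracle]
            assert counts == sorted(counts, reverse=True)


class TestIntervalLength:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(74136, 74184, 48), (7611, 7691, 80), (500, 500, 0)],
    )
    def test_endpoint_difference_convention(self, lo, hi, expected):
        assert interval_length(make_candidate(lo, hi)) == expected
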