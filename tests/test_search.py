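"""Stochastic search, exact BFS oracle, scenario enumeration, breakpoints."""
import math

import numpy as np
import pytest

import dimsum as dm
from dimsum.arrangements import SignedArrangement
from dimsum.search import first_hit_lengths

from conftest import all_signed_arrangements


def arr(values):
    return SignedArrangement.from_signed_ints(values)


class TestExactMinDistance:
    @pytest.mark.parametrize(
        "source, target, flip, expected",
        [
            ([+1, +2, +3], [+1, +2, +3], False, 0),
            ([+1], [-1], False, 1),
            ([+1, +2, +3], [+3, -1, -2], False, 2),  # Typha -> Anomochloa LSC
            ([+1, +2], [+2, -1], False, 2),          # two-block LSC / SSC instances
            ([+1, +2], [-2, +1], False, 2),
            ([+1, +2], [+2, -1], True, 1),           # SSC under flip equivalence
            ([+1, +2], [-2, +1], True, 1),
        ],
    )
    def test_known_instances(self, source, target, flip, expected):
        assert dm.exact_min_distance(arr(source), arr(target), flip) == expected

    def test_capacity_error_above_cap(self):
        a = arr(list(range(1, 6)))
        with pytest.raises(dm.CapacityError):
            dm.exact_min_distance(a, a, cap=4)

    def test_flip_never_increases_distance(self, distances_by_n):
        for n in (1, 2, 3, 4):
            ident = arr(list(range(1, n + 1)))
            for t, d in distances_by_n[n].items():
                df = dm.exact_min_distance(ident, arr(list(t)), flip_equivalence=True)
                assert df <= d


class TestEnumerateMinimalScenarios:
    def test_identical_endpoints_give_empty_scenario(self):
        scs = dm.enumerate_minimal_scenarios(arr([+1, +2]), arr([+1, +2]))
        assert len(scs) == 1 and scs[0].events == ()

    def test_single_block_flip(self):
        scs = dm.enumerate_minimal_scenarios(arr([+1]), arr([-1]))
        assert [(ev.start, ev.end) for sc in scs for ev in sc.events] == [(1, 1)]

    def test_full_flip_unique_minimal(self):
        scs = dm.enumerate_minimal_scenarios(arr([+1, +2]), arr([-2, -1]))
        assert len(scs) == 1
        assert [(ev.start, ev.end) for ev in scs[0].events] == [(1, 2)]

    def test_every_scenario_is_minimal_and_sound(self):
        source, target = arr([+1, +2, +3]), arr([+3, -1, -2])
        d = dm.exact_min_distance(source, target)
        scs = dm.enumerate_minimal_scenarios(source, target)
        assert scs, "no minimal scenarios returned"
        for sc in scs:
            assert len(sc.events) == d
            assert dm.arrangements_equal(sc.terminal, target)

    def test_matches_brute_force_at_depth_two(self, distances_by_n):
        # every distance-2 target of n=3: count length-2 event sequences by
        # brute force and compare
        intervals = [(s, e) for s in range(1, 4) for e in range(s, 4)]
        source = arr([+1, +2, +3])
        for t, d in distances_by_n[3].items():
            if d != 2:
                continue
            target = arr(list(t))
            expected = 0
            for ev1 in intervals:
                mid = dm.apply_inversion(source, dm.InversionEvent(*ev1))
                for ev2 in intervals:
                    end = dm.apply_inversion(mid, dm.InversionEvent(*ev2))
                    if end.signature() == target.signature():
                        expected += 1
            got = dm.enumerate_minimal_scenarios(source, target)
            assert len(got) == expected


class TestBreakpoints:
    @pytest.mark.parametrize(
        "source, target, expected",
        [
            ([+1, +2], [+1, +2], 0),
            ([+1, +2], [-2, -1], 2),
            ([+1, +2, +3], [+3, -1, -2], 4),
        ],
    )
    def test_examples(self, source, target, expected):
        assert dm.breakpoint_count(arr(source), arr(target)) == expected

    def test_lower_bound_exhaustive(self, distances_by_n):
        for n in (1, 2, 3, 4):
            ident = arr(list(range(1, n + 1)))
            for t, d in distances_by_n[n].items():
                bp = dm.breakpoint_count(ident, arr(list(t)))
                assert d >= math.ceil(bp / 2)

    def test_invariant_under_relabelling(self, distances_by_n):
        # distance/breakpoints of (s, t) equal those of (identity, relabel(s, t))
        rng = np.random.default_rng(5)
        states = all_signed_arrangements(3)
        for _ in range(25):
            s = arr(list(states[rng.integers(len(states))]))
            t_vals = states[rng.integers(len(states))]
            t = SignedArrangement(
                "region",
                tuple(
                    dm.SignedBlock(s.blocks[abs(v) - 1].label,
                                   s.blocks[abs(v) - 1].sign * (1 if v > 0 else -1))
                    for v in t_vals
                ),
            )
            u = dm.relabel_against_reference(s, t).values
            assert dm.exact_min_distance(s, t) == distances_by_n[3][u]
            ident = arr([1, 2, 3])
            assert dm.breakpoint_count(s, t) == dm.breakpoint_count(ident, arr(list(u)))


class TestDimsum:
    def test_source_equals_target(self):
        a = arr([+1, +2])
        res = dm.dimsum(a, a, dm.SearchConfig(replicates=17, seed=0))
        assert res.min_length == 0
        assert res.hits_by_length == {0: 17}
        assert len(res.solutions) == 1 and res.solutions[0].events == ()

    def test_ssc_instance_min_two_without_flip(self):
        source, target = arr([+1, +2]), arr([+2, -1])
        res = dm.dimsum(source, target, dm.SearchConfig(replicates=10_000, seed=11))
        assert res.min_length == 2 == dm.exact_min_distance(source, target)

    def test_ssc_instance_min_one_with_flip(self):
        source, target = arr([+1, +2]), arr([+2, -1])
        cfg = dm.SearchConfig(replicates=10_000, seed=11, flip_equivalence=True)
        res = dm.dimsum(source, target, cfg)
        assert res.min_length == 1 == dm.exact_min_distance(
            source, target, flip_equivalence=True
        )

    def test_solutions_are_sound(self):
        source, target = arr([+1, +2, +3]), arr([+3, -1, -2])
        cfg = dm.SearchConfig(replicates=2_000, seed=3)
        res = dm.dimsum(source, target, cfg)
        assert res.solutions
        for sc in res.solutions[:200]:
            assert dm.arrangements_equal(sc.terminal, target)

    def test_soundness_under_flip(self):
        source, target = arr([+1, +2]), arr([+2, -1])
        cfg = dm.SearchConfig(replicates=500, seed=9, flip_equivalence=True)
        res = dm.dimsum(source, target, cfg)
        for sc in res.solutions:
            assert dm.arrangements_equal(sc.terminal, target, flip_equivalence=True)

    def test_bit_identical_reruns(self):
        source, target = arr([+1, +2, +3]), arr([+3, -1, -2])
        cfg = dm.SearchConfig(replicates=3_000, seed=42)
        r1 = dm.dimsum(source, target, cfg)
        r2 = dm.dimsum(source, target, cfg)
        assert r1.to_json() == r2.to_json()

    def test_hits_count_replicates_pre_deduplication(self):
        source, target = arr([+1, +2]), arr([-2, -1])
        res = dm.dimsum(source, target, dm.SearchConfig(replicates=5_000, seed=2))
        assert sum(res.hits_by_length.values()) <= res.replicates_run
        # the one-event solution is hit by many replicates but stored once
        assert res.hits_by_length[1] > 1
        assert sum(1 for sc in res.solutions if len(sc.events) == 1) == 1

    def test_record_all_solutions_off_keeps_only_minima(self):
        source, target = arr([+1, +2]), arr([-2, -1])
        cfg = dm.SearchConfig(replicates=5_000, seed=2, record_all_solutions=False)
        res = dm.dimsum(source, target, cfg)
        assert {len(sc.events) for sc in res.solutions} == {res.min_length}

    def test_label_mismatch_rejected(self):
        a = arr([+1, +2])
        b = SignedArrangement.from_signed_ints([+1, +2], labels=["X", "Y"])
        with pytest.raises(dm.IncomparableArrangementsError):
            dm.dimsum(a, b)

    def test_config_validation(self):
        with pytest.raises(dm.ConfigError):
            dm.SearchConfig(replicates=0)
        with pytest.raises(dm.ConfigError):
            dm.SearchConfig(max_steps=0)

    def test_all_targets_view_matches_scalar_runs(self, distances_by_n):
        cfg = dm.SearchConfig(replicates=4_000, seed=13)
        fh = first_hit_lengths(3, cfg)
        ident = arr([1, 2, 3])
        rng = np.random.default_rng(1)
        targets = sorted(distances_by_n[3])
        for t in [targets[i] for i in rng.integers(0, len(targets), 6)]:
            res = dm.dimsum(ident, arr(list(t)), cfg)
            assert res.min_length == fh.get(t)
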