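"""Semantic extraction and gait-pair-mechanism validation.

The brute-force oracle here re-evaluates the transition rules with an
independent table-driven scan, so the production implementation is checked
against a second, structurally different encoding of the same rules.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitpipe.semantics_gpm import (
    EventType,
    FOOT_EVENTS,
    GaitSemanticEvent,
    TurnInterval,
    adjacent_available_pairs,
    build_cycle_dictionary,
    chain_available,
    extract_semantics,
    legal_successor,
    turn_intervals,
)
from gaitpipe.skeleton_io import FrameLabel

L = {name: FrameLabel(name) for name in "SLDRT"}


def labels(s: str) -> list[FrameLabel]:
    return [L[ch] for ch in s]


def oracle_extract(seq: list[FrameLabel]) -> list[tuple[int, str]]:
    """Independent rule table evaluated pairwise (brute force)."""
    rules = [
        (lambda p, c: c == "D" and p == "L", "L_down"),
        (lambda p, c: c == "D" and p == "R", "R_down"),
        (lambda p, c: c == "L" and p == "D", "L_up"),
        (lambda p, c: c == "R" and p == "D", "R_up"),
        (lambda p, c: c == "T" and p != "T", "Turn_start"),
        (lambda p, c: c != "T" and p == "T", "Turn_end"),
        (lambda p, c: c != "S" and p == "S", "Gait_start"),
    ]
    out = []
    for i in range(1, len(seq)):
        p, c = seq[i - 1].value, seq[i].value
        for rule, name in rules:
            if rule(p, c):
                out.append((i, name))
    return out


class TestExtractSemantics:
    def test_hand_derived_example(self):
        events = extract_semantics(labels("SSLDRD"))
        assert [(e.frame, e.type.value) for e in events] == [
            (2, "Gait_start"),
            (3, "L_down"),
            (4, "R_up"),
            (5, "R_down"),
        ]

    def test_all_standstill_no_events(self):
        assert extract_semantics(labels("SSSSSSS")) == []

    def test_mid_walk_example(self):
        events = extract_semantics(labels("DLDR"))
        assert [(e.frame, e.type.value) for e in events] == [
            (1, "L_up"),
            (2, "L_down"),
            (3, "R_up"),
        ]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            extract_semantics([])

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="SLDRT", min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, s):
        got = [(e.frame, e.type.value) for e in extract_semantics(labels(s))]
        assert got == oracle_extract(labels(s))


class TestTurnIntervals:
    def test_single_pair(self):
        events = [
            GaitSemanticEvent(100, EventType.TURN_START),
            GaitSemanticEvent(160, EventType.TURN_END),
        ]
        assert turn_intervals(events) == [TurnInterval(100, 160)]

    def test_no_turns(self):
        assert turn_intervals([GaitSemanticEvent(3, EventType.L_UP)]) == []

    def test_two_disjoint_turns_in_order(self):
        events = [
            GaitSemanticEvent(10, EventType.TURN_START),
            GaitSemanticEvent(20, EventType.TURN_END),
            GaitSemanticEvent(50, EventType.TURN_START),
            GaitSemanticEvent(55, EventType.TURN_END),
        ]
        assert turn_intervals(events) == [TurnInterval(10, 20), TurnInterval(50, 55)]

    def test_unmatched_trailing_start_closes_at_end(self):
        events = [GaitSemanticEvent(40, EventType.TURN_START)]
        assert turn_intervals(events, sequence_length=90) == [TurnInterval(40, 90)]

    def test_end_before_start_is_error(self):
        with pytest.raises(ValueError):
            turn_intervals([GaitSemanticEvent(5, EventType.TURN_END)])


class TestLegalSuccessor:
    legal = [
        (EventType.L_UP, EventType.L_DOWN),
        (EventType.L_DOWN, EventType.R_UP),
        (EventType.R_UP, EventType.R_DOWN),
        (EventType.R_DOWN, EventType.L_UP),
    ]

    @pytest.mark.parametrize("a,b", legal)
    def test_cyclic_order_is_legal(self, a, b):
        assert legal_successor(a, b)

    def test_only_four_pairs_legal(self):
        foot = sorted(FOOT_EVENTS, key=lambda e: e.value)
        count = sum(legal_successor(a, b) for a in foot for b in foot)
        assert count == 4
        assert not legal_successor(EventType.L_UP, EventType.R_DOWN)

    def test_non_foot_event_rejected(self):
        with pytest.raises(ValueError):
            legal_successor(EventType.TURN_START, EventType.L_UP)


def _chain_events(types, start=10, step=5):
    return [GaitSemanticEvent(start + i * step, t) for i, t in enumerate(types)]


class TestCycleDictionary:
    @pytest.mark.parametrize(
        "types,available",
        [
            # the printed dictionary patterns: a full cyclic chain is kept,
            # a repeated semantic or an out-of-order return is discarded
            ([EventType.L_DOWN, EventType.R_UP, EventType.R_DOWN, EventType.L_UP], True),
            ([EventType.L_DOWN, EventType.R_UP, EventType.R_UP], False),
            ([EventType.L_UP, EventType.L_DOWN, EventType.R_UP, EventType.L_UP], False),
        ],
    )
    def test_reference_chain_patterns(self, types, available):
        assert chain_available(types) is available

    def test_exhaustive_four_event_chains(self):
        """All 256 type chains agree with an independent legality table."""
        foot = sorted(FOOT_EVENTS, key=lambda e: e.value)
        nxt = {"L_up": "L_down", "L_down": "R_up", "R_up": "R_down", "R_down": "L_up"}
        for chain in itertools.product(foot, repeat=4):
            expected = all(nxt[a.value] == b.value for a, b in zip(chain, chain[1:]))
            assert chain_available(list(chain)) is expected

    def test_edge_events_excluded_and_chunking(self):
        # 10 foot events in legal order; first and last drop, leaving 8 -> 2 cycles
        order = [EventType.L_UP, EventType.L_DOWN, EventType.R_UP, EventType.R_DOWN]
        types = [order[i % 4] for i in range(10)]
        d = build_cycle_dictionary(_chain_events(types))
        assert [e.available for e in d.entries] == [True, True]
        assert d.entries[0].events[0].type is EventType.L_DOWN

    def test_turn_interval_removes_events(self):
        order = [EventType.L_UP, EventType.L_DOWN, EventType.R_UP, EventType.R_DOWN]
        types = [order[i % 4] for i in range(10)]
        events = _chain_events(types)
        base = build_cycle_dictionary(events)
        covered = build_cycle_dictionary(events, [TurnInterval(20, 31)])
        assert len(covered.available_entries) <= len(base.available_entries)

    def test_illegal_chain_stored_unavailable_with_resume(self):
        # a duplicated R_up cannot realign into any legal chain; scanning
        # resumes at the offending event and recovers one later cycle
        types = [
            EventType.L_UP,  # edge-dropped
            EventType.L_DOWN, EventType.R_UP, EventType.R_UP, EventType.R_DOWN,
            EventType.L_UP, EventType.L_DOWN, EventType.R_UP, EventType.R_DOWN,
            EventType.L_UP,  # edge-dropped
        ]
        d = build_cycle_dictionary(_chain_events(types))
        flags = [e.available for e in d.entries]
        assert flags[0] is False
        assert True in flags

    def test_empty_input_empty_dictionary(self):
        assert len(build_cycle_dictionary([])) == 0


class TestAdjacentPairs:
    def _dict_with_flags(self, flags):
        order = [EventType.L_DOWN, EventType.R_UP, EventType.R_DOWN, EventType.L_UP]
        from gaitpipe.semantics_gpm import CycleEntry, GaitCycleDictionary

        entries = [
            CycleEntry(k, tuple(_chain_events(order, start=10 + 40 * k)), avail)
            for k, avail in enumerate(flags)
        ]
        return GaitCycleDictionary(entries=entries)

    def test_pair_straddling_unavailable_excluded(self):
        d = self._dict_with_flags([True, True, False, True])
        pairs = [(a.key, b.key) for a, b in adjacent_available_pairs(d)]
        assert pairs == [(0, 1)]

    def test_all_unavailable_no_pairs(self):
        assert adjacent_available_pairs(self._dict_with_flags([False] * 3)) == []

    def test_all_available_consecutive_enumeration(self):
        d = self._dict_with_flags([True] * 4)
        pairs = [(a.key, b.key) for a, b in adjacent_available_pairs(d)]
        assert pairs == [(0, 1), (1, 2), (2, 3)]


class TestSimulatedLabels:
    def test_available_cycles_track_generator_count(self, default_walk):
        """Clean labels yield about one available cycle per simulated cycle,
        minus pass-boundary and edge exclusions."""
        from gaitpipe.synthetic_gait import GaitSimConfig

        seq, truth = default_walk
        cfg = GaitSimConfig()
        events = extract_semantics(truth.labels)
        turns = turn_intervals(events, sequence_length=len(seq))
        d = build_cycle_dictionary(events, turns)
        total_cycles = cfg.n_passes * cfg.cycles_per_pass
        n_avail = len(d.available_entries)
        assert total_cycles - 2 * cfg.n_passes <= n_avail <= total_cycles
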