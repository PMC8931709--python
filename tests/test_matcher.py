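"""Temporal pairing and the eight-category classification.

Includes the exact brute-force pairing oracle (bitmask dynamic program over
rear subsets) used to certify that the assignment-based matcher always finds
a maximum-cardinality pairing.
"""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doublecount.matcher import (
    MatchCategory,
    ReconciledEvent,
    classify_event,
    pair_streams,
)


def max_cardinality_bruteforce(feasible: list[list[int]]) -> int:
    """Exact maximum one-to-one pairing size by enumeration over rear subsets."""

    @lru_cache(maxsize=None)
    def best(i: int, used: int) -> int:
        if i == len(feasible):
            return 0
        b = best(i + 1, used)
        for j in feasible[i]:
            if not used & (1 << j):
                b = max(b, 1 + best(i + 1, used | (1 << j)))
        return b

    return best(0, 0)


def random_instance(rng, make_record, max_per_side=8, span=60.0):
    taxa = ["NOGA", "BRPE", "gull", "tern", "LAGU", "WWSC", "BLSC"]
    front = [
        make_record(
            seat="front",
            time_s=float(rng.uniform(0, span)),
            taxon_code=taxa[rng.integers(len(taxa))],
            count=int(rng.integers(1, 40)),
        )
        for _ in range(rng.integers(0, max_per_side + 1))
    ]
    rear = [
        make_record(
            seat="rear",
            observer_id="obsB",
            time_s=float(rng.uniform(0, span)),
            taxon_code=taxa[rng.integers(len(taxa))],
            count=int(rng.integers(1, 40)),
        )
        for _ in range(rng.integers(0, max_per_side + 1))
    ]
    return front, rear


def check_against_oracle(front, rear, tax, window=10.0):
    """Pairing is max-cardinality, within-window, and conserves records."""
    events = pair_streams(front, rear, window_s=window, tax=tax)
    paired = [ev for ev in events if ev.is_paired]
    feasible = [
        [j for j, r in enumerate(rear) if abs(f.time_s - r.time_s) <= window]
        for f in front
    ]
    assert len(paired) == max_cardinality_bruteforce([tuple(row) for row in map(tuple, feasible)])
    assert all(ev.dt_s <= window for ev in paired)
    assert len(front) + len(rear) == 2 * len(paired) + (len(events) - len(paired))
    return events


class TestPairing:
    def test_single_pair_within_window(self, make_record, tax):
        f = make_record(seat="front", time_s=100.0)
        r = make_record(seat="rear", time_s=105.0)
        events = pair_streams([f], [r], tax=tax)
        assert len(events) == 1 and events[0].is_paired
        assert events[0].dt_s == pytest.approx(5.0)

    def test_outside_window_gives_two_singletons(self, make_record, tax):
        f = make_record(seat="front", time_s=100.0)
        r = make_record(seat="rear", time_s=111.0)
        events = pair_streams([f], [r], tax=tax)
        assert [ev.category for ev in events] == [MatchCategory.NO_MATCH] * 2

    def test_window_is_closed_at_exactly_10s(self, make_record, tax):
        f = make_record(seat="front", time_s=100.0)
        r = make_record(seat="rear", time_s=110.0)
        (ev,) = pair_streams([f], [r], tax=tax)
        assert ev.is_paired

    def test_species_agreement_outranks_smaller_dt(self, make_record, tax):
        f = make_record(seat="front", time_s=100.0, taxon_code="gull")
        r_near = make_record(seat="rear", time_s=104.0, taxon_code="tern")
        r_far = make_record(seat="rear", time_s=109.0, taxon_code="gull")
        events = pair_streams([f], [r_near, r_far], tax=tax)
        paired = [ev for ev in events if ev.is_paired]
        assert len(paired) == 1 and paired[0].rear.time_s == 109.0

    def test_two_fronts_one_rear_leaves_one_singleton(self, make_record, tax):
        fronts = [make_record(seat="front", time_s=t) for t in (100.0, 103.0)]
        rear = make_record(seat="rear", time_s=101.0)
        events = pair_streams(fronts, [rear], tax=tax)
        assert sum(ev.is_paired for ev in events) == 1
        assert sum(ev.category is MatchCategory.NO_MATCH for ev in events) == 1

    def test_cross_transect_pairing_forbidden(self, make_record, tax):
        f = make_record(seat="front", time_s=100.0, transect_id="T1")
        r = make_record(seat="rear", time_s=101.0, transect_id="T2")
        events = pair_streams([f], [r], tax=tax)
        assert all(ev.category is MatchCategory.NO_MATCH for ev in events)

    def test_mixed_sides_rejected(self, make_record, tax):
        f = make_record(seat="front", side="left")
        r = make_record(seat="rear", side="right")
        with pytest.raises(ValueError, match="survey_event, side"):
            pair_streams([f], [r], tax=tax)

    def test_negative_window_rejected(self, make_record, tax):
        with pytest.raises(ValueError, match="window"):
            pair_streams([make_record()], [], window_s=-1.0, tax=tax)

    def test_matches_bruteforce_on_random_instances(self, make_record, tax):
        rng = np.random.default_rng(42)
        for _ in range(100):
            front, rear = random_instance(rng, make_record)
            check_against_oracle(front, rear, tax)

    def test_deterministic_under_input_permutation(self, make_record, tax):
        rng = np.random.default_rng(7)
        front, rear = random_instance(rng, make_record)
        baseline = pair_streams(front, rear, tax=tax)
        for _ in range(5):
            rng.shuffle(front)
            rng.shuffle(rear)
            assert pair_streams(front, rear, tax=tax) == baseline

    @given(
        ft=st.lists(st.integers(0, 50), max_size=6),
        rt=st.lists(st.integers(0, 50), max_size=6),
        w_small=st.integers(0, 12),
        w_extra=st.integers(0, 12),
    )
    @settings(derandomize=True, max_examples=60)
    def test_shrinking_window_never_adds_pairs(self, ft, rt, w_small, w_extra, tax):
        from doublecount.records import ObserverRecord

        def rec(seat, i, t):
            return ObserverRecord(
                record_id=f"{seat}{i}", survey_event="e", unit_id="U", transect_id="T",
                side="left", seat=seat, observer_id=seat, time_s=float(t),
                taxon_code="NOGA", count=1,
            )

        front = [rec("front", i, t) for i, t in enumerate(ft)]
        rear = [rec("rear", i, t) for i, t in enumerate(rt)]
        small = sum(ev.is_paired for ev in pair_streams(front, rear, float(w_small), tax))
        large = sum(
            ev.is_paired for ev in pair_streams(front, rear, float(w_small + w_extra), tax)
        )
        assert small <= large


class TestClassification:
    @pytest.mark.parametrize(
        "taxon_a,count_a,taxon_b,count_b,expected",
        [
            ("NOGA", 5, "NOGA", 5, MatchCategory.SPECIES_COUNT_MATCH),
            ("gull", 8, "tern", 8, MatchCategory.GENERIC_COUNT_MATCH),
            ("BRPE", 12, "BRPE", 45, MatchCategory.SPECIES_BIN_MATCH),  # both 11-100
            ("gull", 12, "tern", 45, MatchCategory.GENERIC_BIN_MATCH),
            ("BRPE", 4, "BRPE", 30, MatchCategory.SPECIES_ONLY_MATCH),  # bins differ
            ("WWSC", 4, "BLSC", 30, MatchCategory.GENERIC_ONLY_MATCH),
            ("NOGA", 2, "BRPE", 2, MatchCategory.MISMATCH),  # different families
        ],
    )
    def test_category_precedence(self, make_record, tax, taxon_a, count_a, taxon_b, count_b, expected):
        f = make_record(seat="front", taxon_code=taxon_a, count=count_a)
        r = make_record(seat="rear", taxon_code=taxon_b, count=count_b)
        assert classify_event(f, r, tax) == expected

    def test_singleton_classification_rejected(self, make_record, tax):
        ev = ReconciledEvent(front=make_record(), rear=None, category=MatchCategory.NO_MATCH)
        with pytest.raises(ValueError, match="singleton"):
            classify_event(ev, tax)

    def test_event_invariant_paired_iff_not_nomatch(self, make_record):
        with pytest.raises(ValueError):
            ReconciledEvent(
                front=make_record(), rear=None, category=MatchCategory.SPECIES_COUNT_MATCH
            )
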