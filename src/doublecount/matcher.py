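"""Temporal reconciliation of front/rear observer record streams.

Front- and rear-seat observers on the same aircraft side record observations
independently; the same flock typically appears in both streams a few seconds
apart. Reconciliation pairs records made within a temporal window (10 s by
convention) into one event per flock, leaving unmatched records as singleton
"No Match" events, and classifies every paired event into one of eight
mutually exclusive agreement categories:

=================== ========================================================
SpeciesCountMatch   species identification and exact count both matched
GenericCountMatch   taxonomic family and exact count matched
SpeciesBinMatch     species and log10 count bin matched (counts did not)
GenericBinMatch     family and log10 count bin matched (counts did not)
SpeciesOnlyMatch    species matched; neither count nor bin matched
GenericOnlyMatch    family matched; neither count nor bin matched
Mismatch            paired in time but species and family both differed
NoMatch             no record from the other observer within the window
=================== ========================================================

Pairing is a maximum-cardinality one-to-one assignment within each group of
temporally linked records: as many pairs as the window permits are formed,
and among assignments of equal size the one with the best identification
agreement (species > family > none) and then the smallest time differences is
chosen. This makes the pair count a well-defined property of the data rather
than of processing order, and it is deterministic for any input ordering.
"""

from __future__ import annotations

import enum
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .records import ObserverRecord, TaxonomyTable, count_bin

__all__ = [
    "MatchCategory",
    "ReconciledEvent",
    "classify_event",
    "events_to_frame",
    "pair_streams",
    "reconcile_records",
    "write_events",
]


class MatchCategory(str, enum.Enum):
    SPECIES_COUNT_MATCH = "SpeciesCountMatch"
    GENERIC_COUNT_MATCH = "GenericCountMatch"
    SPECIES_BIN_MATCH = "SpeciesBinMatch"
    GENERIC_BIN_MATCH = "GenericBinMatch"
    SPECIES_ONLY_MATCH = "SpeciesOnlyMatch"
    GENERIC_ONLY_MATCH = "GenericOnlyMatch"
    MISMATCH = "Mismatch"
    NO_MATCH = "NoMatch"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Categories whose events contain both a front and a rear record.
PAIRED_CATEGORIES = frozenset(MatchCategory) - {MatchCategory.NO_MATCH}


@dataclass(frozen=True)
class ReconciledEvent:
    """A matched front/rear record pair, or an unmatched singleton."""

    front: ObserverRecord | None
    rear: ObserverRecord | None
    category: MatchCategory
    dt_s: float | None = None

    def __post_init__(self) -> None:
        if self.front is None and self.rear is None:
            raise ValueError("event must contain at least one record")
        both = self.front is not None and self.rear is not None
        if both != (self.category is not MatchCategory.NO_MATCH):
            raise ValueError("paired events and only paired events have a non-NoMatch category")

    @property
    def is_paired(self) -> bool:
        return self.front is not None and self.rear is not None

    @property
    def survey_event(self) -> str:
        return (self.front or self.rear).survey_event

    @property
    def side(self) -> str:
        return (self.front or self.rear).side

    @property
    def max_count(self) -> int:
        counts = [r.count for r in (self.front, self.rear) if r is not None]
        return max(counts)


def classify_event(
    front: ObserverRecord | ReconciledEvent,
    rear: ObserverRecord | None = None,
    tax: TaxonomyTable | None = None,
) -> MatchCategory:
    """Classify a paired event into its agreement category.

    Accepts either a :class:`ReconciledEvent` with both records present, or
    the two records directly. The rules are applied in strict precedence:
    exact count agreement first, then log10-bin agreement, then
    identification-only agreement; species-level identification outranks
    family-level at each stage.
    """
    if isinstance(front, ReconciledEvent):
        ev, tax = front, rear if isinstance(rear, TaxonomyTable) else tax
        if not ev.is_paired:
            raise ValueError("singleton events are NoMatch by construction")
        front, rear = ev.front, ev.rear
    if tax is None:
        raise TypeError("a TaxonomyTable is required")
    level = tax.match_level(front.taxon_code, rear.taxon_code)
    counts_equal = front.count == rear.count
    bins_equal = count_bin(front.count) == count_bin(rear.count)
    if level == "species":
        if counts_equal:
            return MatchCategory.SPECIES_COUNT_MATCH
        if bins_equal:
            return MatchCategory.SPECIES_BIN_MATCH
        return MatchCategory.SPECIES_ONLY_MATCH
    if level == "family":
        if counts_equal:
            return MatchCategory.GENERIC_COUNT_MATCH
        if bins_equal:
            return MatchCategory.GENERIC_BIN_MATCH
        return MatchCategory.GENERIC_ONLY_MATCH
    return MatchCategory.MISMATCH


_LEVEL_RANK = {"none": 0, "family": 1, "species": 2}


def _components(
    front: Sequence[ObserverRecord],
    rear: Sequence[ObserverRecord],
    window_s: float,
) -> list[tuple[list[int], list[int]]]:
    """Split records into connected components of the time-feasibility graph."""
    parent = list(range(len(front) + len(rear)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    rear_times = [r.time_s for r in rear]
    for i, f in enumerate(front):
        lo = bisect_left(rear_times, f.time_s - window_s)
        hi = bisect_right(rear_times, f.time_s + window_s)
        for j in range(lo, hi):
            if rear[j].transect_id == f.transect_id:
                union(i, len(front) + j)

    groups: dict[int, tuple[list[int], list[int]]] = {}
    for i in range(len(front)):
        groups.setdefault(find(i), ([], []))[0].append(i)
    for j in range(len(rear)):
        groups.setdefault(find(len(front) + j), ([], []))[1].append(j)
    return [groups[k] for k in sorted(groups)]


def _assign_component(
    fronts: Sequence[ObserverRecord],
    rears: Sequence[ObserverRecord],
    window_s: float,
    tax: TaxonomyTable,
) -> list[tuple[int, int, float]]:
    """Best one-to-one assignment inside one component: (fi, rj, dt) triples.

    Scores are layered so that total pair count dominates, then total
    identification agreement, then total closeness in time: with
    ``L = min(nf, nr) + 1`` a feasible pair scores
    ``BASE + level_rank * L + (1 - dt/window)`` and an infeasible cell scores
    0, where ``BASE`` exceeds any achievable sum of the lower-order terms.
    """
    nf, nr = len(fronts), len(rears)
    if nf == 0 or nr == 0:
        return []
    level_scale = float(min(nf, nr) + 1)
    base = min(nf, nr) * (2 * level_scale + 1.0) + 1.0
    score = np.zeros((nf, nr))
    dt = np.empty((nf, nr))
    for i, f in enumerate(fronts):
        for j, r in enumerate(rears):
            d = abs(f.time_s - r.time_s)
            dt[i, j] = d
            if d <= window_s and f.transect_id == r.transect_id:
                rank = _LEVEL_RANK[tax.match_level(f.taxon_code, r.taxon_code)]
                score[i, j] = base + rank * level_scale + (1.0 - d / window_s if window_s else 1.0)
    rows, cols = linear_sum_assignment(score, maximize=True)
    return [(i, j, dt[i, j]) for i, j in zip(rows, cols) if score[i, j] > 0]


def pair_streams(
    front: Iterable[ObserverRecord],
    rear: Iterable[ObserverRecord],
    window_s: float = 10.0,
    tax: TaxonomyTable | None = None,
) -> list[ReconciledEvent]:
    """Reconcile one side's front and rear streams into events.

    All records must share one survey event and one aircraft side. Records on
    different transects are never paired even when temporally close. Every
    record appears in exactly one event, so
    ``len(front) + len(rear) == 2 * paired + singletons`` always holds.
    """
    if window_s < 0:
        raise ValueError(f"window_s must be >= 0, got {window_s}")
    if tax is None:
        raise TypeError("a TaxonomyTable is required")
    front = sorted(front, key=lambda r: (r.time_s, r.record_id))
    rear = sorted(rear, key=lambda r: (r.time_s, r.record_id))
    keys = {(r.survey_event, r.side) for r in front} | {(r.survey_event, r.side) for r in rear}
    if len(keys) > 1:
        raise ValueError(f"records span multiple (survey_event, side) groups: {sorted(keys)}")

    events: list[ReconciledEvent] = []
    n_paired = 0
    for fidx, ridx in _components(front, rear, window_s):
        fs = [front[i] for i in fidx]
        rs = [rear[j] for j in ridx]
        assigned = _assign_component(fs, rs, window_s, tax)
        used_f = {i for i, _, _ in assigned}
        used_r = {j for _, j, _ in assigned}
        for i, j, d in assigned:
            events.append(
                ReconciledEvent(
                    front=fs[i],
                    rear=rs[j],
                    category=classify_event(fs[i], rs[j], tax),
                    dt_s=d,
                )
            )
            n_paired += 1
        for i, f in enumerate(fs):
            if i not in used_f:
                events.append(ReconciledEvent(front=f, rear=None, category=MatchCategory.NO_MATCH))
        for j, r in enumerate(rs):
            if j not in used_r:
                events.append(ReconciledEvent(front=None, rear=r, category=MatchCategory.NO_MATCH))

    assert len(front) + len(rear) == 2 * n_paired + (len(events) - n_paired), (
        "record conservation violated"
    )
    events.sort(key=lambda e: ((e.front or e.rear).time_s, (e.front or e.rear).record_id))
    return events


def reconcile_records(
    records: Iterable[ObserverRecord],
    tax: TaxonomyTable,
    window_s: float = 10.0,
) -> list[ReconciledEvent]:
    """Reconcile a full survey: split by (survey_event, side) and pair each."""
    groups: dict[tuple[str, str], tuple[list[ObserverRecord], list[ObserverRecord]]] = {}
    for r in records:
        grp = groups.setdefault((r.survey_event, r.side), ([], []))
        grp[0 if r.seat == "front" else 1].append(r)
    events: list[ReconciledEvent] = []
    for key in sorted(groups):
        f, b = groups[key]
        events.extend(pair_streams(f, b, window_s=window_s, tax=tax))
    return events


def events_to_frame(events: Iterable[ReconciledEvent]) -> pd.DataFrame:
    rows = []
    for k, ev in enumerate(events):
        f, r = ev.front, ev.rear
        rows.append(
            {
                "event_id": f"E{k:06d}",
                "survey_event": ev.survey_event,
                "side": ev.side,
                "category": ev.category.value,
                "dt_s": ev.dt_s,
                "front_record_id": f.record_id if f else "",
                "rear_record_id": r.record_id if r else "",
                "front_taxon": f.taxon_code if f else "",
                "rear_taxon": r.taxon_code if r else "",
                "front_count": f.count if f else "",
                "rear_count": r.count if r else "",
                "front_observer": f.observer_id if f else "",
                "rear_observer": r.observer_id if r else "",
            }
        )
    return pd.DataFrame(rows)


def write_events(events: Iterable[ReconciledEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)
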