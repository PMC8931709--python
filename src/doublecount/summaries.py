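"""Summary statistics for reconciled double-observer events.

Implements the standard reporting surface for a reconciled double-observer
survey: the category-by-season count table with percentages, naive
per-observer detection probabilities (share of a partner's records the
observer also recorded, no model-based correction), exact-count versus
log10-bin agreement overall and by flock-size class, and the size
distribution of missed (unmatched) observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matcher import MatchCategory, ReconciledEvent

__all__ = [
    "CategoryTable",
    "ObserverSession",
    "aggregate_shares",
    "agreement_rates",
    "category_percentages",
    "category_table",
    "missed_size_distribution",
    "naive_detection",
]

CATEGORY_ORDER = [c.value for c in MatchCategory]

EXACT_CATEGORIES = {MatchCategory.SPECIES_COUNT_MATCH, MatchCategory.GENERIC_COUNT_MATCH}
BIN_CATEGORIES = EXACT_CATEGORIES | {
    MatchCategory.SPECIES_BIN_MATCH,
    MatchCategory.GENERIC_BIN_MATCH,
}
SPECIES_ID_CATEGORIES = {
    MatchCategory.SPECIES_COUNT_MATCH,
    MatchCategory.SPECIES_BIN_MATCH,
    MatchCategory.SPECIES_ONLY_MATCH,
}
GENERIC_ID_CATEGORIES = {
    MatchCategory.GENERIC_COUNT_MATCH,
    MatchCategory.GENERIC_BIN_MATCH,
    MatchCategory.GENERIC_ONLY_MATCH,
}

#: Flock-size classes used for the agreement-by-size breakdown.
DEFAULT_SIZE_CLASSES: tuple[tuple[int, int | None], ...] = ((1, 5), (6, 30), (31, None))


class CategoryTable:
    """Counts of reconciled events per (survey_event, match category)."""

    def __init__(self, counts: pd.DataFrame):
        counts = counts.reindex(columns=CATEGORY_ORDER, fill_value=0).astype(int)
        if (counts.values < 0).any():
            raise ValueError("category counts must be non-negative")
        self.counts = counts

    @classmethod
    def from_counts(cls, counts: dict[str, dict[str, int]]) -> "CategoryTable":
        """Build from ``{survey_event: {category name: count}}``."""
        df = pd.DataFrame(counts).T
        return cls(df)

    @property
    def survey_events(self) -> list[str]:
        return list(self.counts.index)

    def category_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def event_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())

    def to_frame(self) -> pd.DataFrame:
        """Table-layout frame: categories as rows, survey events as columns."""
        out = self.counts.T.copy()
        out["Total"] = out.sum(axis=1)
        out.loc["Total"] = out.sum(axis=0)
        return out


def category_table(events: Iterable[ReconciledEvent]) -> CategoryTable:
    """Tabulate events per (survey_event, category); a pair counts once."""
    rows: dict[str, dict[str, int]] = {}
    for ev in events:
        cell = rows.setdefault(ev.survey_event, {c: 0 for c in CATEGORY_ORDER})
        cell[ev.category.value] += 1
    if not rows:
        return CategoryTable(pd.DataFrame(columns=CATEGORY_ORDER))
    return CategoryTable.from_counts(rows)


def category_percentages(tab: CategoryTable) -> pd.DataFrame:
    """Per-category percentages, overall and per survey event (one decimal).

    Returns a frame indexed by category with one column per survey event plus
    ``overall_pct``. An empty table yields an empty frame rather than a
    division error.
    """
    if tab.total == 0:
        return pd.DataFrame(index=pd.Index(CATEGORY_ORDER, name="category"))
    out = pd.DataFrame(index=pd.Index(CATEGORY_ORDER, name="category"))
    event_totals = tab.event_totals()
    for ev in tab.survey_events:
        tot = event_totals[ev]
        col = tab.counts.loc[ev] * 100.0 / tot if tot else np.nan
        out[ev] = col.round(1)
    out["overall_pct"] = (tab.category_totals() * 100.0 / tab.total).round(1)
    return out


def aggregate_shares(tab: CategoryTable) -> dict[str, float]:
    """Derived overall agreement shares, in percent of all events.

    ``exact_count_pct``: exact count and at least family-level ID matched.
    ``bin_level_pct``: adds log10-bin matches.
    ``species_id_pct`` / ``generic_id_pct``: identification agreement at
    species / family-only level regardless of count agreement.
    """
    totals = tab.category_totals()
    n = tab.total
    if n == 0:
        raise ValueError("empty category table")

    def share(cats: set[MatchCategory]) -> float:
        return 100.0 * sum(totals[c.value] for c in cats) / n

    return {
        "exact_count_pct": share(EXACT_CATEGORIES),
        "bin_level_pct": share(BIN_CATEGORIES),
        "species_id_pct": share(SPECIES_ID_CATEGORIES),
        "generic_id_pct": share(GENERIC_ID_CATEGORIES),
        "mismatch_pct": share({MatchCategory.MISMATCH}),
        "no_match_pct": share({MatchCategory.NO_MATCH}),
    }


def _class_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f"{lo}+"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


def agreement_rates(
    events: Iterable[ReconciledEvent],
    size_classes: Sequence[tuple[int, int | None]] = DEFAULT_SIZE_CLASSES,
) -> pd.DataFrame:
    """Exact-count and bin-level agreement among paired events, by size class.

    Only paired events enter the denominators; a paired event's flock size is
    the larger of the two recorded counts. Returns one row per size class
    plus an ``all`` row, with columns ``n``, ``exact_count_pct`` and
    ``bin_level_pct``. Size classes with no events are omitted.
    """
    paired = [ev for ev in events if ev.is_paired]
    rows = []

    def rates(sub: list[ReconciledEvent], label: str) -> dict | None:
        if not sub:
            return None
        n = len(sub)
        exact = sum(ev.category in EXACT_CATEGORIES for ev in sub)
        binlev = sum(ev.category in BIN_CATEGORIES for ev in sub)
        return {
            "size_class": label,
            "n": n,
            "exact_count_pct": 100.0 * exact / n,
            "bin_level_pct": 100.0 * binlev / n,
        }

    for lo, hi in size_classes:
        sub = [
            ev for ev in paired if lo <= ev.max_count and (hi is None or ev.max_count <= hi)
        ]
        row = rates(sub, _class_label(lo, hi))
        if row:
            rows.append(row)
    overall = rates(paired, "all")
    if overall:
        rows.append(overall)
    return pd.DataFrame(rows, columns=["size_class", "n", "exact_count_pct", "bin_level_pct"])


@dataclass(frozen=True)
class ObserverSession:
    """One observer's stint: who they were paired with, on which side/seat."""

    survey_event: str
    observer_id: str
    partner_id: str
    side: str
    seat: str

    def __post_init__(self) -> None:
        if self.observer_id == self.partner_id:
            raise ValueError("observer and partner must differ")


def naive_detection(
    events: Iterable[ReconciledEvent],
    sessions: Iterable[ObserverSession],
    denominator: str = "events",
) -> pd.DataFrame:
    """Naive per-observer detection probability per survey event.

    For observer X paired with partner Y, detection(X) is the share of Y's
    events that X also recorded: paired / (paired + Y-only singletons). This
    is the uncorrected proportion-matched statistic; under independent
    detection its expectation is X's true detection probability.

    The returned frame has observers as rows, survey events as columns, a
    ``sd`` column (per-observer SD across survey events) and an ``sd`` row
    (across observers within a survey event). Cells with no partner events
    are NaN. With ``denominator="records"`` the partner's record count is
    used instead of the event count (identical here since each singleton or
    pair contributes one partner record, but kept explicit for clarity).
    """
    if denominator not in ("events", "records"):
        raise ValueError(f"unknown denominator {denominator!r}")
    by_obs: dict[str, dict[str, str]] = {}
    for s in sessions:
        by_obs.setdefault(s.survey_event, {})[(s.observer_id, s.side)] = s.partner_id

    num: dict[tuple[str, str], int] = {}
    den: dict[tuple[str, str], int] = {}

    def bump(observer: str, event: str, detected: bool) -> None:
        key = (observer, event)
        den[key] = den.get(key, 0) + 1
        if detected:
            num[key] = num.get(key, 0) + 1

    for ev in events:
        se = ev.survey_event
        if ev.is_paired:
            # each observer detected an event their partner also recorded
            bump(ev.front.observer_id, se, True)
            bump(ev.rear.observer_id, se, True)
        else:
            rec = ev.front or ev.rear
            partner = by_obs.get(se, {}).get((rec.observer_id, rec.side))
            if partner is None:
                raise ValueError(
                    f"no session for observer {rec.observer_id!r} in {se!r} ({rec.side})"
                )
            bump(partner, se, False)

    observers = sorted({k[0] for k in den})
    survey_events = sorted({k[1] for k in den})
    out = pd.DataFrame(index=observers, columns=survey_events, dtype=float)
    for (obs, se), d in den.items():
        out.loc[obs, se] = num.get((obs, se), 0) / d
    out["sd"] = out[survey_events].std(axis=1, ddof=1)
    sd_row = out[survey_events].std(axis=0, ddof=1)
    out.loc["sd", survey_events] = sd_row
    out.index.name = "observer"
    return out


def missed_size_distribution(
    events: Iterable[ReconciledEvent],
    size_classes: Sequence[tuple[int, int | None]] | None = ((1, 1), (2, 5), (6, 30), (31, None)),
) -> pd.DataFrame:
    """Distribution of recorded flock size among NoMatch singletons.

    Shares sum to 1 over the singleton events. With ``size_classes=None``
    exact counts are used as classes. No singletons yields an empty frame.
    """
    counts = [
        (ev.front or ev.rear).count for ev in events if ev.category is MatchCategory.NO_MATCH
    ]
    if not counts:
        return pd.DataFrame(columns=["size_class", "n", "share"])
    n = len(counts)
    rows = []
    if size_classes is None:
        for value in sorted(set(counts)):
            k = sum(c == value for c in counts)
            rows.append({"size_class": str(value), "n": k, "share": k / n})
    else:
        for lo, hi in size_classes:
            k = sum(lo <= c and (hi is None or c <= hi) for c in counts)
            if k:
                rows.append({"size_class": _class_label(lo, hi), "n": k, "share": k / n})
    return pd.DataFrame(rows, columns=["size_class", "n", "share"])
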