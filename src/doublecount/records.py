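"""Domain types and CSV I/O for double-observer aerial survey records.

An aerial strip-transect survey with a double-observer protocol produces two
record streams per aircraft side: one from the front-seat observer and one
from the rear-seat observer. Each record is a single in-flight observation of
a bird group ("flock"): who saw it, where, when, what taxon, and how many
individuals. This module defines the record and taxonomy containers, the
ordinal log10 count bins used for coarse count agreement, and schema-validated
CSV readers/writers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "BIN_LABELS",
    "ObserverRecord",
    "RecordValidationError",
    "SchemaError",
    "TaxonomyError",
    "TaxonomyTable",
    "count_bin",
    "load_records",
    "load_taxonomy",
    "shift_times",
    "write_records",
]

RECORD_COLUMNS = [
    "record_id",
    "survey_event",
    "unit_id",
    "transect_id",
    "side",
    "seat",
    "observer_id",
    "time_s",
    "taxon_code",
    "count",
    "lat",
    "lon",
]

TAXONOMY_COLUMNS = ["taxon_code", "common_name", "family_code", "level"]

SIDES = frozenset({"left", "right"})
SEATS = frozenset({"front", "rear"})

#: Ordinal flock-size bins on a log10 scale. "101-1000" includes 1000 so the
#: ranges stay disjoint; "1000+" means >= 1001.
BIN_LABELS = ("0", "1-10", "11-100", "101-1000", "1000+")


class SchemaError(ValueError):
    """A CSV is missing a required column or is otherwise malformed."""


class RecordValidationError(ValueError):
    """One or more rows violate record invariants; carries row numbers."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            "{} invalid row(s):\n{}".format(len(self.errors), "\n".join(self.errors))
        )


class TaxonomyError(ValueError):
    """A taxon code is unknown or the taxonomy table is inconsistent."""


def count_bin(count: int) -> str:
    """Map a non-negative group count to its log10 ordinal bin label.

    Bins are 0, 1-10, 11-100, 101-1000 and 1000+ (i.e. >= 1001); each
    non-negative integer falls in exactly one bin.
    """
    c = int(count)
    if c != count:
        raise ValueError(f"count must be an integer, got {count!r}")
    if c < 0:
        raise ValueError(f"count must be >= 0, got {c}")
    if c == 0:
        return "0"
    if c <= 10:
        return "1-10"
    if c <= 100:
        return "11-100"
    if c <= 1000:
        return "101-1000"
    return "1000+"


@dataclass(frozen=True)
class ObserverRecord:
    """One in-flight observation: a group of >= 1 birds seen by one observer."""

    record_id: str
    survey_event: str
    unit_id: str
    transect_id: str
    side: str
    seat: str
    observer_id: str
    time_s: float
    taxon_code: str
    count: int
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(
                f"record {self.record_id!r}: count must be >= 1, got {self.count}"
            )
        if self.side not in SIDES:
            raise ValueError(
                f"record {self.record_id!r}: side must be left/right, got {self.side!r}"
            )
        if self.seat not in SEATS:
            raise ValueError(
                f"record {self.record_id!r}: seat must be front/rear, got {self.seat!r}"
            )
        if not (self.time_s >= 0) or math.isnan(self.time_s):
            raise ValueError(
                f"record {self.record_id!r}: time_s must be >= 0, got {self.time_s}"
            )


class TaxonomyTable:
    """Mapping from taxon codes to family codes with species/generic levels.

    Species-level codes identify a single species; generic-level codes (e.g.
    "scoter") identify only a family. The aerial-survey convention treats the
    codes ``gull`` and ``tern`` as species-level identifications for matching
    purposes while pooling both under the family Laridae for family-level
    comparisons, because individual gull and tern species are rarely
    separable from the air.
    """

    def __init__(
        self,
        rows: Iterable[tuple[str, str, str, str]],
        species_like_generics: frozenset[str] = frozenset({"gull", "tern"}),
    ):
        self._rows = [tuple(r) for r in rows]
        self.species_like_generics = frozenset(species_like_generics)
        self._family: dict[str, str] = {}
        self._level: dict[str, str] = {}
        self._common: dict[str, str] = {}
        for code, common, family, level in self._rows:
            if code in self._family:
                raise TaxonomyError(f"duplicate taxon_code {code!r}")
            if level not in ("species", "generic"):
                raise TaxonomyError(f"{code!r}: level must be species/generic, got {level!r}")
            if level == "species" and not family:
                raise TaxonomyError(f"species-level code {code!r} has empty family_code")
            self._family[code] = family
            self._level[code] = level
            self._common[code] = common

    # -- lookups ---------------------------------------------------------
    def __contains__(self, code: str) -> bool:
        return code in self._family

    def __len__(self) -> int:
        return len(self._rows)

    def family_of(self, code: str) -> str:
        try:
            return self._family[code]
        except KeyError:
            raise TaxonomyError(f"unknown taxon code {code!r}") from None

    def level_of(self, code: str) -> str:
        try:
            return self._level[code]
        except KeyError:
            raise TaxonomyError(f"unknown taxon code {code!r}") from None

    def species_codes(self, family: str) -> list[str]:
        return [c for c, f in self._family.items() if f == family and self._level[c] == "species"]

    def generic_code(self, family: str) -> str | None:
        """A generic-level code for *family*, preferring plain generic codes."""
        candidates = [
            c
            for c, f in self._family.items()
            if f == family and self._level[c] == "generic" and c not in self.species_like_generics
        ]
        return candidates[0] if candidates else None

    def match_level(self, code_a: str, code_b: str) -> str:
        """Agreement level of two taxon identifications: species, family or none.

        Identical species-level codes (including gull-vs-gull / tern-vs-tern)
        agree at species level; codes sharing a family (including gull vs
        tern under Laridae, and identical plain generic codes) agree at
        family level; anything else does not agree.
        """
        for c in (code_a, code_b):
            if c not in self._family:
                raise TaxonomyError(f"unknown taxon code {c!r}")
        if code_a == code_b:
            species_like = (
                self._level[code_a] == "species" or code_a in self.species_like_generics
            )
            return "species" if species_like else "family"
        fa, fb = self._family[code_a], self._family[code_b]
        if fa and fb and fa == fb:
            return "family"
        return "none"

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "TaxonomyTable":
        df = pd.read_csv(path, dtype=str).fillna("")
        missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"taxonomy CSV {path} missing column(s): {', '.join(missing)}")
        return cls(df[TAXONOMY_COLUMNS].itertuples(index=False, name=None), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=TAXONOMY_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_taxonomy(path: str | Path) -> TaxonomyTable:
    return TaxonomyTable.from_csv(path)


def _times_to_seconds(raw: pd.Series, path: str | Path) -> pd.Series:
    """Interpret the time_s column as seconds or as ISO timestamps.

    ISO timestamps are converted to seconds from the file's earliest record.
    Mixing numeric and timestamp representations in one file is rejected.
    """
    numeric = pd.to_numeric(raw, errors="coerce")
    n_numeric = numeric.notna().sum()
    if n_numeric == len(raw):
        return numeric.astype(float)
    stamps = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    n_stamp = stamps.notna().sum()
    if n_stamp == len(raw):
        return (stamps - stamps.min()).dt.total_seconds()
    if n_numeric > 0 and n_stamp > 0:
        raise SchemaError(
            f"{path}: time_s mixes numeric seconds and ISO timestamps; use one representation"
        )
    bad = raw[numeric.isna() & stamps.isna()].index[:5].tolist()
    raise SchemaError(f"{path}: unparseable time_s values at rows {bad}")


def load_records(path: str | Path) -> list[ObserverRecord]:
    """Read and validate an observer-record CSV.

    Raises :class:`SchemaError` for missing columns and
    :class:`RecordValidationError` (listing offending row numbers) when rows
    violate record invariants.
    """
    df = pd.read_csv(path, dtype={"record_id": str, "taxon_code": str})
    required = [c for c in RECORD_COLUMNS if c not in ("lat", "lon")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"records CSV {path} missing column(s): {', '.join(missing)}")
    for opt in ("lat", "lon"):
        if opt not in df.columns:
            df[opt] = float("nan")
    df["time_s"] = _times_to_seconds(df["time_s"], path)

    records: list[ObserverRecord] = []
    errors: list[str] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df[RECORD_COLUMNS].to_dict("records")):
        rownum = i + 2  # 1-based, after header
        try:
            count_raw = row["count"]
            if float(count_raw) != int(float(count_raw)):
                raise ValueError(f"count {count_raw!r} is not an integer")
            rec = ObserverRecord(
                record_id=str(row["record_id"]),
                survey_event=str(row["survey_event"]),
                unit_id=str(row["unit_id"]),
                transect_id=str(row["transect_id"]),
                side=str(row["side"]),
                seat=str(row["seat"]),
                observer_id=str(row["observer_id"]),
                time_s=float(row["time_s"]),
                taxon_code=str(row["taxon_code"]),
                count=int(float(count_raw)),
                lat=None if pd.isna(row["lat"]) else float(row["lat"]),
                lon=None if pd.isna(row["lon"]) else float(row["lon"]),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {rownum}: {exc}")
            continue
        key = (rec.survey_event, rec.record_id)
        if key in seen:
            errors.append(f"row {rownum}: duplicate (survey_event, record_id) {key}")
            continue
        seen.add(key)
        records.append(rec)
    if errors:
        raise RecordValidationError(errors)
    return records


def records_to_frame(records: Iterable[ObserverRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records], columns=RECORD_COLUMNS)
    return df


def write_records(records: Iterable[ObserverRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def shift_times(records: Iterable[ObserverRecord], offset_s: float) -> list[ObserverRecord]:
    """Apply a per-stream clock offset (seconds) to every record.

    Useful when front and rear data computers were imperfectly synchronized:
    shift one stream before matching rather than widening the window.
    """
    return [replace(r, time_s=r.time_s + offset_s) for r in records]
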