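"""Shared fixtures: a small waterbird taxonomy and an observer-record factory."""

import pytest

from doublecount.records import ObserverRecord, TaxonomyTable
from doublecount.simulate import default_taxonomy


@pytest.fixture(scope="session")
def tax() -> TaxonomyTable:
    return default_taxonomy()


@pytest.fixture
def make_record():
    """Factory for ObserverRecords with sensible defaults."""

    counter = {"n": 0}

    def _make(**kwargs) -> ObserverRecord:
        counter["n"] += 1
        defaults = dict(
            record_id=f"r{counter['n']:03d}",
            survey_event="winter2018",
            unit_id="U1",
            transect_id="T1",
            side="left",
            seat="front",
            observer_id="obsA",
            time_s=0.0,
            taxon_code="NOGA",
            count=1,
        )
        defaults.update(kwargs)
        return ObserverRecord(**defaults)

    return _make
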