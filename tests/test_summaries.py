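"""Category tables, agreement rates, naive detection, missed-size shares."""

import numpy as np
import pytest

from doublecount.matcher import MatchCategory, ReconciledEvent, reconcile_records
from doublecount.simulate import SimConfig, simulate_survey
from doublecount.summaries import (
    CategoryTable,
    ObserverSession,
    aggregate_shares,
    agreement_rates,
    category_percentages,
    category_table,
    missed_size_distribution,
    naive_detection,
)
from _table_fixtures import SEASON_CATEGORY_COUNTS


def paired_event(make_record, tax, taxon_a, count_a, taxon_b, count_b, **kwargs):
    from doublecount.matcher import classify_event

    f = make_record(seat="front", taxon_code=taxon_a, count=count_a, **kwargs)
    r = make_record(
        seat="rear", observer_id="obsB", taxon_code=taxon_b, count=count_b, **kwargs
    )
    return ReconciledEvent(front=f, rear=r, category=classify_event(f, r, tax), dt_s=0.0)


def singleton(make_record, seat="front", count=1, **kwargs):
    rec = make_record(seat=seat, **dict(kwargs, count=count))
    return ReconciledEvent(
        front=rec if seat == "front" else None,
        rear=rec if seat == "rear" else None,
        category=MatchCategory.NO_MATCH,
    )


@pytest.fixture(scope="module")
def season_table():
    return CategoryTable.from_counts(SEASON_CATEGORY_COUNTS)


class TestCategoryTable:
    def test_single_category_single_survey(self, make_record, tax):
        events = [paired_event(make_record, tax, "NOGA", 1, "NOGA", 1) for _ in range(10)]
        tab = category_table(events)
        assert tab.counts.loc["winter2018", "SpeciesCountMatch"] == 10
        assert tab.total == 10

    def test_empty_event_list(self):
        tab = category_table([])
        assert tab.total == 0
        assert category_percentages(tab).empty

    def test_season_fixture_reproduces_published_percentages(self, season_table):
        pct = category_percentages(season_table)["overall_pct"]
        expected = {
            "SpeciesCountMatch": 32.5, "GenericCountMatch": 4.5, "SpeciesBinMatch": 7.5,
            "GenericBinMatch": 4.2, "SpeciesOnlyMatch": 1.2, "GenericOnlyMatch": 0.3,
            "Mismatch": 13.8, "NoMatch": 36.0,
        }
        for cat, val in expected.items():
            assert pct[cat] == pytest.approx(val, abs=0.101)
        assert pct.sum() == pytest.approx(100.0, abs=0.1)

    def test_season_totals_match_event_counts(self, season_table):
        totals = season_table.event_totals()
        assert totals["winter2018"] == 2056
        assert totals["summer2018"] == 1620
        assert totals["winter2019"] == 1706
        assert season_table.total == 5382

    def test_single_category_table_is_100_percent(self):
        tab = CategoryTable.from_counts({"e": {"Mismatch": 7}})
        assert category_percentages(tab).loc["Mismatch", "overall_pct"] == 100.0


class TestAggregateShares:
    def test_derived_agreement_shares(self, season_table):
        shares = aggregate_shares(season_table)
        assert round(shares["bin_level_pct"]) == 49
        assert round(shares["exact_count_pct"]) == 37
        assert round(shares["species_id_pct"]) == 41
        assert round(shares["generic_id_pct"]) == 9
        assert shares["mismatch_pct"] == pytest.approx(13.8, abs=0.05)
        assert shares["bin_level_pct"] >= shares["exact_count_pct"]


class TestAgreementRates:
    def test_small_fixture_arithmetic(self, make_record, tax):
        events = [
            paired_event(make_record, tax, "NOGA", 3, "NOGA", 3),  # exact
            paired_event(make_record, tax, "gull", 2, "tern", 2),  # exact (generic)
            paired_event(make_record, tax, "NOGA", 12, "NOGA", 45),  # bin only
            paired_event(make_record, tax, "NOGA", 4, "NOGA", 30),  # species only
        ]
        rates = agreement_rates(events).set_index("size_class")
        assert rates.loc["all", "exact_count_pct"] == pytest.approx(50.0)
        assert rates.loc["all", "bin_level_pct"] == pytest.approx(75.0)

    def test_size_class_uses_larger_count(self, make_record, tax):
        events = [paired_event(make_record, tax, "NOGA", 4, "NOGA", 30)]
        rates = agreement_rates(events).set_index("size_class")
        assert rates.loc["6-30", "n"] == 1
        assert "1-5" not in rates.index  # empty classes are absent, not zero

    def test_singletons_excluded_from_denominators(self, make_record, tax):
        events = [paired_event(make_record, tax, "NOGA", 1, "NOGA", 1)] + [
            singleton(make_record) for _ in range(5)
        ]
        rates = agreement_rates(events).set_index("size_class")
        assert rates.loc["all", "n"] == 1

    def test_undercount_widens_bin_vs_exact_gap_for_large_flocks(self):
        """Size-growing count error: the bin-minus-exact agreement gap is
        larger for 31+ flocks than for 1-5 flocks."""
        gaps = {"1-5": [], "31+": []}
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_flocks=3000, spacing_dist="fixed")
            d = simulate_survey(cfg)
            events = reconcile_records(d.front + d.rear, d.taxonomy)
            rates = agreement_rates(events).set_index("size_class")
            for cls in gaps:
                if cls in rates.index:
                    gaps[cls].append(
                        rates.loc[cls, "bin_level_pct"] - rates.loc[cls, "exact_count_pct"]
                    )
        assert np.mean(gaps["31+"]) > np.mean(gaps["1-5"])


class TestNaiveDetection:
    def _sessions(self):
        return [
            ObserverSession("winter2018", "obsA", "obsB", "left", "front"),
            ObserverSession("winter2018", "obsB", "obsA", "left", "rear"),
        ]

    def test_definition_arithmetic(self, make_record, tax):
        events = [paired_event(make_record, tax, "NOGA", 1, "NOGA", 1) for _ in range(80)]
        # 20 rear-only singletons: obsB saw them, obsA (front) missed them
        events += [singleton(make_record, seat="rear", observer_id="obsB") for _ in range(20)]
        det = naive_detection(events, self._sessions())
        assert det.loc["obsA", "winter2018"] == pytest.approx(0.80)
        assert det.loc["obsB", "winter2018"] == pytest.approx(1.00)

    def test_all_paired_gives_one(self, make_record, tax):
        events = [paired_event(make_record, tax, "NOGA", 1, "NOGA", 1) for _ in range(5)]
        det = naive_detection(events, self._sessions())
        assert det.loc["obsA", "winter2018"] == 1.0
        assert det.loc["obsB", "winter2018"] == 1.0

    def test_simulated_recovery_and_seat_swap_symmetry(self):
        """Naive detection recovers the configured probabilities, and
        swapping the observers' seats swaps their estimates."""
        cfg = SimConfig.independent_detection(0.9, 0.7, 4000, seed=11)
        d = simulate_survey(cfg)
        det = naive_detection(reconcile_records(d.front + d.rear, d.taxonomy), d.sessions)
        assert det.loc["front1", "sim"] == pytest.approx(0.9, abs=0.02)
        assert det.loc["rear1", "sim"] == pytest.approx(0.7, abs=0.02)

        swapped = SimConfig.independent_detection(0.7, 0.9, 4000, seed=11)
        d2 = simulate_survey(swapped)
        det2 = naive_detection(reconcile_records(d2.front + d2.rear, d2.taxonomy), d2.sessions)
        assert det2.loc["front1", "sim"] == pytest.approx(det.loc["rear1", "sim"], abs=0.02)
        assert det2.loc["rear1", "sim"] == pytest.approx(det.loc["front1", "sim"], abs=0.02)


class TestMissedSizeDistribution:
    def test_share_arithmetic(self, make_record):
        events = [singleton(make_record, count=c) for c in (1, 1, 1, 2)]
        dist = missed_size_distribution(events).set_index("size_class")
        assert dist.loc["1", "share"] == pytest.approx(0.75)
        assert dist["share"].sum() == pytest.approx(1.0)

    def test_no_singletons_gives_empty(self, make_record, tax):
        events = [paired_event(make_record, tax, "NOGA", 1, "NOGA", 1)]
        assert missed_size_distribution(events).empty

    def test_misses_concentrate_at_small_sizes_under_sizedependent_detection(self):
        cfg = SimConfig(seed=5, n_flocks=5000, spacing_dist="fixed")
        d = simulate_survey(cfg)
        events = reconcile_records(d.front + d.rear, d.taxonomy)
        dist = missed_size_distribution(events).set_index("size_class")
        shares = [dist.loc[c, "share"] if c in dist.index else 0.0 for c in ("1", "2-5", "6-30", "31+")]
        assert shares[0] == max(shares)
        assert shares[0] > 0.5  # most missed observations are single birds
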