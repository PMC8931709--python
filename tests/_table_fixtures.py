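"""Worked category-count fixture for a three-season double-observer survey."""

#: Match-category counts per survey season (winter 2018 / summer 2018 /
#: winter 2019 layout). Season totals are 2056, 1620 and 1706 events.
SEASON_CATEGORY_COUNTS = {
    "winter2018": {
        "SpeciesCountMatch": 645, "GenericCountMatch": 86, "SpeciesBinMatch": 144,
        "GenericBinMatch": 84, "SpeciesOnlyMatch": 25, "GenericOnlyMatch": 11,
        "Mismatch": 339, "NoMatch": 722,
    },
    "summer2018": {
        "SpeciesCountMatch": 458, "GenericCountMatch": 71, "SpeciesBinMatch": 150,
        "GenericBinMatch": 88, "SpeciesOnlyMatch": 17, "GenericOnlyMatch": 3,
        "Mismatch": 219, "NoMatch": 614,
    },
    "winter2019": {
        "SpeciesCountMatch": 651, "GenericCountMatch": 85, "SpeciesBinMatch": 111,
        "GenericBinMatch": 54, "SpeciesOnlyMatch": 20, "GenericOnlyMatch": 3,
        "Mismatch": 184, "NoMatch": 598,
    },
}
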