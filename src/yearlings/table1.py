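"""Packaged community summary for the boreal-forest study.

A 29-species table of per-species capture summaries from a six-year,
35-station constant-effort mist-netting study in the oil sands region of
northeastern Alberta: stations with captures, year-unique adult individuals,
SY/ASY/AHY counts, recapture-based age-change rates with their sample sizes,
and yearling proportions. Station counts are stored as printed in the source
table (a handful exceed the 35 operated stations).

The module also carries the study-level capture totals needed for
aging-completeness arithmetic that is not derivable from the per-species
rows (total handlings including within-season recaptures, and the
photographic re-determination counts for birds first aged AHY).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: study window (inclusive calendar years) and station count
STUDY_YEARS = (2011, 2016)
N_YEARS = 6
N_STATIONS = 35

#: total adult handlings, including within-season recaptures
TOTAL_ADULT_CAPTURES = 18_799
#: handlings initially aged AHY in the field
INITIAL_AHY_CAPTURES = 4_754
#: of those, re-determined to SY or ASY after photographic review
REDETERMINED_AHY_CAPTURES = 3_131


def load_table1() -> pd.DataFrame:
    """The packaged 29-species summary table.

    Columns: ``species_code, common_name, n_stations, n_year_inds, n_SY,
    n_ASY, n_AHY, error_rate, n_eligible, yearling_prop`` — the last is the
    proportion as printed (3 decimals) and is redundant with the counts.
    """
    with resources.files("yearlings.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    assert len(df) == 29
    return df
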