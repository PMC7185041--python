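"""Curation of constant-effort banding capture records.

Turns a raw capture stream (one row per handling of a banded bird) into the
analysis unit of the pipeline: the *year-unique individual*, i.e. one banded
bird counted once per calendar year, recounted if it returns in a later year.
Adults are aged in the hand as yearling (SY, second calendar year), older
(ASY, after second year), or indeterminate adult (AHY); juveniles (HY,
hatching year) are retained through parsing but excluded from the adult
tables.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column names expected after schema mapping
REQUIRED_COLUMNS = ("band_id", "species_code", "station_id", "date", "age")


class AgeClass(str, enum.Enum):
    """Field age codes for captured landbirds."""

    HY = "HY"    #: hatching-year juvenile
    SY = "SY"    #: second-calendar-year adult ("yearling")
    ASY = "ASY"  #: after-second-year adult (older than yearling)
    AHY = "AHY"  #: adult of indeterminate age (SY vs. ASY unresolved)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


VALID_AGES = frozenset(a.value for a in AgeClass)
DETERMINATE_ADULT = frozenset({"SY", "ASY"})
ADULT_AGES = frozenset({"SY", "ASY", "AHY"})


@dataclass
class ParseReport:
    """Bookkeeping from :func:`read_captures`."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped_age: int = 0
    n_dropped_date: int = 0
    dropped_age_codes: dict = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_age + self.n_dropped_date


@dataclass
class ConflictReport:
    """Within-year age conflicts found by :func:`resolve_year_unique`."""

    n_band_years: int = 0
    n_sy_asy_conflicts: int = 0
    n_hy_only_excluded: int = 0


def read_captures(path, schema: dict | None = None,
                  year_range: tuple[int, int] | None = None) -> pd.DataFrame:
    """Read and validate a delimited capture file.

    Parameters
    ----------
    path
        CSV file with a header row. Dates must be ISO-8601.
    schema
        Optional mapping from canonical names (``band_id``, ``species_code``,
        ``station_id``, ``date``, ``age``) to the column names used in the
        file, so banding-lab export dialects can be adapted without code
        changes. Canonical names are used when omitted.
    year_range
        Inclusive ``(first, last)`` study window; records outside it are
        rejected with a hard error (they indicate the wrong input file).

    Returns
    -------
    DataFrame with columns ``band_id, species_code, station_id, date, year,
    age, capture_index`` where ``capture_index`` is the ordinal of the capture
    within its band-year (date order, ties by file order). Rows with an
    unrecognised age code or an unparseable date are dropped; the counts are
    logged and attached as ``df.attrs["parse_report"]``.

    Raises
    ------
    ValueError
        If the file is empty or a required column is missing.
    """
    schema = schema or {}
    raw = pd.read_csv(path, dtype=str)
    if raw.empty:
        raise ValueError(f"capture file {path!s} contains no records")
    rename = {v: k for k, v in schema.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(
            f"capture file {path!s} is missing required column(s) {missing}; "
            f"found {list(raw.columns)}")

    report = ParseReport(n_read=len(raw))
    df = raw.loc[:, list(REQUIRED_COLUMNS)].copy()
    df["age"] = df["age"].str.strip().str.upper()

    bad_age = ~df["age"].isin(VALID_AGES)
    if bad_age.any():
        counts = df.loc[bad_age, "age"].value_counts().to_dict()
        report.n_dropped_age = int(bad_age.sum())
        report.dropped_age_codes = {str(k): int(v) for k, v in counts.items()}
        logger.warning("dropped %d record(s) with unknown age code(s) %s",
                       report.n_dropped_age, counts)
        df = df.loc[~bad_age]

    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    bad_date = dates.isna()
    if bad_date.any():
        report.n_dropped_date = int(bad_date.sum())
        logger.warning("dropped %d record(s) with malformed date(s)",
                       report.n_dropped_date)
        df = df.loc[~bad_date]
        dates = dates.loc[~bad_date]
    df["date"] = dates
    df["year"] = dates.dt.year.astype(int)

    if year_range is not None:
        lo, hi = year_range
        outside = (df["year"] < lo) | (df["year"] > hi)
        if outside.any():
            raise ValueError(
                f"{int(outside.sum())} record(s) outside the study window "
                f"{lo}-{hi}; first offending year "
                f"{int(df.loc[outside, 'year'].iloc[0])}")

    df = df.sort_values(["band_id", "year", "date"],
                        kind="stable").reset_index(drop=True)
    df["capture_index"] = df.groupby(["band_id", "year"]).cumcount()
    report.n_kept = len(df)
    if report.n_kept == 0:
        raise ValueError(f"no valid capture records in {path!s}")
    logger.info("read %d capture records (%d dropped) from %s",
                report.n_kept, report.n_dropped, path)
    df.attrs["parse_report"] = report
    return df


def resolve_year_unique(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse a capture stream to one row per (band, year).

    A band-year's resolved age is determinate (SY or ASY) if *any* capture
    that year was determinate; among conflicting determinate calls the latest
    by date wins, since later handlings (and photographic review) supersede
    earlier field calls. Band-years seen only as AHY resolve to AHY.
    Juvenile-only (HY) band-years are excluded here, not at parse time, so
    juvenile counts remain available upstream for diagnostics.

    The station and species of a year-unique individual are those of its
    first capture that year.

    Returns a DataFrame ``band_id, species_code, station_id, year,
    resolved_age`` with a :class:`ConflictReport` in
    ``df.attrs["conflict_report"]``.
    """
    df = records.sort_values(["band_id", "year", "date", "capture_index"],
                             kind="stable")
    key = ["band_id", "year"]

    adult = df[df["age"].isin(ADULT_AGES)]
    first = adult.drop_duplicates(key, keep="first")

    det = adult[adult["age"].isin(DETERMINATE_ADULT)]
    last_det = det.drop_duplicates(key, keep="last").set_index(key)["age"]

    out = first.set_index(key)
    resolved = last_det.reindex(out.index)
    resolved = resolved.fillna(pd.Series("AHY", index=out.index))
    out = out.assign(resolved_age=resolved).reset_index()
    out = out[["band_id", "species_code", "station_id", "year",
               "resolved_age"]].reset_index(drop=True)

    n_all_band_years = df.drop_duplicates(key).shape[0]
    per_year_ages = det.groupby(key)["age"].nunique()
    report = ConflictReport(
        n_band_years=len(out),
        n_sy_asy_conflicts=int((per_year_ages > 1).sum()),
        n_hy_only_excluded=n_all_band_years - len(out),
    )
    if report.n_sy_asy_conflicts:
        logger.warning("%d band-year(s) had conflicting SY/ASY calls; "
                       "latest determination kept", report.n_sy_asy_conflicts)
    out.attrs["conflict_report"] = report
    return out


def filter_target_species(individuals: pd.DataFrame, n_years: int,
                          min_mean_per_year: float = 20.0) -> list[str]:
    """Species with a mean of at least ``min_mean_per_year`` adult
    year-unique individuals (SY, ASY and AHY) captured per year.

    ``n_years`` is the length of the study period, not the number of years a
    species happened to be caught in.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    counts = individuals.groupby("species_code").size()
    keep = counts[counts / n_years >= min_mean_per_year]
    return sorted(keep.index)


def summarize_species(individuals: pd.DataFrame) -> pd.DataFrame:
    """Per-species capture summary (stations, year-individuals, age counts).

    Output columns: ``species_code, n_stations, n_year_inds, n_SY, n_ASY,
    n_AHY``, one row per species, sorted by species code. Totals are
    conserved: the age-class counts of each row sum to its ``n_year_inds``.
    """
    cols = ["species_code", "n_stations", "n_year_inds",
            "n_SY", "n_ASY", "n_AHY"]
    if individuals.empty:
        return pd.DataFrame(columns=cols)
    g = individuals.groupby("species_code")
    out = pd.DataFrame({
        "n_stations": g["station_id"].nunique(),
        "n_year_inds": g.size(),
    })
    age_counts = (individuals.pivot_table(index="species_code",
                                          columns="resolved_age",
                                          aggfunc="size", fill_value=0))
    for age in ("SY", "ASY", "AHY"):
        out[f"n_{age}"] = age_counts.get(age, 0)
    out = out.reset_index()[cols]
    assert (out[["n_SY", "n_ASY", "n_AHY"]].sum(axis=1)
            == out["n_year_inds"]).all()
    return out.sort_values("species_code").reset_index(drop=True)


def write_species_summary(summary: pd.DataFrame, path) -> None:
    """Write the species-summary table with its contract columns."""
    cols = ["species_code", "n_stations", "n_year_inds",
            "n_SY", "n_ASY", "n_AHY"]
    summary[cols].to_csv(path, index=False)
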