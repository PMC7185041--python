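"""Station-scale habitat covariates: EVI aggregation and in-situ cover.

The remote-sensed covariate is the Enhanced Vegetation Index (EVI), a
MODIS-derived greenness measure on 0.25 km cells. Each station is
represented by a 9x9 grid of 81 cells (the area effectively sampled by a
constant-effort station); two June composites per year are averaged into a
single station-year EVI. Grid extraction from satellite imagery is upstream
of this package — cell values arrive in a long-format CSV.

In-situ metrics are cover percentages in three vegetation strata
(understory 0.5-5 m, midstory 5-15 m, upperstory >15 m) estimated per broad
habitat type and combined into station-scale values weighted by the
habitat-type proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

EVI_VALID_RANGE = (-0.2, 1.0)
CELLS_PER_COMPOSITE = 81
STRATA = ("understory", "midstory", "upperstory")

#: OLS condition-number threshold above which a collinearity warning is logged
COLLINEARITY_CONDITION_THRESHOLD = 30.0


def read_evi_cells(path) -> pd.DataFrame:
    """Long-format EVI cell CSV: ``station_id, year, composite_date,
    cell_row, cell_col, value``. Values outside the physical EVI range are a
    hard error; empty cells (blank value) are kept as NaN — missing, never
    zero-filled."""
    df = pd.read_csv(path, dtype={"station_id": str})
    required = {"station_id", "year", "composite_date", "cell_row",
                "cell_col", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"EVI cell file missing column(s) {sorted(missing)}")
    vals = df["value"]
    bad = vals.notna() & ((vals < EVI_VALID_RANGE[0]) |
                          (vals > EVI_VALID_RANGE[1]))
    if bad.any():
        raise ValueError(f"{int(bad.sum())} EVI value(s) outside "
                         f"{EVI_VALID_RANGE}")
    return df


def station_year_evi(cells: pd.DataFrame) -> pd.DataFrame:
    """Mean EVI per station-year over the two June composites.

    Each station-year must carry exactly two composite dates with 81 cells
    each; missing cells (NaN) are excluded from the mean and counted. The
    mean is over the up-to-162 available values, so it is invariant to cell
    ordering. A station-year with no available cell gets NaN and is flagged.

    Returns ``station_id, year, evi, n_cells, n_missing``.
    """
    rows = []
    for (sid, year), grp in cells.groupby(["station_id", "year"]):
        dates = grp["composite_date"].unique()
        if len(dates) != 2:
            raise ValueError(
                f"station {sid} year {year}: expected 2 June composites, "
                f"found {len(dates)}")
        counts = grp.groupby("composite_date").size()
        if (counts != CELLS_PER_COMPOSITE).any():
            raise ValueError(
                f"station {sid} year {year}: composites must have "
                f"{CELLS_PER_COMPOSITE} cells, found {counts.to_dict()}")
        vals = grp["value"].to_numpy(dtype=float)
        n_missing = int(np.isnan(vals).sum())
        if n_missing == vals.size:
            logger.warning("station %s year %s: all EVI cells missing",
                           sid, year)
            mean = np.nan
        else:
            mean = float(np.nanmean(vals))
        rows.append({"station_id": sid, "year": int(year), "evi": mean,
                     "n_cells": vals.size - n_missing,
                     "n_missing": n_missing})
    return pd.DataFrame(rows)


def center_covariate(values) -> tuple[np.ndarray, float]:
    """Center a covariate at zero; the stored mean allows intercepts to be
    mapped back to the raw scale. Dropping the mean and re-adding it is an
    exact round trip."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot center an empty covariate")
    mean = float(np.nanmean(arr))
    return arr - mean, mean


def years_since_reclamation(year, reclamation_start) -> np.ndarray:
    """Data year minus reclamation start year, clamped at 0; un-reclaimed
    stations (missing start year) are 0 years since reclamation."""
    year = np.asarray(year, dtype=float)
    start = np.asarray(reclamation_start, dtype=float)
    out = np.where(np.isnan(start), 0.0, np.clip(year - start, 0, None))
    return out


def weighted_station_cover(habitat: pd.DataFrame) -> pd.DataFrame:
    """Station-scale cover per stratum, weighted by habitat-type proportion.

    ``habitat`` is long by (station, habitat type) with columns
    ``station_id, habitat_type, proportion, understory_cover,
    midstory_cover, upperstory_cover``. Proportions must sum to 1 within
    0.01 per station.
    """
    sums = habitat.groupby("station_id")["proportion"].sum()
    off = sums[(sums - 1.0).abs() > 0.01]
    if not off.empty:
        raise ValueError(
            "habitat-type proportions must sum to 1 +/- 0.01; offending "
            f"station(s): {off.to_dict()}")
    rows = []
    for sid, grp in habitat.groupby("station_id"):
        w = grp["proportion"].to_numpy(dtype=float)
        row = {"station_id": sid}
        for stratum in STRATA:
            row[stratum] = float(w @ grp[f"{stratum}_cover"]
                                 .to_numpy(dtype=float))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StandardizedFit:
    """OLS fit on unit-variance response and predictors."""

    terms: list[str]
    coef: np.ndarray            #: standardized slopes, one per term
    ci_low: np.ndarray
    ci_high: np.ndarray
    r_squared: float
    condition_number: float
    resid_quantiles: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coef": [float(c) for c in self.coef],
            "ci_low": [float(c) for c in self.ci_low],
            "ci_high": [float(c) for c in self.ci_high],
            "r_squared": float(self.r_squared),
            "condition_number": float(self.condition_number),
            "resid_quantiles": self.resid_quantiles,
            "warnings": list(self.warnings),
        }


def standardized_ols(y, X: pd.DataFrame) -> StandardizedFit:
    """OLS with response and every predictor scaled to zero mean and unit
    sample (n-1) standard deviation; normal-theory 95% CIs.

    Standardized slopes are invariant to affine rescaling of the raw
    predictors, which makes coefficients comparable across covariates with
    different units.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != y.size:
        raise ValueError("response and predictors must have equal length")
    if y.size < len(X.columns) + 2:
        raise ValueError("too few rows for the requested regression")
    zy = (y - y.mean()) / y.std(ddof=1)
    Z = pd.DataFrame({c: (X[c] - X[c].mean()) / X[c].std(ddof=1)
                      for c in X.columns})
    model = sm.OLS(zy, sm.add_constant(Z))
    res = model.fit()
    ci = res.conf_int(alpha=0.05)
    terms = list(X.columns)
    warnings = []
    if res.condition_number > COLLINEARITY_CONDITION_THRESHOLD:
        msg = (f"predictors near-collinear (condition number "
               f"{res.condition_number:.1f})")
        warnings.append(msg)
        logger.warning(msg)
    std_resid = res.resid / np.std(res.resid, ddof=len(terms) + 1)
    qs = np.quantile(std_resid, [0.025, 0.25, 0.5, 0.75, 0.975])
    fit = StandardizedFit(
        terms=terms,
        coef=res.params[terms].to_numpy(),
        ci_low=ci.loc[terms, 0].to_numpy(),
        ci_high=ci.loc[terms, 1].to_numpy(),
        r_squared=float(res.rsquared),
        condition_number=float(res.condition_number),
        resid_quantiles={f"q{p}": float(v) for p, v in
                         zip((2.5, 25, 50, 75, 97.5), qs)},
        warnings=warnings,
    )
    return fit


def evi_regression(rows: pd.DataFrame) -> StandardizedFit:
    """Two-predictor regression of station-year EVI on percent natural cover
    and years since reclamation, for the disturbed and reclaimed stations
    (un-reclaimed stations enter at zero years since reclamation).

    ``rows`` needs columns ``evi, pct_natural, years_reclaimed``.
    """
    return standardized_ols(rows["evi"],
                            rows[["pct_natural", "years_reclaimed"]])
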