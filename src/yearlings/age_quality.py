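"""Age-determination accuracy from recapture histories.

Birds are re-aged independently at every handling, so a bird captured more
than once carries an internal consistency check: a determinate call (SY or
ASY) can be propagated forward in calendar time and compared with the next
determinate call. A disagreement means at least one of the two
determinations was wrong. The per-species *change rate* — changed
comparisons over eligible comparisons — is the field's standard proxy for
the age-misclassification rate; if each independent determination errs with
probability ``e``, paired same-year determinations disagree with probability
``2e(1-e)``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .capture_data import DETERMINATE_ADULT

logger = logging.getLogger(__name__)


def propagate_age(age_at_ref: str, elapsed_years: int) -> str:
    """Advance an age class ``elapsed_years`` calendar years.

    A yearling (SY) becomes an older adult (ASY) after one year; ASY is
    absorbing; AHY carries no information and stays AHY. The juvenile class
    HY is also supported (HY -> SY after one year, ASY after two or more)
    although recapture-eligibility below only ever uses determinate adult
    priors.
    """
    elapsed_years = int(elapsed_years)
    if elapsed_years < 0:
        raise ValueError("elapsed_years must be >= 0")
    age = str(age_at_ref)
    if age == "AHY":
        return "AHY"
    if age == "ASY":
        return "ASY"
    if age == "SY":
        return "SY" if elapsed_years == 0 else "ASY"
    if age == "HY":
        return ("HY", "SY")[elapsed_years] if elapsed_years <= 1 else "ASY"
    raise ValueError(f"unknown age class {age_at_ref!r}")


def build_age_histories(captures: pd.DataFrame) -> pd.DataFrame:
    """Chronologically sorted capture stream restricted to adult records of
    birds handled more than once (the only birds that can contribute
    recapture comparisons)."""
    df = captures[captures["age"] != "HY"]
    df = df.sort_values(["band_id", "year", "date", "capture_index"],
                        kind="stable")
    multi = df["band_id"].duplicated(keep=False)
    return df.loc[multi].reset_index(drop=True)


def age_error_rates(captures: pd.DataFrame) -> pd.DataFrame:
    """Per-species age-change rates from the full capture stream.

    For every capture with a *prior determinate* determination of the same
    bird, the prior call is propagated to the current year and compared with
    the current call when that is itself determinate; the comparison is
    eligible, and counts as changed when the two disagree. The reference then
    moves to the current determination (errors are localised to the most
    recent comparison rather than accumulated against the first-ever call).
    Captures aged AHY neither form comparisons nor update the reference.

    Returns one row per species seen in the stream: ``species_code,
    n_eligible, n_changed, rate`` with ``rate = NaN`` (undefined, flagged)
    when a species has no eligible comparison.
    """
    hist = build_age_histories(captures)
    eligible: dict[str, int] = {}
    changed: dict[str, int] = {}

    for band_id, grp in hist.groupby("band_id", sort=False):
        prior_age = None
        prior_year = None
        for species, year, age in zip(grp["species_code"], grp["year"],
                                      grp["age"]):
            if age in DETERMINATE_ADULT:
                if prior_age is not None:
                    expected = propagate_age(prior_age, year - prior_year)
                    eligible[species] = eligible.get(species, 0) + 1
                    if age != expected:
                        changed[species] = changed.get(species, 0) + 1
                prior_age, prior_year = age, year

    species = sorted(captures.loc[captures["age"] != "HY",
                                  "species_code"].unique())
    out = pd.DataFrame({"species_code": species})
    out["n_eligible"] = out["species_code"].map(eligible).fillna(0).astype(int)
    out["n_changed"] = out["species_code"].map(changed).fillna(0).astype(int)
    with np.errstate(invalid="ignore"):
        out["rate"] = np.where(out["n_eligible"] > 0,
                               out["n_changed"] / out["n_eligible"], np.nan)
    n_undef = int(out["rate"].isna().sum())
    if n_undef:
        logger.info("%d species with no eligible recapture comparison "
                    "(rate undefined)", n_undef)
    return out


def community_mean_error(estimates: pd.DataFrame) -> float:
    """Unweighted mean of the defined per-species change rates."""
    rates = estimates["rate"].dropna()
    if rates.empty:
        raise ValueError("no species with a defined error rate")
    return float(rates.mean())


def percent_aged(n_SY, n_ASY, n_AHY):
    """Share of adult year-unique individuals resolved to SY or ASY.

    Accepts scalars or aligned arrays; returns NaN (flagged by the caller)
    where a species has no adults at all. Equals 1 exactly when no bird was
    left at AHY.
    """
    n_SY = np.asarray(n_SY, dtype=float)
    n_ASY = np.asarray(n_ASY, dtype=float)
    n_AHY = np.asarray(n_AHY, dtype=float)
    total = n_SY + n_ASY + n_AHY
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (n_SY + n_ASY) / total, np.nan)
    return float(out) if out.ndim == 0 else out


def error_table(estimates: pd.DataFrame) -> pd.DataFrame:
    """Per-species error table plus a one-row community summary.

    The community row carries the unweighted mean rate and the pooled
    eligible/changed totals under the pseudo-code ``ALL``.
    """
    mean_rate = community_mean_error(estimates)
    community = pd.DataFrame([{
        "species_code": "ALL",
        "n_eligible": int(estimates["n_eligible"].sum()),
        "n_changed": int(estimates["n_changed"].sum()),
        "rate": mean_rate,
    }])
    return pd.concat([estimates, community], ignore_index=True)
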