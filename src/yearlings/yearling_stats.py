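"""Yearling-proportion statistics.

The yearling proportion of a sample is SY / (SY + ASY): the share of
determinate-aged adults that are in their second calendar year.
Indeterminate (AHY) adults never enter the numerator or denominator here;
they are accounted for by the aging-completeness statistic and, in the
hierarchical model, as latent outcomes.

Two community-level summaries exist and differ: the *species mean* (the
unweighted mean of per-species proportions, the community statistic reported
by this pipeline) and the *pooled ratio* (total SY over total determinate
adults, dominated by abundant species). Both are exposed, under distinct
names.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Presentation rounding: half-up at ``ndigits`` decimals.

    Counts are exact integers throughout the pipeline; proportions are only
    rounded at presentation, half-up to match conventional table formatting
    (numpy/python banker's rounding would turn 0.4135 into 0.413).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def yearling_proportion(n_SY, n_ASY):
    """SY / (SY + ASY); NaN (undefined, flagged) when both counts are zero.

    Accepts scalars or aligned arrays.
    """
    n_SY = np.asarray(n_SY, dtype=float)
    n_ASY = np.asarray(n_ASY, dtype=float)
    denom = n_SY + n_ASY
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, n_SY / denom, np.nan)
    return float(out) if out.ndim == 0 else out


def community_mean_proportion(per_species) -> float:
    """Unweighted mean over species of defined yearling proportions."""
    props = pd.Series(per_species, dtype=float).dropna()
    if props.empty:
        raise ValueError("no species with a defined yearling proportion")
    return float(props.mean())


def pooled_proportion(summary: pd.DataFrame) -> float:
    """Pooled ratio: total SY over total determinate adults, all species."""
    sy = float(summary["n_SY"].sum())
    asy = float(summary["n_ASY"].sum())
    if sy + asy == 0:
        raise ValueError("no determinate-aged adults")
    return sy / (sy + asy)


def species_table(summary: pd.DataFrame,
                  error_rates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-species derived table: ``species_code, error_rate, n_eligible,
    yearling_proportion`` (error columns NaN/0 when no error estimates are
    supplied)."""
    out = summary[["species_code"]].copy()
    if error_rates is not None:
        err = error_rates.set_index("species_code")
        out["error_rate"] = err["rate"].reindex(out["species_code"]).values
        out["n_eligible"] = (err["n_eligible"].reindex(out["species_code"])
                             .fillna(0).astype(int).values)
    else:
        out["error_rate"] = np.nan
        out["n_eligible"] = 0
    out["yearling_proportion"] = yearling_proportion(summary["n_SY"],
                                                     summary["n_ASY"])
    return out
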