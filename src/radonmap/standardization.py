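"""Indirect standardization: expected counts and standardized incidence ratios.

Expected counts are computed by applying reference incidence rates per
(sex, five-year age group) stratum to each region's population structure;
the standardized incidence ratio is SIR_i = O_i / E_i. Reference rates
default to internal (pooled over all regions) standardization, under which
the totals close exactly: sum O = sum E, so the E-weighted mean SIR is 1.

The denominator is a single population snapshot (not accumulated
person-years), mirroring the registry convention of the source analysis:
SIRs are internally consistent ratios, not absolute rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_STRATA_COLS = ["region_id", "sex", "age_group", "population", "observed"]


def _check_strata(strata: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _STRATA_COLS if c not in strata.columns]
    if missing:
        raise ValueError(f"strata table lacks columns {missing}")
    if (strata["population"] < 0).any() or (strata["observed"] < 0).any():
        raise ValueError("populations and observed counts must be nonnegative")
    if (strata["observed"] > strata["population"]).any():
        raise ValueError("observed cases exceed population in some strata")
    return strata


def filter_strata(
    strata: pd.DataFrame, sex: str | None = None, max_age: int | None = None
) -> pd.DataFrame:
    """Restrict a strata table by sex and/or maximum age.

    ``max_age=19`` keeps the children-and-adolescents bands (0-4 .. 15-19).
    Age-band lower bounds are parsed from the age_group labels.
    """
    out = _check_strata(strata)
    if sex is not None:
        if sex not in ("male", "female"):
            raise ValueError(f"unknown sex {sex!r}")
        out = out[out["sex"] == sex]
    if max_age is not None:
        lower = out["age_group"].str.replace("+", "", regex=False)
        lower = lower.str.split("-").str[0].astype(int)
        out = out[lower + 4 <= max_age]
    if out.empty:
        raise ValueError("no strata left after filtering")
    return out.copy()


def reference_rates_from_pooled(strata: pd.DataFrame) -> pd.DataFrame:
    """Internal reference rates: pooled cases over pooled population per stratum.

    rate(s, a) = sum_regions O(r, s, a) / sum_regions pop(r, s, a).
    Errors on any stratum whose pooled population is zero, naming it.
    """
    _check_strata(strata)
    pooled = strata.groupby(["sex", "age_group"], sort=True)[
        ["population", "observed"]
    ].sum()
    zero = pooled[pooled["population"] == 0]
    if not zero.empty:
        stratum = zero.index[0]
        raise ValueError(f"zero pooled population in stratum {stratum}")
    rates = (pooled["observed"] / pooled["population"]).rename("rate")
    return rates.reset_index()


def expected_counts(strata: pd.DataFrame, rates: pd.DataFrame) -> pd.Series:
    """Expected cases per region: E_i = sum_(s,a) pop(i,s,a) * rate(s,a)."""
    _check_strata(strata)
    if (rates["rate"] < 0).any() or not np.isfinite(rates["rate"]).all():
        raise ValueError("reference rates must be finite and >= 0")
    merged = strata.merge(rates, on=["sex", "age_group"], how="left")
    if merged["rate"].isna().any():
        bad = merged.loc[merged["rate"].isna(), ["sex", "age_group"]].drop_duplicates()
        raise ValueError(
            f"missing reference rate for strata: {list(map(tuple, bad.to_numpy()))}"
        )
    merged["expected"] = merged["population"] * merged["rate"]
    return merged.groupby("region_id", sort=False)["expected"].sum()


def observed_by_region(strata: pd.DataFrame) -> pd.Series:
    """Total observed cases per region."""
    _check_strata(strata)
    return strata.groupby("region_id", sort=False)["observed"].sum()


def sir(observed: pd.Series, expected: pd.Series) -> pd.DataFrame:
    """Standardized incidence ratio per region: SIR_i = O_i / E_i.

    Returns columns region_id, observed, expected, sir. Zero (or missing)
    expected counts are an error — a region with E = 0 has no defined SIR.
    """
    o = pd.Series(observed)
    e = pd.Series(expected).reindex(o.index)
    if e.isna().any():
        raise ValueError("expected counts missing for some regions")
    if (e <= 0).any():
        bad = list(e.index[e <= 0])
        raise ValueError(f"expected count is zero for regions {bad}")
    return pd.DataFrame(
        {
            "region_id": o.index,
            "observed": o.to_numpy(float),
            "expected": e.to_numpy(float),
            "sir": (o / e).to_numpy(float),
        }
    ).reset_index(drop=True)


def sir_from_strata(
    strata: pd.DataFrame,
    sex: str | None = None,
    max_age: int | None = None,
    rates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Filter, standardize and compute SIRs in one step.

    With ``rates=None`` the reference rates are derived internally from the
    filtered table itself (so sexes are never mixed when ``sex`` is given,
    and child analyses standardize within the restricted age range).
    """
    sub = filter_strata(strata, sex=sex, max_age=max_age)
    if rates is None:
        rates = reference_rates_from_pooled(sub)
    e = expected_counts(sub, rates)
    o = observed_by_region(sub)
    return sir(o, e)
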