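"""Assemble, impute and standardize the external-driver table.

External drivers of colony-level network structure: daily group size, group
composition (age of the birds), ecological conditions (daily mean
temperature, daily mean humidity, daily cloud coverage in okta), physical
environment (aviary aspect and floor area) and observation effort (daily
camera detections for the camera system matching the network type).

Numeric drivers are centred and scaled to unit standard deviation (n-1
denominator) within each analysis subset (network type x season), since the
seasons are analysed as independent replicates.  Factor drivers are encoded
as 0/1 indicators against reference levels aspect=northeast,
aviary area=12 m^2 and age=1 year.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUMERIC_DRIVERS = ["group_size", "temp_c", "humidity_pct", "cloud_okta",
                   "n_detections"]
FACTOR_INDICATORS = {
    "age_2": ("age_years", 2),
    "aspect_southwest": ("aspect", "southwest"),
    "aviary_large": ("aviary_area_m2", 24.0),
}
#: fixed effects of the informed models, in reporting order
FIXED_EFFECTS = [
    "group_size_z", "age_2", "temp_c_z", "humidity_pct_z", "cloud_okta_z",
    "aspect_southwest", "aviary_large", "n_detections_z",
]


def impute_humidity(rows: pd.DataFrame, max_missing_frac: float = 0.25,
                    ) -> pd.DataFrame:
    """Replace missing humidity values with the same-year mean.

    Only missing cells are touched.  A year with all humidity missing, or a
    missing fraction above ``max_missing_frac``, is an error.
    """
    df = rows.copy()
    missing = df["humidity_pct"].isna()
    if not missing.any():
        return df
    frac = missing.mean()
    if frac > max_missing_frac:
        raise ValueError(
            f"{frac:.0%} of humidity values missing exceeds the allowed "
            f"{max_missing_frac:.0%}")
    year_means = df.groupby("year")["humidity_pct"].transform("mean")
    dead_years = sorted(df.loc[missing & year_means.isna(), "year"].unique())
    if dead_years:
        raise ValueError(f"no humidity observations at all in year(s) {dead_years}")
    df.loc[missing, "humidity_pct"] = year_means[missing]
    logger.info("imputed %d missing humidity value(s) with year means",
                int(missing.sum()))
    return df


def scale_numeric(rows: pd.DataFrame, columns: list[str],
                  ) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Centre and scale columns to unit sd, adding ``<col>_z`` columns.

    Returns the augmented table and the {column: (mean, sd)} parameters so
    partial-residual plots can be back-transformed to the raw driver scale.
    The sd uses the n-1 denominator.  Constant columns are an error.
    """
    df = rows.copy()
    params: dict[str, tuple[float, float]] = {}
    for col in columns:
        vals = pd.to_numeric(df[col], errors="raise").astype(float)
        if vals.isna().any():
            raise ValueError(f"column {col!r} has missing values; impute first")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} is constant; cannot scale")
        df[col + "_z"] = (vals - mean) / sd
        params[col] = (mean, sd)
    return df, params


def encode_factors(rows: pd.DataFrame) -> pd.DataFrame:
    """Add the 0/1 indicator columns for the factor drivers."""
    df = rows.copy()
    for name, (col, level) in FACTOR_INDICATORS.items():
        df[name] = (df[col] == level).astype(int)
    return df


def join_model_table(metrics: pd.DataFrame, covs: pd.DataFrame) -> pd.DataFrame:
    """Inner-join metric rows to covariate rows on (colony_id, date).

    Every metric row must find exactly one covariate row; unmatched
    colony-days are an error (no silent drop).
    """
    dup = covs.duplicated(["colony_id", "date"])
    if dup.any():
        raise ValueError("covariate table has duplicate colony-day rows")
    merged = metrics.merge(covs, on=["colony_id", "date"], how="left",
                           indicator=True)
    unmatched = merged[merged["_merge"] == "left_only"]
    if len(unmatched):
        days = sorted(map(tuple, unmatched[["colony_id", "date"]].values))
        raise ValueError(f"metric rows without covariates: {days[:10]}"
                         + (" ..." if len(days) > 10 else ""))
    return merged.drop(columns="_merge")


def build_model_table(metrics: pd.DataFrame, covariates: pd.DataFrame,
                      net_type: str, season: str) -> pd.DataFrame:
    """Model-ready table for one analysis subset (network type x season).

    Selects the season's covariate rows, realizes the observation-effort
    driver for the network type (perch detections for interaction networks,
    feeder detections for association networks), imputes humidity, scales
    the numeric drivers within the subset, encodes factors and joins to the
    metric rows of that subset.
    """
    covs = covariates[covariates["season"] == season].copy()
    if covs.empty:
        raise ValueError(f"no covariate rows for season {season!r}")
    detcol = ("n_detections_perch" if net_type == "interaction"
              else "n_detections_feeder")
    covs["n_detections"] = pd.to_numeric(covs[detcol], errors="raise")
    covs = impute_humidity(covs)
    # a driver constant within the subset carries no information there
    # (e.g. group size in a study without removals); skip it with a warning
    scalable = [c for c in NUMERIC_DRIVERS
                if covs[c].astype(float).std(ddof=1) > 0]
    for c in set(NUMERIC_DRIVERS) - set(scalable):
        logger.warning("driver %r is constant in subset (%s, %s); dropped",
                       c, net_type, season)
    covs, params = scale_numeric(covs, scalable)
    covs = encode_factors(covs)
    sub = metrics[metrics["net_type"] == net_type].copy()
    sub = sub[sub["date"].isin(set(covs["date"]))]
    if sub.empty:
        raise ValueError(f"no {net_type} metric rows in season {season!r}")
    table = join_model_table(sub, covs)
    table.attrs["scaling"] = params
    table.attrs["subset"] = (net_type, season)
    return table
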