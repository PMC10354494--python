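"""Read, write and validate detection-record and covariate tables.

The interchange format for every stage is plain CSV with a fixed header so
that fixtures are deterministic and diff-able.  Dates are ISO-8601 strings
throughout; ``frame_id`` is an integer frame index within a colony-day-camera
(the camera cadence itself is metadata and plays no role in the analysis).

Detections CSV columns::

    colony_id,date,frame_id,camera_id,location_type,bird_id,x_px

``x_px`` is the pixel coordinate of the detected barcode along the perch; it
is required for perch records and empty for feeder records.

Covariates CSV columns::

    colony_id,date,season,year,group_size,age_years,temp_c,humidity_pct,
    cloud_okta,aspect,aviary_area_m2,n_detections_perch,n_detections_feeder

The covariate table carries separate perch and feeder detection totals; the
single observation-effort covariate entering a model is realized at
model-table assembly time, matching the camera system of the network type
under analysis.
"""

from __future__ import annotations

import pandas as pd

DETECTION_COLUMNS = [
    "colony_id", "date", "frame_id", "camera_id",
    "location_type", "bird_id", "x_px",
]
DETECTION_KEY = ["colony_id", "date", "frame_id", "camera_id", "bird_id"]

LOCATION_TYPES = ("social_perch", "copulation_perch", "feeder")
PERCH_LOCATIONS = ("social_perch", "copulation_perch")

COVARIATE_COLUMNS = [
    "colony_id", "date", "season", "year", "group_size", "age_years",
    "temp_c", "humidity_pct", "cloud_okta", "aspect", "aviary_area_m2",
    "n_detections_perch", "n_detections_feeder",
]
ASPECTS = ("northeast", "southwest")
SEASONS = ("pre", "post")


class SchemaError(ValueError):
    """A table does not conform to the expected schema."""


def _lines(index) -> str:
    # +2: one for the header line, one for 1-based numbering
    shown = [str(i + 2) for i in list(index)[:10]]
    suffix = ", ..." if len(index) > 10 else ""
    return ", ".join(shown) + suffix


def validate_detections(records: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    """Validate a detection table and normalize its dtypes.

    Raises :class:`SchemaError` naming offending line numbers (1-based, header
    included, matching the CSV file) for unknown location types, duplicate
    record keys, or perch records with a missing/negative pixel coordinate.
    """
    missing = [c for c in DETECTION_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"{source}: missing detection columns {missing}")
    df = records.loc[:, DETECTION_COLUMNS].reset_index(drop=True)
    for col in ("colony_id", "date", "camera_id", "location_type", "bird_id"):
        df[col] = df[col].astype(str)
    df["frame_id"] = pd.to_numeric(df["frame_id"], errors="raise").astype("int64")
    df["x_px"] = pd.array(pd.to_numeric(df["x_px"], errors="raise"), dtype="Int64")

    bad_loc = df.index[~df["location_type"].isin(LOCATION_TYPES)]
    if len(bad_loc):
        vals = sorted(df.loc[bad_loc, "location_type"].unique())
        raise SchemaError(
            f"{source}: unknown location_type {vals} on line(s) {_lines(bad_loc)}"
        )
    dup = df.index[df.duplicated(DETECTION_KEY, keep=False)]
    if len(dup):
        raise SchemaError(
            f"{source}: duplicate (colony_id,date,frame_id,camera_id,bird_id) "
            f"key on line(s) {_lines(dup)}"
        )
    is_perch = df["location_type"].isin(PERCH_LOCATIONS)
    no_x = df.index[is_perch & df["x_px"].isna()]
    if len(no_x):
        raise SchemaError(f"{source}: perch record without x_px on line(s) {_lines(no_x)}")
    neg_x = df.index[df["x_px"].notna() & (df["x_px"] < 0)]
    if len(neg_x):
        raise SchemaError(f"{source}: negative x_px on line(s) {_lines(neg_x)}")
    return df


def read_detections(path) -> pd.DataFrame:
    """Read and validate a detections CSV."""
    df = pd.read_csv(
        path,
        dtype={
            "colony_id": str, "date": str, "camera_id": str,
            "location_type": str, "bird_id": str, "x_px": "Int64",
        },
    )
    return validate_detections(df, source=str(path))


def write_detections(records: pd.DataFrame, path) -> None:
    validate_detections(records).to_csv(path, index=False)


def summarize_detections(records: pd.DataFrame) -> pd.DataFrame:
    """Per-colony-day detection totals (the observation-effort driver).

    Returns one row per colony-day present in ``records`` with the number of
    perch detections (social + copulation perches pooled), feeder detections
    and distinct birds seen.
    """
    df = records
    if df.empty:
        return pd.DataFrame(columns=[
            "colony_id", "date", "n_detections_perch",
            "n_detections_feeder", "n_birds_seen",
        ])
    is_perch = df["location_type"].isin(PERCH_LOCATIONS)
    out = (
        df.groupby(["colony_id", "date"], sort=True)["bird_id"]
        .nunique()
        .rename("n_birds_seen")
        .reset_index()
    )
    key = pd.MultiIndex.from_frame(out[["colony_id", "date"]])
    perch = df[is_perch].groupby(["colony_id", "date"]).size()
    feeder = df[~is_perch].groupby(["colony_id", "date"]).size()
    out.insert(2, "n_detections_perch", perch.reindex(key, fill_value=0).to_numpy())
    out.insert(3, "n_detections_feeder", feeder.reindex(key, fill_value=0).to_numpy())
    return out


def validate_covariates(rows: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    missing = [c for c in COVARIATE_COLUMNS if c not in rows.columns]
    if missing:
        raise SchemaError(f"{source}: missing covariate columns {missing}")
    df = rows.loc[:, COVARIATE_COLUMNS].reset_index(drop=True)
    df["colony_id"] = df["colony_id"].astype(str)
    df["date"] = df["date"].astype(str)
    bad_season = df.index[~df["season"].isin(SEASONS)]
    if len(bad_season):
        raise SchemaError(f"{source}: unknown season on line(s) {_lines(bad_season)}")
    bad_aspect = df.index[~df["aspect"].isin(ASPECTS)]
    if len(bad_aspect):
        raise SchemaError(f"{source}: unknown aspect on line(s) {_lines(bad_aspect)}")
    cloud = pd.to_numeric(df["cloud_okta"], errors="raise")
    bad_cloud = df.index[(cloud < 0) | (cloud > 8)]
    if len(bad_cloud):
        raise SchemaError(
            f"{source}: cloud_okta outside 0..8 on line(s) {_lines(bad_cloud)}"
        )
    dup = df.index[df.duplicated(["colony_id", "date"], keep=False)]
    if len(dup):
        raise SchemaError(
            f"{source}: duplicate (colony_id,date) covariate row on line(s) {_lines(dup)}"
        )
    return df


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"colony_id": str, "date": str})
    return validate_covariates(df, source=str(path))


def write_covariates(rows: pd.DataFrame, path) -> None:
    validate_covariates(rows).to_csv(path, index=False)
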