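"""Generate detection streams with the structure the analysis assumes.

The generator emulates a multi-year aviary study: sets of colonies observed
over a pre-breeding block and a post-breeding block of days each year, with
perch cameras recording affiliative clumping and feeder cameras recording
foraging co-occurrence, frame by frame.

Generative model
----------------
Latent sociality is additive on the log-odds scale.  For dyad (i, j) of
colony c on date d, the probability of clumping *given co-presence on a
perch camera* is::

    inv-logit(intercept + u_c + v_d + g_i + g_j + p_ij + sum_k beta_k x_k(c,d))

with colony effects u ~ N(0, sd_colony^2), date effects v ~ N(0, sd_date^2)
shared by the colonies observed that day, individual gregariousness
g ~ N(0, sd_individual^2) and pair bonds p ~ N(0, sd_dyad^2).  Covariate
values x_k are standardized within the study before entering the predictor.

Perch co-presence is generated as a dyadic encounter process: each perch
camera frame holds at most one encounter -- a uniformly sampled pair (with
probability ``p_pair``), a single bird (``p_single``) or nothing.  This keeps
the conditional clumping probability of every dyad exactly equal to the
linear-predictor value above, so the construction stage can be validated
against the generator analytically.  Clumped pairs are written with a pixel
distance drawn uniformly in [0, 79]; co-present non-clumped pairs in
[80, 2000], making the one-body-width rule exactly recoverable.

Feeder records come from a parallel bout process: each bird independently
joins a feeding bout in each frame with probability inv-logit of a similar
linear predictor (its own intercept, no dyad term), choosing uniformly among
the feeders.

Every emitted record is retained independently with a per-colony-day
detection rate drawn uniformly from ``detection_rate_range`` -- the
observation-effort driver.  A single integer seed drives all randomness
through deterministic sub-stream derivation, so identical configurations
produce bit-identical output.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from colonynet.detections_io import summarize_detections

NUMERIC_BETA_KEYS = ("temp_c", "humidity_pct", "cloud_okta", "group_size")
BINARY_BETA_KEYS = ("aspect_southwest", "aviary_large", "age_2")

PERCH_CAMERAS = (
    ("social_perch_1", "social_perch"),
    ("social_perch_2", "social_perch"),
    ("copulation_perch", "copulation_perch"),
)


def _default_beta() -> dict[str, float]:
    return {"temp_c": 0.2, "humidity_pct": -0.05, "cloud_okta": -0.1,
            "group_size": 0.1}


@dataclass
class SyntheticConfig:
    """Study design and generative parameters.

    The defaults mirror the reference study design: 4 colonies per year over
    3 years, 28 birds per colony, 10 pre-breeding days and 14/10/28
    post-breeding days per year.  ``frames_per_day`` (default 2000 per
    camera) is desk-scale while keeping per-dyad sampling above the
    ~20-observations-per-dyad guideline for robust networks.
    """

    n_years: int = 3
    colonies_per_year: int = 4
    birds_per_colony: int = 28
    days_pre: int = 10
    days_post_by_year: tuple[int, ...] = (14, 10, 28)
    frames_per_day: int = 2000
    sd_colony: float = 0.6
    sd_date: float = 0.3
    sd_individual: float = 0.25
    sd_dyad: float = 0.4
    beta: dict[str, float] = field(default_factory=_default_beta)
    detection_rate_range: tuple[float, float] = (0.6, 1.0)
    intercept: float = -1.0
    feeder_intercept: float = -2.0
    p_pair: float = 0.5
    p_single: float = 0.2
    n_feeders: int = 1
    removal_prob: float = 0.002
    humidity_missing_days: int = 1
    start_year: int = 2017
    seed: int = 0

    def __post_init__(self):
        self.days_post_by_year = tuple(self.days_post_by_year)
        if len(self.days_post_by_year) != self.n_years:
            raise ValueError("days_post_by_year must have length n_years")
        if self.birds_per_colony < 2:
            raise ValueError("birds_per_colony must be >= 2")
        for name in ("sd_colony", "sd_date", "sd_individual", "sd_dyad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.detection_rate_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("detection_rate_range must lie within (0, 1]")
        if not (0 <= self.p_pair and 0 <= self.p_single
                and self.p_pair + self.p_single <= 1):
            raise ValueError("p_pair + p_single must lie in [0, 1]")
        if not (0 <= self.removal_prob < 1):
            raise ValueError("removal_prob must lie in [0, 1)")
        for key, val in self.beta.items():
            if key not in NUMERIC_BETA_KEYS + BINARY_BETA_KEYS:
                raise ValueError(f"unknown beta covariate {key!r}")
            if not np.isfinite(val):
                raise ValueError(f"non-finite beta for {key!r}")

    @property
    def colonies(self) -> list[str]:
        return [f"{self.start_year + y}_C{k + 1}"
                for y in range(self.n_years)
                for k in range(self.colonies_per_year)]

    def year_of(self, colony_id: str) -> int:
        return int(colony_id.split("_")[0])

    def dates_of_year(self, year_index: int) -> list[tuple[str, str]]:
        """[(ISO date, season), ...] for one study year."""
        year = self.start_year + year_index
        out = []
        pre0 = datetime.date(year, 3, 1)
        for i in range(self.days_pre):
            out.append(((pre0 + datetime.timedelta(days=i)).isoformat(), "pre"))
        post0 = datetime.date(year, 7, 1)
        for i in range(self.days_post_by_year[year_index]):
            out.append(((post0 + datetime.timedelta(days=i)).isoformat(), "post"))
        return out


@dataclass
class GroundTruth:
    """Latent effects and covariates behind one simulated study."""

    colony_effects: dict[str, float]
    date_effects: dict[str, float]
    individual_effects: dict[str, float]
    dyad_effects: dict[tuple[str, str], float]
    covariate_effects: dict[tuple[str, str], float]  # sum_k beta_k x_k per colony-day
    covariates: pd.DataFrame
    config: SyntheticConfig

    def clump_probability(self, colony_id: str, date: str,
                          bird_a: str, bird_b: str) -> float:
        """Expected clumping probability of a dyad given perch co-presence."""
        cfg = self.config
        key = tuple(sorted((bird_a, bird_b)))
        eta = (cfg.intercept + self.colony_effects[colony_id]
               + self.date_effects[date]
               + self.covariate_effects[(colony_id, date)]
               + self.individual_effects[bird_a]
               + self.individual_effects[bird_b]
               + self.dyad_effects[key])
        return float(expit(eta))

    def feeder_join_probability(self, colony_id: str, date: str,
                                bird: str) -> float:
        cfg = self.config
        eta = (cfg.feeder_intercept + self.colony_effects[colony_id]
               + self.date_effects[date]
               + self.covariate_effects[(colony_id, date)]
               + self.individual_effects[bird])
        return float(expit(eta))

    def to_json(self, path) -> None:
        payload = {
            "colony_effects": self.colony_effects,
            "date_effects": self.date_effects,
            "individual_effects": self.individual_effects,
            "dyad_effects": {f"{a}|{b}": v
                             for (a, b), v in self.dyad_effects.items()},
            "covariate_effects": {f"{c}|{d}": v
                                  for (c, d), v in self.covariate_effects.items()},
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _bird_ids(colony_id: str, n: int) -> list[str]:
    return [f"{colony_id}_B{i:02d}" for i in range(n)]


def _simulate_covariates_roster(config: SyntheticConfig,
                                rng: np.random.Generator,
                                ) -> tuple[pd.DataFrame, dict]:
    """Covariate rows plus the per-colony-day roster of present birds."""
    rows = []
    roster: dict[tuple[str, str], list[int]] = {}
    for yi in range(config.n_years):
        year = config.start_year + yi
        dates = config.dates_of_year(yi)
        # weather is shared by the colonies observed in the same year/date
        weather = {}
        for d, season in dates:
            if season == "pre":  # early spring: cooler
                temp = rng.uniform(0.0, 16.0)
            else:  # mid-summer
                temp = rng.uniform(10.0, 25.6)
            humidity = rng.uniform(48.1, 92.7)
            cloud = int(rng.integers(0, 9))
            weather[d] = (temp, humidity, cloud)
        aviary_area = 12.0 if yi == 0 else 24.0
        age = 1 if yi % 2 == 0 else 2
        for k in range(config.colonies_per_year):
            colony = f"{year}_C{k + 1}"
            aspect = ("northeast", "southwest")[int(rng.integers(2))]
            present = list(range(config.birds_per_colony))
            for d, season in dates:
                if config.removal_prob > 0 and len(present) > 2:
                    keep = rng.random(len(present)) >= config.removal_prob
                    remaining = [b for b, k2 in zip(present, keep) if k2]
                    if len(remaining) >= 2:  # a colony never drops below a dyad
                        present = remaining
                roster[(colony, d)] = list(present)
                temp, humidity, cloud = weather[d]
                rows.append({
                    "colony_id": colony, "date": d, "season": season,
                    "year": year, "group_size": len(present),
                    "age_years": age, "temp_c": round(temp, 1),
                    "humidity_pct": round(humidity, 1), "cloud_okta": cloud,
                    "aspect": aspect, "aviary_area_m2": aviary_area,
                    "n_detections_perch": pd.NA, "n_detections_feeder": pd.NA,
                })
    cov = pd.DataFrame(rows)
    if config.humidity_missing_days > 0:
        all_dates = cov["date"].unique()
        n_miss = min(config.humidity_missing_days, len(all_dates))
        miss = rng.choice(all_dates, size=n_miss, replace=False)
        cov.loc[cov["date"].isin(miss), "humidity_pct"] = np.nan
    return cov, roster


def simulate_covariates(config: SyntheticConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """One covariate row per colony-day (detection counts not yet known)."""
    cov, _ = _simulate_covariates_roster(config, rng)
    return cov


def _covariate_effects(config: SyntheticConfig, cov: pd.DataFrame,
                       ) -> dict[tuple[str, str], float]:
    """sum_k beta_k x_k(c, d) with x standardized within the study.

    Missing humidity enters through its year mean, mirroring the imputation
    applied at analysis time.
    """
    eff = np.zeros(len(cov))
    for key, b in config.beta.items():
        if key in NUMERIC_BETA_KEYS:
            vals = cov[key].astype(float)
            if key == "humidity_pct":
                vals = vals.fillna(cov.groupby("year")[key].transform("mean"))
                vals = vals.fillna(vals.mean())  # a year with no observation
            sd = vals.std(ddof=1)
            z = (vals - vals.mean()) / sd if sd > 0 else vals * 0.0
            eff = eff + b * np.nan_to_num(z.to_numpy())
        else:
            level = {"aspect_southwest": ("aspect", "southwest"),
                     "aviary_large": ("aviary_area_m2", 24.0),
                     "age_2": ("age_years", 2)}[key]
            eff = eff + b * (cov[level[0]] == level[1]).to_numpy(dtype=float)
    return {(c, d): float(e)
            for c, d, e in zip(cov["colony_id"], cov["date"], eff)}


def simulate_study(config: SyntheticConfig,
                   ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the full detection stream of a study.

    Returns the validated detection table (post-dropout) and the ground
    truth (latent effects, covariates with realized detection counts).
    """
    root = np.random.SeedSequence(config.seed)
    ss_cov, ss_eff, ss_days = root.spawn(3)
    cov, roster = _simulate_covariates_roster(config,
                                              np.random.default_rng(ss_cov))
    rng_eff = np.random.default_rng(ss_eff)

    colonies = config.colonies
    u = {c: rng_eff.normal(0.0, config.sd_colony) for c in colonies}
    all_dates = list(dict.fromkeys(cov["date"]))
    v = {d: rng_eff.normal(0.0, config.sd_date) for d in all_dates}
    g: dict[str, float] = {}
    p: dict[tuple[str, str], float] = {}
    birds_of = {}
    for c in colonies:
        birds = _bird_ids(c, config.birds_per_colony)
        birds_of[c] = birds
        for b in birds:
            g[b] = rng_eff.normal(0.0, config.sd_individual)
        for i in range(len(birds)):
            for j in range(i + 1, len(birds)):
                p[(birds[i], birds[j])] = rng_eff.normal(0.0, config.sd_dyad)

    coveff = _covariate_effects(config, cov)

    colony_days = list(zip(cov["colony_id"], cov["date"]))
    day_streams = ss_days.spawn(len(colony_days))

    F = config.frames_per_day
    chunks: list[pd.DataFrame] = []
    for (colony, date), stream in zip(colony_days, day_streams):
        rng = np.random.default_rng(stream)
        birds = birds_of[colony]
        present = np.asarray(roster[(colony, date)], dtype=int)
        m = len(present)
        g_arr = np.asarray([g[b] for b in birds])
        nb = len(birds)
        p_mat = np.zeros((nb, nb))
        for i in range(nb):
            for j in range(i + 1, nb):
                p_mat[i, j] = p_mat[j, i] = p[(birds[i], birds[j])]
        eta0 = config.intercept + u[colony] + v[date] + coveff[(colony, date)]

        cam_col, loc_col, frame_col, bird_col, x_col = [], [], [], [], []
        for cam, loc in PERCH_CAMERAS:
            r = rng.random(F)
            pair_frames = np.flatnonzero(r < config.p_pair)
            single_frames = np.flatnonzero(
                (r >= config.p_pair) & (r < config.p_pair + config.p_single))
            k = len(pair_frames)
            if k and m >= 2:
                ia = rng.integers(0, m, k)
                ib = (ia + rng.integers(1, m, k)) % m
                a = present[np.minimum(ia, ib)]
                b = present[np.maximum(ia, ib)]
                eta = eta0 + g_arr[a] + g_arr[b] + p_mat[a, b]
                clumped = rng.random(k) < expit(eta)
                xa = rng.integers(0, 8000, k)
                delta = np.where(clumped,
                                 rng.integers(0, 80, k),
                                 rng.integers(80, 2001, k))
                xb = xa + delta
                frame_col.append(np.repeat(pair_frames, 2))
                bird_col.append(np.column_stack([a, b]).ravel())
                x_col.append(np.column_stack([xa, xb]).ravel())
                cam_col.append(np.full(2 * k, cam, dtype=object))
                loc_col.append(np.full(2 * k, loc, dtype=object))
            ks = len(single_frames)
            if ks and m >= 1:
                sb = present[rng.integers(0, m, ks)]
                frame_col.append(single_frames)
                bird_col.append(sb)
                x_col.append(rng.integers(0, 8000, ks))
                cam_col.append(np.full(ks, cam, dtype=object))
                loc_col.append(np.full(ks, loc, dtype=object))

        # feeder bout process
        pj = expit(config.feeder_intercept + u[colony] + v[date]
                   + coveff[(colony, date)] + g_arr[present])
        join = rng.random((F, m)) < pj[None, :]
        fr, bi = np.nonzero(join)
        if len(fr):
            feeders = rng.integers(0, config.n_feeders, len(fr))
            frame_col.append(fr)
            bird_col.append(present[bi])
            x_col.append(np.full(len(fr), -1))
            cam_col.append(np.array([f"feeder_{f + 1}" for f in feeders],
                                    dtype=object))
            loc_col.append(np.full(len(fr), "feeder", dtype=object))

        if not frame_col:
            continue
        frames = np.concatenate(frame_col)
        bird_idx = np.concatenate(bird_col)
        xs = np.concatenate(x_col)
        cams = np.concatenate(cam_col)
        locs = np.concatenate(loc_col)

        lam = rng.uniform(*config.detection_rate_range)
        keep = rng.random(len(frames)) < lam

        bird_names = np.asarray(birds, dtype=object)[bird_idx[keep]]
        x_kept = xs[keep].astype(float)
        x_kept[x_kept < 0] = np.nan
        chunks.append(pd.DataFrame({
            "colony_id": colony, "date": date,
            "frame_id": frames[keep].astype(np.int64),
            "camera_id": cams[keep], "location_type": locs[keep],
            "bird_id": bird_names,
            "x_px": pd.array(x_kept, dtype="Int64"),
        }))

    detections = (pd.concat(chunks, ignore_index=True) if chunks
                  else pd.DataFrame(columns=["colony_id", "date", "frame_id",
                                             "camera_id", "location_type",
                                             "bird_id", "x_px"]))
    # realized observation effort per colony-day
    summary = summarize_detections(detections)
    cov = cov.drop(columns=["n_detections_perch", "n_detections_feeder"]).merge(
        summary[["colony_id", "date", "n_detections_perch",
                 "n_detections_feeder"]],
        on=["colony_id", "date"], how="left")
    cov[["n_detections_perch", "n_detections_feeder"]] = (
        cov[["n_detections_perch", "n_detections_feeder"]].fillna(0).astype(int))

    truth = GroundTruth(colony_effects=u, date_effects=v,
                        individual_effects=g, dyad_effects=p,
                        covariate_effects=coveff, covariates=cov,
                        config=config)
    return detections, truth


def simulate_metric_responses(n_colonies: int = 12, n_days: int = 30,
                              var_colony: float = 1.0, var_date: float = 0.0,
                              var_resid: float = 1.0, mean: float = 0.0,
                              rng: np.random.Generator | None = None,
                              seed: int | None = None) -> pd.DataFrame:
    """Balanced colony x day table of Gaussian responses with known components.

    Direct simulation at the metric level (one value per colony-day) for
    parameter-recovery and coverage experiments; dates are shared across
    colonies so date effects are crossed with colony effects.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    colonies = [f"C{i + 1:02d}" for i in range(n_colonies)]
    dates = [f"D{j + 1:03d}" for j in range(n_days)]
    uc = np.sqrt(var_colony) * rng.standard_normal(n_colonies)
    vd = np.sqrt(var_date) * rng.standard_normal(n_days)
    ci = np.repeat(np.arange(n_colonies), n_days)
    di = np.tile(np.arange(n_days), n_colonies)
    y = (mean + uc[ci] + vd[di]
         + np.sqrt(var_resid) * rng.standard_normal(n_colonies * n_days))
    return pd.DataFrame({
        "colony_id": np.asarray(colonies, dtype=object)[ci],
        "date": np.asarray(dates, dtype=object)[di],
        "y": y,
    })
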