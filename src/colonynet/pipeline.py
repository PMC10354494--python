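"""Orchestrate simulate -> networks -> metrics -> models as a reproducible run.

A run is driven by a single YAML config and an output directory.  Every stage
writes plain CSV/JSON and can also consume the previous stage's files, so a
real detection dataset can be slotted in at the ``networks`` stage without
code changes.  A machine-readable manifest records the seed, package version,
every design toggle in effect and the SHA-256 digest of each output, and
reruns with the same config and seed are byte-identical.

Config keys::

    seed: int                      # master seed (overridable on the CLI)
    synthetic: {...}               # SyntheticConfig fields; omit to skip simulate
    mask: [{colony_id, date, net_type}, ...]   # explicit dropped networks
    mask_random: {n, net_type, season}         # randomly dropped networks
    analysis:
      threshold_px: 80             # clumping distance (pixels)
      n_correction_reps: 100       # disconnected-metric repetitions
      weight_mode: cost            # or "inverse" (1/weight path costs)
      cv_mode: per_individual      # or "global"
      join: chain                  # or "star" correction topology
      fixed_effects: [...]         # defaults to the full driver set
      repeatability_include_fixed: false
      bootstrap_reps: 1000
      bootstrap_method: parametric # or "rows"
      bootstrap_models: [uninformed]
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from colonynet import covariates as cov_mod
from colonynet import detections_io as dio
from colonynet import network_construction as nc
from colonynet import network_metrics as nm
from colonynet import variance_models as vm
from colonynet.synthetic_data import SyntheticConfig, simulate_study

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "networks", "metrics", "fit", "bootstrap")
DEFAULT_STAGES = ("simulate", "networks", "metrics", "fit")

DEFAULT_ANALYSIS = {
    "threshold_px": 80,
    "n_correction_reps": 100,
    "weight_mode": "cost",
    "cv_mode": "per_individual",
    "join": "chain",
    "fixed_effects": list(cov_mod.FIXED_EFFECTS),
    "repeatability_include_fixed": False,
    "bootstrap_reps": 1000,
    "bootstrap_method": "parametric",
    "bootstrap_models": ["uninformed"],
    "net_types": list(nc.NET_TYPES),
    "seasons": list(dio.SEASONS),
}


@dataclass
class StudyAccounting:
    """How many daily networks the study yielded, by season, and what is missing."""

    n_networks_total: int
    n_networks_pre: int
    n_networks_post: int
    n_missing: int
    missing: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineConfig:
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    mask: list[dict] = field(default_factory=list)
    mask_random: dict | None = None
    analysis: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = dict(DEFAULT_ANALYSIS)
        unknown = set(self.analysis) - set(DEFAULT_ANALYSIS)
        if unknown:
            raise ValueError(f"unknown analysis config key(s) {sorted(unknown)}")
        merged.update(self.analysis)
        self.analysis = merged
        for m in self.mask:
            if set(m) != {"colony_id", "date", "net_type"}:
                raise ValueError(f"mask entries need colony_id/date/net_type: {m}")
        if self.mask_random is not None:
            if set(self.mask_random) - {"n", "net_type", "season"}:
                raise ValueError(f"unknown mask_random key in {self.mask_random}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {"seed", "synthetic", "mask", "mask_random", "analysis"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)}")
        syn = raw.get("synthetic")
        if syn is not None:
            valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
            bad = set(syn) - valid
            if bad:
                raise ValueError(f"unknown synthetic config key(s) {sorted(bad)}")
            syn = SyntheticConfig(**syn)
        return cls(seed=int(raw.get("seed", 0)), synthetic=syn,
                   mask=list(raw.get("mask", [])),
                   mask_random=raw.get("mask_random"),
                   analysis=dict(raw.get("analysis", {})))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def account_networks(networks: list[nc.DailyNetwork],
                     expected_design: pd.DataFrame) -> StudyAccounting:
    """Compare the built networks against the expected study design.

    ``expected_design`` has one row per expected network with columns
    colony_id, date, net_type, season.
    """
    expected = expected_design[["colony_id", "date", "net_type", "season"]].copy()
    present = {(n.colony_id, n.date, n.net_type) for n in networks}
    keys = list(zip(expected["colony_id"], expected["date"],
                    expected["net_type"]))
    expected["present"] = [k in present for k in keys]
    got = expected[expected["present"]]
    missing = expected[~expected["present"]]
    return StudyAccounting(
        n_networks_total=int(len(got)),
        n_networks_pre=int((got["season"] == "pre").sum()),
        n_networks_post=int((got["season"] == "post").sum()),
        n_missing=int(len(missing)),
        missing=missing[["colony_id", "date", "net_type"]].to_dict("records"),
    )


def _apply_mask(networks: list[nc.DailyNetwork], config: PipelineConfig,
                covariates: pd.DataFrame) -> list[nc.DailyNetwork]:
    drop = {(m["colony_id"], m["date"], m["net_type"]) for m in config.mask}
    if config.mask_random:
        spec = dict(config.mask_random)
        n = int(spec.get("n", 0))
        net_type = spec.get("net_type", "association")
        season = spec.get("season")
        pool = [net for net in networks if net.net_type == net_type]
        if season is not None:
            season_dates = set(
                covariates.loc[covariates["season"] == season, "date"])
            pool = [net for net in pool if net.date in season_dates]
        rng = np.random.default_rng(np.random.SeedSequence(
            [config.seed, 0x6D61736B]))  # dedicated masking stream
        idx = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
        drop |= {(pool[i].colony_id, pool[i].date, pool[i].net_type)
                 for i in idx}
    if drop:
        logger.info("masking %d network(s) from the study", len(drop))
    return [net for net in networks
            if (net.colony_id, net.date, net.net_type) not in drop]


def _expected_design(covariates: pd.DataFrame, net_types) -> pd.DataFrame:
    base = covariates[["colony_id", "date", "season"]]
    frames = [base.assign(net_type=t) for t in net_types]
    return pd.concat(frames, ignore_index=True)


def _season_of_dates(covariates: pd.DataFrame) -> dict[str, str]:
    return dict(zip(covariates["date"], covariates["season"]))


def _fit_tables(metrics: pd.DataFrame, covariates: pd.DataFrame,
                analysis: dict) -> dict[tuple[str, str], pd.DataFrame]:
    tables = {}
    for net_type in analysis["net_types"]:
        for season in analysis["seasons"]:
            try:
                tables[(net_type, season)] = cov_mod.build_model_table(
                    metrics, covariates, net_type, season)
            except ValueError as exc:
                logger.warning("no model table for %s/%s: %s",
                               net_type, season, exc)
    return tables


def _estimable_effects(table: pd.DataFrame, requested) -> tuple[str, ...]:
    """Drop requested fixed effects that are absent or constant in a subset."""
    kept = tuple(f for f in requested
                 if f in table.columns and table[f].nunique() > 1)
    dropped = set(requested) - set(kept)
    if dropped:
        logger.warning("fixed effect(s) %s not estimable in this subset",
                       sorted(dropped))
    return kept


def _fit_stage(tables, analysis) -> dict[str, pd.DataFrame]:
    include_fixed = analysis["repeatability_include_fixed"]
    rep_rows, r2_rows, coef_rows, vif_rows = [], [], [], []
    for (net_type, season), table in sorted(tables.items()):
        fixed = _estimable_effects(table, analysis["fixed_effects"])
        for metric in nm.METRIC_NAMES:
            sub = table.dropna(subset=[metric])
            if sub[metric].nunique() < 3:
                logger.warning("skipping %s %s %s: degenerate response",
                               net_type, season, metric)
                continue
            uni = vm.fit_lmm(sub, vm.uninformed_spec(metric))
            rep_rows.append({
                "net_type": net_type, "season": season, "metric": metric,
                "model": "uninformed",
                "R": vm.repeatability(uni, include_fixed=include_fixed),
                "var_colony": uni.var_colony, "var_date": uni.var_date,
                "var_resid": uni.var_resid, "n_obs": uni.n_obs,
                "converged": uni.converged,
            })
            inf = vm.fit_lmm(sub, vm.informed_spec(metric, fixed))
            rm2, rc2 = vm.r2_marginal_conditional(inf)
            rep_rows.append({
                "net_type": net_type, "season": season, "metric": metric,
                "model": "informed",
                "R": vm.repeatability(inf, include_fixed=include_fixed),
                "var_colony": inf.var_colony, "var_date": inf.var_date,
                "var_resid": inf.var_resid, "n_obs": inf.n_obs,
                "converged": inf.converged,
            })
            r2_rows.append({
                "net_type": net_type, "season": season, "metric": metric,
                "RM2": rm2, "RC2": rc2, "n_obs": inf.n_obs,
            })
            for name, (est, se, lo, hi) in inf.beta.items():
                coef_rows.append({
                    "net_type": net_type, "season": season, "metric": metric,
                    "term": name, "estimate": est, "se": se,
                    "ci_low": lo, "ci_high": hi,
                })
        if len(fixed) >= 2:
            spec = vm.informed_spec(nm.METRIC_NAMES[0], fixed)
            for name, vif in vm.compute_vif(table, spec).items():
                vif_rows.append({"net_type": net_type, "season": season,
                                 "term": name, "vif": vif})
    return {
        "repeatability": pd.DataFrame(rep_rows),
        "r2": pd.DataFrame(r2_rows),
        "coefficients": pd.DataFrame(coef_rows),
        "vif": pd.DataFrame(vif_rows),
    }


def _bootstrap_stage(tables, analysis, seed) -> pd.DataFrame:
    include_fixed = analysis["repeatability_include_fixed"]
    B = int(analysis["bootstrap_reps"])
    method = analysis["bootstrap_method"]
    rows = []
    ss = np.random.SeedSequence([seed, 0x626F6F74])
    for (net_type, season), table in sorted(tables.items()):
        fixed = _estimable_effects(table, analysis["fixed_effects"])
        for metric in nm.METRIC_NAMES:
            sub = table.dropna(subset=[metric])
            if sub[metric].nunique() < 3:
                continue
            for model in analysis["bootstrap_models"]:
                spec = (vm.uninformed_spec(metric) if model == "uninformed"
                        else vm.informed_spec(metric, fixed))
                child = ss.spawn(1)[0]
                est = vm.bootstrap_repeatability(
                    sub, spec, B=B, rng=np.random.default_rng(child),
                    method=method, include_fixed=include_fixed)
                rows.append({
                    "net_type": net_type, "season": season, "metric": metric,
                    "model": model, "R": est.R, "ci_low": est.ci_low,
                    "ci_high": est.ci_high, "n_bootstrap": est.n_bootstrap,
                    "n_failed": est.n_failed, "method": est.method,
                })
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | str | Path, outdir,
                 stages=DEFAULT_STAGES, seed: int | None = None) -> Path:
    """Run the requested stages, writing all outputs under ``outdir``.

    Later stages read earlier stages' CSVs from ``outdir`` when those stages
    are not part of this invocation, so the pipeline can resume or ingest
    externally produced files.  Returns the output directory.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
        if config.synthetic is not None:
            config.synthetic = dataclasses.replace(config.synthetic,
                                                   seed=int(seed))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = config.analysis

    detections = covariates = networks = metrics = None

    if "simulate" in stages:
        if config.synthetic is None:
            raise ValueError("simulate stage requires a 'synthetic' config block")
        logger.info("simulate: %d colonies", len(config.synthetic.colonies))
        detections, truth = simulate_study(config.synthetic)
        dio.write_detections(detections, outdir / "detections.csv")
        covariates = truth.covariates
        dio.write_covariates(covariates, outdir / "covariates.csv")
        truth.to_json(outdir / "ground_truth.json")

    if "networks" in stages:
        if detections is None:
            detections = dio.read_detections(outdir / "detections.csv")
        if covariates is None:
            covariates = dio.read_covariates(outdir / "covariates.csv")
        logger.info("networks: building daily networks")
        networks = nc.build_networks(detections,
                                     net_types=tuple(analysis["net_types"]),
                                     threshold_px=analysis["threshold_px"])
        networks = _apply_mask(networks, config, covariates)
        nc.write_networks(networks, outdir / "edges.csv", outdir / "nodes.csv")
        accounting = account_networks(
            networks, _expected_design(covariates, analysis["net_types"]))
        (outdir / "accounting.json").write_text(
            json.dumps(accounting.to_dict(), indent=1) + "\n")

    if "metrics" in stages:
        if networks is None:
            networks = nc.read_networks(outdir / "edges.csv",
                                        outdir / "nodes.csv")
        logger.info("metrics: %d networks", len(networks))
        metrics = nm.metrics_table(
            networks, n_reps=analysis["n_correction_reps"],
            seed=config.seed, weight_mode=analysis["weight_mode"],
            cv_mode=analysis["cv_mode"], join=analysis["join"])
        metrics.to_csv(outdir / "metrics.csv", index=False)

    if "fit" in stages or "bootstrap" in stages:
        if metrics is None:
            metrics = pd.read_csv(outdir / "metrics.csv",
                                  dtype={"colony_id": str, "date": str})
        if covariates is None:
            covariates = dio.read_covariates(outdir / "covariates.csv")
        tables = _fit_tables(metrics, covariates, analysis)
        if "fit" in stages:
            logger.info("fit: %d analysis subsets", len(tables))
            for name, frame in _fit_stage(tables, analysis).items():
                frame.to_csv(outdir / f"{name}.csv", index=False)
        if "bootstrap" in stages:
            logger.info("bootstrap: B=%d", analysis["bootstrap_reps"])
            _bootstrap_stage(tables, analysis, config.seed).to_csv(
                outdir / "bootstrap.csv", index=False)

    from colonynet import __version__  # deferred: avoids a circular import

    manifest = {
        "package": "colonynet",
        "version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "analysis": {k: analysis[k] for k in sorted(analysis)},
        "synthetic": (None if config.synthetic is None else {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config.synthetic).items()}),
        "mask": config.mask,
        "mask_random": config.mask_random,
        "outputs": {p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))
                    + sorted(outdir.glob("*.json")) if p.name != "manifest.json"},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return outdir
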