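"""Linear mixed models for partitioning colony-day metric variance.

Two model families are fitted per metric, network type and season:

* **uninformed** -- the metric with only a colony-identity random intercept;
  its intraclass correlation is the baseline colony repeatability
  ``R = var_colony / (var_colony + var_resid)``.
* **informed** -- the metric with the external drivers as fixed effects and
  crossed random intercepts for colony identity and date; its repeatability
  ``R = var_colony / (var_colony + var_date + var_resid)`` measures
  consistent colony differences after controlling for the drivers (adjusted
  ICC: the fixed-effect variance is excluded from the denominator by
  default; ``include_fixed=True`` switches to the unadjusted form).

Variance components are estimated by restricted maximum likelihood (REML), a
deterministic frequentist substitute for a posterior-based fit; the
repeatability and R-squared formulas are estimator-agnostic.  Marginal and
conditional R-squared follow the variance-partitioning convention for mixed
models: ``RM2 = var_fixed / var_total`` and
``RC2 = (var_fixed + var_colony + var_date) / var_total`` where ``var_fixed``
is the sample variance of the fixed-effect linear predictor over the data.

Crossed-random-effect models are fitted with statsmodels ``MixedLM``
variance components.  Models with a single colony random intercept use an
exact profiled-REML solver (one-dimensional optimization of the restricted
likelihood in the variance ratio): it hits the same optimum as ``MixedLM``
-- equivalence is enforced by tests -- but is orders of magnitude faster and
well behaved at the var_colony = 0 boundary, which matters for the
1000-replicate bootstrap.

Bootstrap confidence intervals are parametric by default: each replicate
simulates new colony (and date) effects and residuals from the fitted
components, refits, and re-derives R; the 2.5/97.5 percentiles of the
replicates form the interval.  A nonparametric alternative resampling
colony-day rows within colonies is available via ``method="rows"``, but it
holds the realized colony effects fixed and therefore understates
between-colony sampling noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from statsmodels.regression.mixed_linear_model import MixedLM

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054  # 97.5% normal quantile


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, fixed-effect columns, random grouping factors."""

    response: str
    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ("colony_id",)
    subset: tuple[str, str] | None = None

    def __post_init__(self):
        if tuple(self.random) not in (("colony_id",), ("colony_id", "date")):
            raise ValueError(
                "random must be ('colony_id',) or ('colony_id', 'date')")


def uninformed_spec(response: str, subset=None) -> ModelSpec:
    """Colony random intercept only, no fixed effects."""
    return ModelSpec(response=response, fixed=(), random=("colony_id",),
                     subset=subset)


def informed_spec(response: str, fixed: tuple[str, ...], subset=None) -> ModelSpec:
    """External drivers as fixed effects, colony and date random intercepts."""
    return ModelSpec(response=response, fixed=tuple(fixed),
                     random=("colony_id", "date"), subset=subset)


@dataclass
class VarianceDecomposition:
    """Coefficients and variance components of one fitted mixed model."""

    spec: ModelSpec
    beta: dict[str, tuple[float, float, float, float]]  # est, se, lo, hi
    var_colony: float
    var_date: float
    var_resid: float
    var_fixed: float
    n_obs: int
    converged: bool
    method: str
    fitted_fixed: np.ndarray = field(repr=False, default=None)
    ranef_rows: np.ndarray = field(repr=False, default=None)
    row_index: np.ndarray = field(repr=False, default=None)


@dataclass
class RepeatabilityEstimate:
    """Point estimate and 95% percentile bootstrap interval for R."""

    R: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    n_failed: int = 0
    method: str = "parametric"
    samples: np.ndarray = field(repr=False, default=None)


def _design(table: pd.DataFrame, spec: ModelSpec,
            ) -> tuple[np.ndarray, np.ndarray, list[str], pd.DataFrame]:
    cols = [spec.response, *spec.fixed, *spec.random]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"model table lacks columns {missing}")
    d = table.dropna(subset=[spec.response, *spec.fixed]).copy()
    if d.empty:
        raise ValueError(f"no complete rows for response {spec.response!r}")
    y = d[spec.response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(d))]
                        + [d[c].to_numpy(dtype=float) for c in spec.fixed])
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in model matrix")
    names = ["intercept", *spec.fixed]
    for g in spec.random:
        if d[g].nunique() < 2:
            raise ValueError(f"grouping factor {g!r} has fewer than 2 levels")
    return y, X, names, d


def _oneway_profiled_reml(y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                          n_groups: int) -> dict:
    """Exact REML for a Gaussian model with one random intercept factor.

    Profiles beta and the residual variance out of the restricted likelihood
    and optimizes the single variance ratio lambda = var_group/var_resid on
    the log scale (Woodbury identities keep each evaluation O(n)).
    """
    n, p = X.shape
    ng = np.bincount(codes, minlength=n_groups).astype(float)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    SX = np.zeros((n_groups, p))
    np.add.at(SX, codes, X)
    Sy = np.bincount(codes, weights=y, minlength=n_groups)

    def solve_at(lam: float):
        w = lam / (1.0 + lam * ng)
        XtViX = XtX - (SX * w[:, None]).T @ SX
        XtViy = Xty - SX.T @ (w * Sy)
        yViy = yty - float(w @ (Sy * Sy))
        beta = np.linalg.solve(XtViX, XtViy)
        quad = max(yViy - float(beta @ XtViy), 1e-300)
        sig2 = quad / (n - p)
        return beta, sig2, XtViX

    def neg_restricted_ll(loglam: float) -> float:
        lam = np.exp(loglam)
        _, sig2, XtViX = solve_at(lam)
        logdetV = float(np.log1p(lam * ng).sum())
        sign, logdetXX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        return 0.5 * ((n - p) * np.log(sig2) + logdetV + logdetXX)

    res = minimize_scalar(neg_restricted_ll, bounds=(-30.0, 15.0),
                          method="bounded",
                          options={"xatol": 1e-8, "maxiter": 200})
    # the lower bound is effectively lambda = 0; snap tiny ratios to zero
    lam = float(np.exp(res.x))
    beta, sig2, XtViX = solve_at(lam)
    var_group = lam * sig2
    if var_group < 1e-10 * sig2:
        var_group = 0.0
    cov_beta = np.linalg.inv(XtViX) * sig2
    resid = y - X @ beta
    Sr = np.bincount(codes, weights=resid, minlength=n_groups)
    blup = lam * Sr / (1.0 + lam * ng)
    return {
        "beta": beta, "cov_beta": cov_beta, "var_group": var_group,
        "var_resid": sig2, "ranef_rows": blup[codes],
        "converged": bool(res.success),
    }


def _beta_table(names, est, se) -> dict:
    return {
        name: (float(b), float(s), float(b - Z975 * s), float(b + Z975 * s))
        for name, b, s in zip(names, est, se)
    }


def _fit_oneway(y, X, names, d, spec) -> VarianceDecomposition:
    codes, levels = pd.factorize(d[spec.random[0]], sort=True)
    out = _oneway_profiled_reml(y, X, codes, len(levels))
    fitted = X @ out["beta"]
    return VarianceDecomposition(
        spec=spec,
        beta=_beta_table(names, out["beta"], np.sqrt(np.diag(out["cov_beta"]))),
        var_colony=float(out["var_group"]),
        var_date=0.0,
        var_resid=float(out["var_resid"]),
        var_fixed=float(np.var(fitted, ddof=1)) if len(spec.fixed) else 0.0,
        n_obs=len(y),
        converged=out["converged"],
        method="profiled_reml",
        fitted_fixed=fitted,
        ranef_rows=out["ranef_rows"],
        row_index=d.index.to_numpy(),
    )


def _fit_statsmodels(y, X, names, d, spec) -> VarianceDecomposition:
    from statsmodels.regression.mixed_linear_model import VCSpec

    n = len(y)
    mats, vc_names, colnames = [], [], []
    for g in spec.random:
        codes, levels = pd.factorize(d[g], sort=True)
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), codes] = 1.0
        mats.append([Z])
        vc_names.append(g)
        colnames.append([[f"{g}[{lv}]" for lv in levels]])
    vcs = VCSpec(vc_names, colnames, mats)
    model = MixedLM(y, X, groups=np.zeros(n), exog_re=None, exog_vc=vcs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
        vcomp = {name: max(float(v), 0.0)
                 for name, v in zip(vc_names, result.vcomp)}
        fe = np.asarray(result.fe_params, dtype=float)
        bse = np.asarray(result.bse_fe, dtype=float)
        fitted = X @ fe
        ranef = np.asarray(result.fittedvalues, dtype=float) - fitted
    return VarianceDecomposition(
        spec=spec,
        beta=_beta_table(names, fe, bse),
        var_colony=vcomp.get("colony_id", 0.0),
        var_date=vcomp.get("date", 0.0),
        var_resid=float(result.scale),
        var_fixed=float(np.var(fitted, ddof=1)) if len(spec.fixed) else 0.0,
        n_obs=n,
        converged=bool(result.converged),
        method="mixedlm_vc",
        fitted_fixed=fitted,
        ranef_rows=ranef,
        row_index=d.index.to_numpy(),
    )


def fit_lmm(table: pd.DataFrame, spec: ModelSpec, engine: str = "auto",
            ) -> VarianceDecomposition:
    """Fit a Gaussian random-intercept model by REML.

    ``engine="auto"`` uses the exact profiled-REML solver for a single colony
    random effect and statsmodels ``MixedLM`` variance components for the
    crossed colony+date structure.  ``engine="statsmodels"`` forces the
    latter everywhere (used by the equivalence tests).  Non-convergence is
    flagged on the result, never silent.
    """
    y, X, names, d = _design(table, spec)
    if engine not in ("auto", "profile", "statsmodels"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "profile" and len(spec.random) != 1:
        raise ValueError("profile engine only supports a single random factor")
    use_profile = (engine == "profile"
                   or (engine == "auto" and len(spec.random) == 1))
    vd = (_fit_oneway if use_profile else _fit_statsmodels)(y, X, names, d, spec)
    if not vd.converged:
        logger.warning("REML fit for %s did not converge (method=%s)",
                       spec.response, vd.method)
    return vd


def repeatability(vd: VarianceDecomposition, include_fixed: bool = False,
                  ) -> float:
    """Colony repeatability (intraclass correlation) from the fit.

    ``R = var_colony / (var_colony + var_date + var_resid)``; with
    ``include_fixed=True`` the fixed-effect variance joins the denominator.
    """
    denom = vd.var_colony + vd.var_date + vd.var_resid
    if include_fixed:
        denom += vd.var_fixed
    if denom == 0:
        raise ValueError("all variance components are zero; R undefined")
    return vd.var_colony / denom


def r2_marginal_conditional(vd: VarianceDecomposition) -> tuple[float, float]:
    """Marginal and conditional R-squared on the total-variance scale."""
    total = vd.var_fixed + vd.var_colony + vd.var_date + vd.var_resid
    if total == 0:
        raise ValueError("zero total variance; R2 undefined")
    rm2 = vd.var_fixed / total
    rc2 = (vd.var_fixed + vd.var_colony + vd.var_date) / total
    return rm2, rc2


def _parametric_draw(vd: VarianceDecomposition, d: pd.DataFrame,
                     spec: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    n = len(d)
    y = vd.fitted_fixed.copy()
    ccodes, clevels = pd.factorize(d[spec.random[0]], sort=True)
    y += (np.sqrt(vd.var_colony) * rng.standard_normal(len(clevels)))[ccodes]
    if len(spec.random) > 1:
        dcodes, dlevels = pd.factorize(d[spec.random[1]], sort=True)
        y += (np.sqrt(vd.var_date) * rng.standard_normal(len(dlevels)))[dcodes]
    y += np.sqrt(vd.var_resid) * rng.standard_normal(n)
    return y


def bootstrap_repeatability(table: pd.DataFrame, spec: ModelSpec,
                            B: int = 1000,
                            rng: np.random.Generator | None = None,
                            seed: int | None = None,
                            method: str = "parametric",
                            include_fixed: bool = False,
                            engine: str = "auto") -> RepeatabilityEstimate:
    """95% percentile bootstrap interval for colony repeatability.

    ``method="parametric"`` (default) simulates replicate datasets from the
    fitted model; ``method="rows"`` resamples colony-day rows with
    replacement within each colony, preserving the colony levels.
    Non-convergent replicates are dropped and counted; more than 10% of them
    triggers a warning.  Deterministic given data and seed.
    """
    if method not in ("parametric", "rows"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    _, _, _, d = _design(table, spec)
    point_vd = fit_lmm(d, spec, engine=engine)
    point = repeatability(point_vd, include_fixed=include_fixed)
    samples = []
    n_failed = 0
    groups = {g: idx.to_numpy() for g, idx in d.groupby(spec.random[0]).groups.items()}
    for _ in range(B):
        if method == "parametric":
            boot = d.copy()
            boot[spec.response] = _parametric_draw(point_vd, d, spec, rng)
        else:
            take = np.concatenate([
                idx[rng.integers(0, len(idx), len(idx))]
                for idx in groups.values()
            ])
            boot = d.loc[take].reset_index(drop=True)
        try:
            vd = fit_lmm(boot, spec, engine=engine)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not vd.converged:
            n_failed += 1
            continue
        samples.append(repeatability(vd, include_fixed=include_fixed))
    if n_failed > 0.1 * B:
        logger.warning("bootstrap: %d/%d replicates failed to converge",
                       n_failed, B)
    arr = np.asarray(samples)
    if arr.size == 0:
        raise RuntimeError("all bootstrap replicates failed")
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return RepeatabilityEstimate(R=point, ci_low=float(lo), ci_high=float(hi),
                                 n_bootstrap=B, n_failed=n_failed,
                                 method=method, samples=arr)


def compute_vif(table: pd.DataFrame, spec: ModelSpec) -> dict[str, float]:
    """Variance inflation factor per fixed effect (1/(1-R^2_j)).

    Each fixed-effect column is regressed on the others plus an intercept;
    perfectly collinear columns are an error naming the column.
    """
    if len(spec.fixed) < 2:
        raise ValueError("VIF needs at least two fixed effects")
    _, X, names, _ = _design(table, spec)
    out = {}
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        xj = X[:, j]
        others = np.delete(X, j, axis=1)  # keeps the intercept column
        coef, _, _, _ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        ssr = float(resid @ resid)
        sst = float(((xj - xj.mean()) ** 2).sum())
        if sst == 0:
            raise ValueError(f"fixed effect {name!r} is constant")
        r2 = 1.0 - ssr / sst
        if r2 > 1.0 - 1e-10:
            raise ValueError(f"fixed effect {name!r} is perfectly collinear "
                             "with the others")
        out[name] = 1.0 / (1.0 - r2)
    return out


def partial_residuals(table: pd.DataFrame, vd: VarianceDecomposition,
                      focal: str) -> pd.Series:
    """Corrected metric series for one focal driver.

    Subtracts every other fixed-effect contribution and the predicted
    random-effect contributions from the response, leaving intercept + focal
    term + residual -- the quantity plotted against the focal driver.
    """
    spec = vd.spec
    if focal not in spec.fixed:
        raise ValueError(f"focal driver {focal!r} not in the fitted model")
    d = table.loc[vd.row_index]
    y = d[spec.response].to_numpy(dtype=float)
    corrected = y - vd.ranef_rows
    for name in spec.fixed:
        if name == focal:
            continue
        est = vd.beta[name][0]
        corrected = corrected - est * d[name].to_numpy(dtype=float)
    return pd.Series(corrected, index=vd.row_index, name=f"{spec.response}_corrected")
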