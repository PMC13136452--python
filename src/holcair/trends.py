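"""Linear mixed-effects trends of annual pollution by redlining category.

The model for tract *i* in category *c(i)* and year *t*::

    y_it = b0 + b_c(i) + (b_t + g_c(i)) * (t - t0) + u_i + e_it
    u_i ~ N(0, s2_u),  e_it ~ N(0, s2_e)

with the A category as reference (b_A = g_A = 0) and year centered at the
first panel year, so ``b0`` is the reference level at the origin year and
``b_t`` its annual slope.  The tract random intercept ``u_i`` absorbs the
correlation of repeated annual measures within a tract.

Estimation is REML (maximum likelihood fallback on non-convergence) via
statsmodels MixedLM.  Overall tests of category differences in levels (at
a given year) and in slopes are Wald chi-square tests on the fixed-effect
covariance; pairwise category-vs-reference contrasts use a Bonferroni
threshold alpha/m with m the number of non-reference categories present,
and are gated on the overall test by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

#: Table row order used in reports: worst grade first, reference last.
REPORT_ORDER = ("D", "C", "B", "ungraded", "A")


class FitError(RuntimeError):
    """Raised when the mixed model cannot be fit on the given panel."""


@dataclass
class TrendFit:
    """Fitted fixed effects, their covariance, and variance components."""

    reference: str
    year_origin: int
    categories: tuple[str, ...]        # non-reference categories, model order
    params: pd.Series                  # named fixed effects
    cov: pd.DataFrame                  # fixed-effect covariance block
    sigma2_u: float                    # tract random-intercept variance
    sigma2_e: float                    # residual variance
    n_obs: int
    n_tracts: int
    n_tracts_by_category: dict = field(default_factory=dict)
    converged: bool = True
    method: str = "reml"

    def param_names(self) -> list[str]:
        return list(self.params.index)


@dataclass
class ContrastResult:
    label: str
    estimate: float
    se: float
    statistic: float
    p: float
    significant: bool
    evaluated: bool = True


def _design(df: pd.DataFrame, reference: str, categories: list[str]
            ) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for c in categories:
        X[f"level[{c}]"] = (df.category == c).astype(float)
    X["year"] = df.yr
    for c in categories:
        X[f"slope[{c}]"] = (df.category == c) * df.yr
    return X


def fit_trend(panel: pd.DataFrame, scores: pd.DataFrame, reference: str = "A",
              year_origin: int | None = None, reml: bool = True) -> TrendFit:
    """Fit the category × year mixed model with tract random intercepts.

    ``panel`` is the exposure panel (``tract_id, year, mean`` at minimum,
    one pollutant); ``scores`` supplies each tract's category.  Rows with
    missing annual means are dropped.  When the residual variance is
    numerically zero (noise-free panels) the mixed likelihood is singular;
    the fixed effects are then the exact least-squares solution and the
    fit degrades gracefully to it with zero variance components.
    """
    df = panel.merge(scores[["tract_id", "category"]], on="tract_id", how="left")
    if df.category.isna().any():
        missing = df.loc[df.category.isna(), "tract_id"].unique()[:5]
        raise ValueError(f"panel tracts without a category, e.g. {list(missing)}")
    df = df.dropna(subset=["mean"]).reset_index(drop=True)
    cats_present = [c for c in REPORT_ORDER if c in set(df.category)]
    if reference not in cats_present:
        raise ValueError(f"reference category {reference!r} not present")
    if len(cats_present) < 2 or df.year.nunique() < 2:
        raise ValueError("need >= 2 categories and >= 2 distinct years")
    counts = df.groupby("category")["tract_id"].nunique()
    singular = counts[counts < 2]
    if len(singular):
        raise FitError(f"categories with a single tract: {list(singular.index)}")

    y0 = int(df.year.min()) if year_origin is None else int(year_origin)
    df["yr"] = df.year - y0
    # model order: B, C, D, ungraded (reference excluded), stable and readable
    categories = [c for c in ("B", "C", "D", "ungraded", "A") if c in cats_present
                  and c != reference]
    X = _design(df, reference, categories)
    y = df["mean"].to_numpy(float)
    meta = dict(n_obs=len(df), n_tracts=df.tract_id.nunique(),
                n_tracts_by_category={c: int(df[df.category == c].tract_id.nunique())
                                      for c in cats_present})

    # Noise-free / perfectly collinear panels: the mixed likelihood has no
    # interior optimum, but the fixed effects are the exact LS solution.
    beta_ls, res, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    resid = y - X.to_numpy() @ beta_ls
    if float(resid @ resid) / len(y) < 1e-16:
        log.info("panel is noise-free; exact least-squares fit")
        k = X.shape[1]
        return TrendFit(reference=reference, year_origin=y0,
                        categories=tuple(categories),
                        params=pd.Series(beta_ls, index=X.columns),
                        cov=pd.DataFrame(np.zeros((k, k)), index=X.columns,
                                         columns=X.columns),
                        sigma2_u=0.0, sigma2_e=0.0, converged=True,
                        method="exact", **meta)

    last_err = None
    for use_reml, name in ([(True, "reml")] if reml else []) + [(False, "ml")]:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, X, groups=df.tract_id.to_numpy())
                result = model.fit(reml=use_reml, method="lbfgs")
            if not result.converged:
                raise FitError(f"{name} fit did not converge")
            k = X.shape[1]
            cov = pd.DataFrame(np.asarray(result.cov_params())[:k, :k],
                               index=X.columns, columns=X.columns)
            return TrendFit(reference=reference, year_origin=y0,
                            categories=tuple(categories),
                            params=pd.Series(np.asarray(result.fe_params),
                                             index=X.columns),
                            cov=cov,
                            sigma2_u=float(np.asarray(result.cov_re)[0, 0]),
                            sigma2_e=float(result.scale),
                            converged=True, method=name, **meta)
        except (FitError, np.linalg.LinAlgError, ValueError) as err:
            last_err = err
            log.warning("%s fit failed (%s); falling back", name, err)
    # Both likelihood fits failed — in practice the random-effect variance is
    # on its zero boundary, where the model reduces to OLS with iid errors.
    log.warning("mixed fits failed (%s); using the OLS boundary model", last_err)
    k = X.shape[1]
    Xm = X.to_numpy()
    dof = len(y) - k
    if dof <= 0:
        raise FitError(f"mixed model failed and OLS is underdetermined: {last_err}")
    s2 = float(resid @ resid) / dof
    cov = pd.DataFrame(s2 * np.linalg.inv(Xm.T @ Xm), index=X.columns,
                       columns=X.columns)
    return TrendFit(reference=reference, year_origin=y0,
                    categories=tuple(categories),
                    params=pd.Series(beta_ls, index=X.columns), cov=cov,
                    sigma2_u=0.0, sigma2_e=s2, converged=True, method="ols",
                    **meta)


def _contrast_vector(fit: TrendFit, category: str, mode: str,
                     year: int | None = None) -> pd.Series:
    c = pd.Series(0.0, index=fit.param_names())
    if mode == "level":
        t = year - fit.year_origin
        c["Intercept"] = 1.0
        c["year"] = t
        if category != fit.reference:
            c[f"level[{category}]"] = 1.0
            c[f"slope[{category}]"] = t
    elif mode == "slope":
        c["year"] = 1.0
        if category != fit.reference:
            c[f"slope[{category}]"] = 1.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return c


def _known(fit: TrendFit, category: str) -> None:
    if category != fit.reference and category not in fit.categories:
        raise ValueError(f"category {category!r} not in fit")


def predicted_level(fit: TrendFit, category: str, year: int
                    ) -> tuple[float, float]:
    """Model-predicted mean level for a category at a calendar year, with
    its standard error from the fixed-effect covariance."""
    _known(fit, category)
    c = _contrast_vector(fit, category, "level", year)
    est = float(c @ fit.params)
    se = float(np.sqrt(max(c @ fit.cov @ c, 0.0)))
    return est, se


def category_slope(fit: TrendFit, category: str) -> tuple[float, float]:
    """A category's annual slope (units/yr) and its standard error."""
    _known(fit, category)
    c = _contrast_vector(fit, category, "slope")
    est = float(c @ fit.params)
    se = float(np.sqrt(max(c @ fit.cov @ c, 0.0)))
    return est, se


def _wald(fit: TrendFit, C: np.ndarray) -> float:
    b = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    cb = C @ b
    cvc = C @ V @ C.T
    if not np.any(cvc):
        # exact (noise-free) fit: the test degenerates to equality of the
        # offsets themselves
        return 0.0 if np.any(np.abs(cb) > 1e-12) else 1.0
    try:
        w = float(cb @ np.linalg.solve(cvc, cb))
    except np.linalg.LinAlgError as err:
        raise FitError(f"singular contrast covariance: {err}")
    return float(stats.chi2.sf(w, df=C.shape[0]))


def overall_level_test(fit: TrendFit, year: int) -> float:
    """Wald chi-square p-value that all category level offsets at ``year``
    (b_c + g_c * (year - t0)) are simultaneously zero."""
    t = year - fit.year_origin
    names = fit.param_names()
    C = np.zeros((len(fit.categories), len(names)))
    for i, cat in enumerate(fit.categories):
        C[i, names.index(f"level[{cat}]")] = 1.0
        C[i, names.index(f"slope[{cat}]")] = t
    return _wald(fit, C)


def overall_slope_test(fit: TrendFit) -> float:
    """Wald chi-square p-value that all category slope offsets are zero."""
    names = fit.param_names()
    C = np.zeros((len(fit.categories), len(names)))
    for i, cat in enumerate(fit.categories):
        C[i, names.index(f"slope[{cat}]")] = 1.0
    return _wald(fit, C)


def pairwise_contrasts(fit: TrendFit, mode: str = "level",
                       year: int | None = None, alpha: float = 0.05,
                       gate: bool = True) -> list[ContrastResult]:
    """Each non-reference category vs the reference, Bonferroni adjusted.

    ``mode`` is "level" (requires ``year``) or "slope".  The Bonferroni
    threshold is alpha/m with m the number of non-reference categories.
    With ``gate=True`` the contrasts are computed but flagged
    ``evaluated=False`` (never significant) unless the corresponding
    overall test rejects at ``alpha``.
    """
    if mode == "level" and year is None:
        raise ValueError("mode='level' requires a year")
    m = len(fit.categories)
    overall_p = (overall_level_test(fit, year) if mode == "level"
                 else overall_slope_test(fit))
    gated_out = gate and not overall_p < alpha
    out = []
    for cat in fit.categories:
        ref_c = _contrast_vector(fit, fit.reference, mode, year)
        cat_c = _contrast_vector(fit, cat, mode, year)
        d = cat_c - ref_c
        est = float(d @ fit.params)
        se = float(np.sqrt(max(d @ fit.cov @ d, 0.0)))
        z = est / se if se > 0 else np.inf * np.sign(est or 1)
        p = float(2 * stats.norm.sf(abs(z)))
        label = (f"{cat} vs {fit.reference}, "
                 + (f"level at {year}" if mode == "level" else "slope"))
        out.append(ContrastResult(label=label, estimate=est, se=se, statistic=z,
                                  p=p,
                                  significant=(not gated_out) and p < alpha / m,
                                  evaluated=not gated_out))
    return out


def build_trend_table(panel: pd.DataFrame, scores: pd.DataFrame,
                      years: list[int], reference: str = "A",
                      alpha: float = 0.05, gate: bool = True,
                      year_origin: int | None = None) -> dict:
    """Assemble the per-category levels/slopes report.

    Returns a dict with ``fit`` (the :class:`TrendFit`), ``table`` (rows in
    D, C, B, ungraded, reference order: predicted level per requested year
    with a Bonferroni star, and the slope), ``overall_level_p`` per year,
    ``overall_slope_p``, and the raw ``contrasts``.
    """
    fit = fit_trend(panel, scores, reference=reference, year_origin=year_origin)
    cats = [c for c in REPORT_ORDER if c in (*fit.categories, fit.reference)]
    level_p = {y: overall_level_test(fit, y) for y in years}
    slope_p = overall_slope_test(fit)
    contrasts = {("level", y): pairwise_contrasts(fit, "level", year=y,
                                                  alpha=alpha, gate=gate)
                 for y in years}
    contrasts[("slope", None)] = pairwise_contrasts(fit, "slope", alpha=alpha,
                                                    gate=gate)

    def _star(mode, y, cat):
        if cat == fit.reference:
            return False
        for cr in contrasts[(mode, y)]:
            if cr.label.startswith(f"{cat} vs"):
                return cr.significant
        return False

    rows = []
    for cat in cats:
        row = {"category": cat if cat != fit.reference else f"{cat} (ref)",
               "n_tracts": fit.n_tracts_by_category.get(cat, 0)}
        for y in years:
            est, se = predicted_level(fit, cat, y)
            row[f"level_{y}"] = est
            row[f"se_{y}"] = se
            row[f"sig_{y}"] = _star("level", y, cat)
        s_est, s_se = category_slope(fit, cat)
        row["slope"] = s_est
        row["slope_se"] = s_se
        row["slope_sig"] = _star("slope", None, cat)
        rows.append(row)
    return {"fit": fit, "table": pd.DataFrame(rows), "overall_level_p": level_p,
            "overall_slope_p": slope_p, "contrasts": contrasts,
            "bonferroni_m": len(fit.categories), "alpha": alpha}
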