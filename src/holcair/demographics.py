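"""Category-level census/SVI summaries and percent change between periods.

Census and American Community Survey variables (population, race/ethnicity
shares, income, poverty, home value, rent, education) and the CDC Social
Vulnerability Index are averaged over the tracts of each redlining
category, separately for an early period (the 2000 census) and a late one
(an ACS multi-year window), and the percent change between the two
category means is reported.

Means are unweighted tract averages with missing values omitted — so a
tract counts once regardless of its population.  Percent change is
computed on the category-level means, not on tract-level changes; internal
math stays full precision, with display rounding only at serialization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .redlining_score import CATEGORY_ORDER

PERIODS = ("early", "late")


def category_means(table: pd.DataFrame, scores: pd.DataFrame, variable: str,
                   period: str) -> dict[str, tuple[float, int]]:
    """Unweighted mean of one variable over each category's tracts.

    Returns ``{category: (mean, n)}`` with NaN mean when no tract in the
    category has a value.  ``table`` is the long census table
    (``tract_id, period, variable, value``) or the SVI table
    (``tract_id, period, svi``).
    """
    if "svi" in table.columns and variable == "svi":
        sub = table[table.period == period].rename(columns={"svi": "value"})
    else:
        if "variable" not in table.columns or variable not in set(table.variable):
            raise ValueError(f"unknown variable {variable!r}")
        sub = table[(table.period == period) & (table.variable == variable)]
    merged = sub.merge(scores[["tract_id", "category"]], on="tract_id")
    out = {}
    for cat in CATEGORY_ORDER:
        vals = merged.loc[merged.category == cat, "value"].dropna()
        out[cat] = (float(vals.mean()) if len(vals) else float("nan"), int(len(vals)))
    return out


def percent_change(early_mean: float, late_mean: float) -> float:
    """``100 * (late - early) / early``, the change between period means."""
    if early_mean is None or late_mean is None or not np.isfinite(early_mean) \
            or not np.isfinite(late_mean):
        return float("nan")
    if early_mean == 0:
        raise ValueError("percent change undefined for a zero early mean")
    return 100.0 * (late_mean - early_mean) / early_mean


def svi_summary(svi: pd.DataFrame, scores: pd.DataFrame, period: str,
                ) -> dict[str, tuple[float, float]]:
    """Per-category SVI mean and sample SD (n-1), missing omitted.

    SD is NaN for categories with fewer than two tracts.
    """
    sub = svi[svi.period == period].merge(scores[["tract_id", "category"]],
                                          on="tract_id")
    out = {}
    for cat in CATEGORY_ORDER:
        vals = sub.loc[sub.category == cat, "svi"].dropna()
        mean = float(vals.mean()) if len(vals) else float("nan")
        sd = float(vals.std(ddof=1)) if len(vals) >= 2 else float("nan")
        out[cat] = (mean, sd)
    return out


def build_summary(census: pd.DataFrame, svi: pd.DataFrame,
                  scores: pd.DataFrame) -> pd.DataFrame:
    """Full category × period summary of every census variable plus SVI.

    One row per (variable, category) with early/late means, contributing
    tract counts, and the percent change of the category means; SVI rows
    also carry the per-period SD.
    """
    rows = []
    variables = sorted(census.variable.unique())
    for var in variables:
        early = category_means(census, scores, var, "early")
        late = category_means(census, scores, var, "late")
        for cat in CATEGORY_ORDER:
            (em, en), (lm, ln) = early[cat], late[cat]
            change = (percent_change(em, lm)
                      if np.isfinite(em) and em != 0 and np.isfinite(lm)
                      else float("nan"))
            rows.append({"variable": var, "category": cat,
                         "early_mean": em, "early_n": en,
                         "late_mean": lm, "late_n": ln,
                         "pct_change": change})
    sv_e, sv_l = (svi_summary(svi, scores, p) for p in PERIODS)
    for cat in CATEGORY_ORDER:
        (em, esd), (lm, lsd) = sv_e[cat], sv_l[cat]
        rows.append({"variable": "svi", "category": cat,
                     "early_mean": em, "early_sd": esd,
                     "late_mean": lm, "late_sd": lsd,
                     "pct_change": percent_change(em, lm)
                     if np.isfinite(em) and em != 0 else float("nan")})
    return pd.DataFrame(rows)


def round_for_display(summary: pd.DataFrame) -> pd.DataFrame:
    """Display precision: integers for monetary/population means, one
    decimal for percentages and percent change, three for SVI."""
    out = summary.copy()

    def _round_mean(row, col):
        v = getattr(row, col)
        if not np.isfinite(v):
            return v
        if row.variable == "svi":
            return round(v, 3)
        if row.variable.startswith("pct_"):
            return round(v, 1)
        return round(v)

    for col in ("early_mean", "late_mean"):
        out[col] = [_round_mean(r, col) for r in out.itertuples(index=False)]
    out["pct_change"] = out["pct_change"].round(1)  # .pct_change is a DataFrame method
    return out
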