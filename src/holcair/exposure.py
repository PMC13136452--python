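"""Grid-to-tract exposure aggregation.

Daily pollutant estimates arrive on a regular grid (nominally 1 km²).
Each census tract gets an area-proportional weighted daily value — the
average of overlapping cell values weighted by the fraction of the tract's
area each cell covers — which is then averaged within calendar years to a
tract-year exposure panel.  A robust screening step can first remove
sustained runs of aberrant values (the kind of multi-month dips that
occasionally contaminate modeled pollution surfaces), either automatically
or from a manual exclusion list.

Note the two denominators used in this package: pollution weights divide
by total tract geometry area, while redlining grade fractions divide by
census land area.  Both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

import logging

log = logging.getLogger(__name__)

#: Minimum fraction of a tract covered by grid cells with data for a
#: tract-day value to be computed (weights are renormalized above this).
DEFAULT_MIN_COVERAGE = 0.8
#: Minimum fraction of days in a year required for an annual mean.
DEFAULT_MIN_DAY_FRAC = 0.75

ROBUST_SD_FACTOR = 1.4826  # MAD -> SD for a normal distribution


@dataclass
class PollutionGrid:
    """One pollutant's daily values on a polygon grid.

    ``cells`` has columns ``cell_id, geometry``; ``values`` has
    ``cell_id, date, value`` in long form.  ``injected_mask`` is only set
    by the synthetic generator's aberrant-value injector (ground truth for
    screening tests).
    """

    pollutant: str
    cells: pd.DataFrame
    values: pd.DataFrame
    injected_mask: np.ndarray | None = None

    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        d = pd.to_datetime(self.values["date"])
        return d.min(), d.max()


@dataclass
class WeightVector:
    """Per-tract area weights over grid cells.

    ``weights[cell] = area(tract ∩ cell) / area(tract)``; ``coverage`` is
    their raw sum (≤ 1, shy of 1 where the grid falls short of the tract).
    """

    tract_id: str
    weights: dict[str, float] = field(default_factory=dict)
    coverage: float = 0.0


@dataclass
class AnnualExposure:
    tract_id: str | None
    year: int
    pollutant: str | None
    mean: float
    n_days: int


def _weights_one(tract_geometry: BaseGeometry, cells: pd.DataFrame,
                 tree: STRtree, geoms: list, tract_id: str,
                 min_area_m2: float) -> WeightVector:
    area = tract_geometry.area
    if area <= 0:
        raise ValueError(f"tract {tract_id!r} has zero area")
    weights = {}
    for i in tree.query(tract_geometry):
        a = tract_geometry.intersection(geoms[i]).area
        if a > min_area_m2:
            weights[cells.cell_id.iloc[i]] = a / area
    return WeightVector(tract_id=tract_id, weights=weights,
                        coverage=float(sum(weights.values())))


def compute_area_weights(tract_geometry: BaseGeometry, cells: pd.DataFrame,
                         tract_id: str = "?",
                         min_area_m2: float = 1e-6) -> WeightVector:
    """Fraction of the tract's area overlapped by each grid cell."""
    geoms = list(cells.geometry)
    return _weights_one(tract_geometry, cells, STRtree(geoms), geoms,
                        tract_id, min_area_m2)


def tract_daily_value(weights: WeightVector, day_values: dict[str, float],
                      min_coverage: float = DEFAULT_MIN_COVERAGE) -> float:
    """Area-weighted average of the cells with data on one day.

    Weights of cells missing that day are dropped and the rest renormalized;
    returns NaN when the surviving weights cover less than ``min_coverage``
    of the tract.
    """
    num = den = 0.0
    for cell, w in weights.weights.items():
        v = day_values.get(cell)
        if v is not None and np.isfinite(v):
            num += w * v
            den += w
    if den < min_coverage * max(weights.coverage, 1e-12) or den == 0:
        return float("nan")
    return num / den


def annual_average(daily: pd.Series, year: int,
                   min_day_frac: float = DEFAULT_MIN_DAY_FRAC,
                   tract_id: str | None = None,
                   pollutant: str | None = None) -> AnnualExposure:
    """Arithmetic mean of non-missing daily values within one year.

    ``daily`` is indexed by date.  The mean is NaN when fewer than
    ``min_day_frac`` of the year's days are available.
    """
    if not 0 < min_day_frac <= 1:
        raise ValueError("min_day_frac must lie in (0, 1]")
    idx = pd.to_datetime(daily.index)
    sel = daily[idx.year == year].dropna()
    days_in_year = pd.Timestamp(year=year, month=12, day=31).dayofyear
    n = len(sel)
    mean = float(sel.mean()) if n >= min_day_frac * days_in_year else float("nan")
    return AnnualExposure(tract_id=tract_id, year=year, pollutant=pollutant,
                          mean=mean, n_days=n)


def _detrended_residuals(values: pd.DataFrame) -> pd.Series:
    """Residuals after removing a per-cell Theil–Sen annual trend and the
    cell's month-of-year median residual.

    Screening must not mistake the study period's own secular trend
    (roughly -1 unit/yr over 17 years) for aberrance, so each cell is
    detrended against its annual medians before month-level medians and
    MADs are formed.
    """
    df = values.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df.date.dt.year
    df["month"] = df.date.dt.month
    y0 = int(df.year.min())
    resid = pd.Series(np.nan, index=df.index)
    for _, grp in df.groupby("cell_id"):
        ann = grp.groupby("year")["value"].median()
        if len(ann) >= 2:
            slope = stats.theilslopes(ann.to_numpy(), ann.index.to_numpy())[0]
        else:
            slope = 0.0
        resid.loc[grp.index] = grp["value"] - slope * (grp["year"] - y0)
    df["resid"] = resid
    med = df.groupby(["cell_id", "month"])["resid"].transform("median")
    return df["resid"] - med


def _sustained_deviation(dev: pd.Series, dates: pd.Series, cells: pd.Series,
                         min_run_days: int) -> pd.Series:
    """Centered rolling median of the deviation over a min_run_days window,
    per cell.

    A sustained aberrant run keeps its full magnitude under the rolling
    median, while isolated noisy days are damped — so thresholding the
    smoothed deviation flags clusters lasting on the order of
    ``min_run_days`` and ignores single-day excursions.
    """
    df = pd.DataFrame({"dev": dev, "date": pd.to_datetime(dates), "cell": cells})
    out = pd.Series(np.nan, index=dev.index)
    for _, grp in df.groupby("cell"):
        grp = grp.sort_values("date")
        sm = grp.dev.rolling(min_run_days, center=True,
                             min_periods=max(1, min_run_days // 2)).median()
        out.loc[grp.index] = sm
    return out


def screen_aberrant(grid: PollutionGrid, method: str = "robust_z",
                    threshold: float = 5.0, min_run_days: int = 14,
                    manual_list: list[dict] | None = None,
                    ) -> tuple[PollutionGrid, pd.DataFrame]:
    """Remove sustained aberrant cell-day values.

    ``robust_z`` flags cell-days whose detrended deviation from the same
    cell's month-of-year median — smoothed by a centered ``min_run_days``
    rolling median so only sustained runs survive — exceeds ``threshold``
    robust SDs (1.4826×MAD);
    ``manual_list`` removes exactly the configured exclusions, each a dict
    with keys ``cells`` (list of cell ids or "all"), ``start`` and ``end``
    (inclusive ISO dates).  Returns the cleaned grid and a per-year report
    of removal counts.
    """
    values = grid.values.reset_index(drop=True)
    dates = pd.to_datetime(values["date"])
    if method == "robust_z":
        if threshold <= 0:
            raise ValueError("threshold must be > 0")
        dev = _detrended_residuals(values)
        key = pd.DataFrame({"cell_id": values.cell_id, "month": dates.dt.month,
                            "dev": dev})
        mad = key.groupby(["cell_id", "month"])["dev"].transform(
            lambda s: np.median(np.abs(s.to_numpy() - np.median(s.to_numpy()))))
        rsd = ROBUST_SD_FACTOR * mad
        smooth = _sustained_deviation(dev, values["date"], values["cell_id"],
                                      min_run_days)
        removed = smooth.abs() > threshold * rsd.replace(0, np.inf)
    elif method == "manual_list":
        removed = pd.Series(False, index=values.index)
        for item in manual_list or []:
            sel = (dates >= pd.Timestamp(item["start"])) & (dates <= pd.Timestamp(item["end"]))
            if item.get("cells", "all") != "all":
                sel &= values.cell_id.isin(item["cells"])
            removed |= sel
    else:
        raise ValueError(f"unknown screening method {method!r}")

    report = (pd.DataFrame({"year": dates.dt.year, "removed": removed})
              .groupby("year")["removed"].sum().rename("n_removed").reset_index())
    cleaned = PollutionGrid(pollutant=grid.pollutant, cells=grid.cells,
                            values=values.loc[~removed].reset_index(drop=True))
    cleaned.values.attrs["removed_mask"] = removed.to_numpy()
    return cleaned, report


def area_weight_matrix(tracts: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Dense tract × cell weight matrix (rows: tract_id, cols: cell_id)."""
    geoms = list(cells.geometry)
    tree = STRtree(geoms)
    W = pd.DataFrame(0.0, index=tracts.tract_id, columns=cells.cell_id)
    for t in tracts.itertuples(index=False):
        wv = _weights_one(t.geometry, cells, tree, geoms, t.tract_id, 1e-6)
        for cell, w in wv.weights.items():
            W.loc[t.tract_id, cell] = w
    return W


def aggregate_city(tracts: pd.DataFrame, grid: PollutionGrid,
                   screen: str | None = None, threshold: float = 5.0,
                   min_run_days: int = 14, manual_list: list[dict] | None = None,
                   min_coverage: float = DEFAULT_MIN_COVERAGE,
                   min_day_frac: float = DEFAULT_MIN_DAY_FRAC,
                   ) -> pd.DataFrame:
    """Weights → screening → daily tract values → annual means.

    Returns the exposure panel: one row per (tract, year) with columns
    ``tract_id, year, pollutant, mean, n_days``; the screening report, when
    screening ran, is attached as ``panel.attrs["screen_report"]``.
    """
    report = None
    if screen is not None:
        grid, report = screen_aberrant(grid, method=screen, threshold=threshold,
                                       min_run_days=min_run_days,
                                       manual_list=manual_list)
    W = area_weight_matrix(tracts, grid.cells)  # ntracts x ncells
    short = W.sum(axis=1)
    for tid, cov in short[short < 0.999].items():
        log.warning("tract %s: grid covers only %.1f%% of its area; "
                    "weights renormalized above min_coverage=%.2f",
                    tid, 100 * cov, min_coverage)
    vals = grid.values.copy()
    vals["date"] = pd.to_datetime(vals["date"])
    V = vals.pivot(index="date", columns="cell_id", values="value")
    V = V.reindex(columns=W.columns)

    Wm = W.to_numpy()           # (T, C)
    Vm = V.to_numpy()           # (D, C)
    has = np.isfinite(Vm)
    num = np.where(has, Vm, 0.0) @ Wm.T      # (D, T)
    den = has.astype(float) @ Wm.T
    coverage = W.sum(axis=1).to_numpy()      # raw coverage per tract
    low = den < min_coverage * np.maximum(coverage, 1e-12)[None, :]
    daily = np.where(low | (den == 0), np.nan, num / np.where(den == 0, 1, den))

    years = V.index.year
    rows = []
    for tix, tid in enumerate(W.index):
        s = pd.Series(daily[:, tix], index=V.index)
        for y in np.unique(years):
            ae = annual_average(s, int(y), min_day_frac, tract_id=tid,
                                pollutant=grid.pollutant)
            rows.append({"tract_id": tid, "year": ae.year,
                         "pollutant": grid.pollutant, "mean": ae.mean,
                         "n_days": ae.n_days})
    panel = pd.DataFrame(rows)
    if report is not None:
        panel.attrs["screen_report"] = report
    return panel
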