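"""Synthetic city generator with known ground truth.

Builds the four inputs the analysis pipeline consumes — a census-tract
lattice, HOLC-style graded polygons, a daily pollution grid, and
census/SVI tables — from a :class:`SyntheticTruth` parameter set, so every
downstream stage (scoring, exposure aggregation, demographic summaries,
trend fitting) can be tested against known parameters without any
external download.

All geometry lives in a single planar frame with meter units.  Real-data
users must supply layers in a shared equal-area projection; nothing here
reprojects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .exposure import PollutionGrid

GRADES = ("A", "B", "C", "D")
CATEGORIES = ("A", "B", "C", "D", "ungraded")

#: Default per-category pollutant level at the origin year (ppb, NO2-like
#: magnitudes) and annual change (ppb/yr).
DEFAULT_INTERCEPTS = {"A": 33.5, "B": 35.1, "C": 35.3, "D": 35.7, "ungraded": 36.0}
DEFAULT_SLOPES = {"A": -1.01, "B": -0.93, "C": -0.91, "D": -0.90, "ungraded": -0.87}

#: Default census effects: variable -> category -> (early mean, late mean, SD).
#: Magnitudes follow large-city census gradients across redlining categories
#: (income and education highest in A tracts, poverty and %Black highest in D).
DEFAULT_CENSUS_EFFECTS = {
    "total_population": {
        "A": (4458, 4776, 600), "B": (4290, 4540, 600), "C": (4636, 4448, 600),
        "D": (4176, 4240, 600), "ungraded": (4848, 4523, 600),
    },
    "pct_white": {
        "A": (85.0, 74.5, 8.0), "B": (81.5, 71.5, 8.0), "C": (70.1, 63.4, 8.0),
        "D": (55.3, 54.6, 8.0), "ungraded": (86.6, 79.8, 8.0),
    },
    "pct_black": {
        "A": (3.9, 6.7, 3.0), "B": (5.6, 8.0, 3.0), "C": (15.4, 16.3, 5.0),
        "D": (22.1, 21.6, 6.0), "ungraded": (3.7, 4.6, 3.0),
    },
    "median_income": {
        "A": (94054, 104553, 15000), "B": (85507, 94626, 14000),
        "C": (69640, 78482, 12000), "D": (52459, 62484, 10000),
        "ungraded": (82775, 87525, 14000),
    },
    "pct_poverty": {
        "A": (5.2, 11.3, 3.0), "B": (6.6, 9.5, 3.0), "C": (8.6, 11.9, 3.5),
        "D": (16.1, 17.1, 4.5), "ungraded": (6.1, 10.0, 3.0),
    },
}

#: Default SVI effects: category -> (early mean, late mean, SD).  D tracts
#: roughly twice as vulnerable as A tracts, as observed in redlined cities.
DEFAULT_SVI_EFFECTS = {
    "A": (0.332, 0.348, 0.234), "B": (0.357, 0.355, 0.254),
    "C": (0.481, 0.445, 0.273), "D": (0.664, 0.598, 0.249),
    "ungraded": (0.328, 0.314, 0.232),
}

DEFAULT_GRADE_LAYOUT = {"A": 0.2, "B": 0.2, "C": 0.2, "D": 0.2}  # 20% margin


@dataclass
class SyntheticTruth:
    """Ground-truth parameters for one synthetic city.

    ``category_intercepts``/``category_slopes`` define the pollutant level
    at ``year_origin`` and its annual change for each redlining category
    (units of the pollutant, ppb or μg/m³).  Daily values add an annual
    sinusoid of ``seasonal_amplitude``, a tract-level random intercept with
    SD ``tract_re_sd``, and iid daily noise with SD ``noise_sd``.
    """

    category_intercepts: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    category_slopes: dict = field(default_factory=lambda: dict(DEFAULT_SLOPES))
    seasonal_amplitude: float = 3.0
    noise_sd: float = 2.0
    tract_re_sd: float = 0.5
    grade_layout: dict = field(default_factory=lambda: dict(DEFAULT_GRADE_LAYOUT))
    census_effects: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_CENSUS_EFFECTS.items()})
    svi_effects: dict = field(default_factory=lambda: dict(DEFAULT_SVI_EFFECTS))
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.tract_re_sd < 0:
            raise ValueError("noise_sd and tract_re_sd must be >= 0")
        cov = [v for v in self.grade_layout.values()]
        if any(not 0 <= v <= 1 for v in cov) or sum(cov) > 1 + 1e-9:
            raise ValueError("grade coverage fractions must lie in [0,1] and sum to <= 1")

    def replace(self, **kw) -> "SyntheticTruth":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticCity:
    """A fully generated city plus the truth that produced it."""

    tracts: pd.DataFrame
    graded_areas: pd.DataFrame
    pollution: PollutionGrid
    census: pd.DataFrame
    svi: pd.DataFrame
    truth: SyntheticTruth


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Per-component substream of a master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def generate_tracts(nx: int, ny: int, cell_m: float, seed: int = 0) -> pd.DataFrame:
    """Tile ``[0, nx*cell_m] x [0, ny*cell_m]`` with square census tracts.

    Returns a DataFrame with columns ``tract_id``, ``geometry`` (shapely
    polygon, meters) and ``land_area`` (m², equal to the polygon area: the
    synthetic city has no water).
    """
    if nx < 1 or ny < 1 or cell_m <= 0:
        raise ValueError("nx, ny must be >= 1 and cell_m > 0")
    rows = []
    for iy in range(ny):
        for ix in range(nx):
            geom = box(ix * cell_m, iy * cell_m, (ix + 1) * cell_m, (iy + 1) * cell_m)
            rows.append({"tract_id": f"T{ix:03d}{iy:03d}", "geometry": geom,
                         "land_area": cell_m * cell_m})
    return pd.DataFrame(rows)


def _snap(x: float, step: float) -> float:
    return round(x / step) * step


def generate_holc_map(tracts: pd.DataFrame, layout: dict | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Lay non-overlapping graded rectangles over the tract lattice.

    ``layout`` maps grade letters to target coverage fractions of the full
    lattice area; whatever is left over stays ungraded (an optional
    ``"margin"`` key may state that remainder explicitly and is validated).
    Grades are placed as vertical bands spanning the lattice, with the
    ungraded margin carved out as a central horizontal strip — so the
    convex hull of the graded areas still contains the ungraded tracts,
    as in cities whose HOLC maps left interior pockets unmapped.  All
    edges snap to half-tract positions so exact overlap fractions are
    analytically computable and some tracts straddle two grades.  The
    band order is shuffled by ``seed``.
    """
    layout = dict(layout if layout is not None else DEFAULT_GRADE_LAYOUT)
    margin = layout.pop("margin", None)
    bad = set(layout) - set(GRADES)
    if bad:
        raise ValueError(f"unknown grade keys in layout: {sorted(bad)}")
    total = sum(layout.values())
    if total > 1 + 1e-9:
        raise ValueError("requested coverage fractions sum to > 1")
    if margin is not None and abs((1 - total) - margin) > 0.05 + 1e-9:
        raise ValueError("explicit margin inconsistent with 1 - sum(coverage)")
    margin = 1 - total

    xmin = min(g.bounds[0] for g in tracts.geometry)
    ymin = min(g.bounds[1] for g in tracts.geometry)
    xmax = max(g.bounds[2] for g in tracts.geometry)
    ymax = max(g.bounds[3] for g in tracts.geometry)
    W, H = xmax - xmin, ymax - ymin
    # half-tract snapping step
    cell = np.sqrt(tracts.land_area.iloc[0])
    step = cell / 2.0

    # central ungraded strip of height margin*H, edges snapped to half-tracts
    mh = _snap(H * margin, step)
    if mh >= H:
        raise ValueError("margin leaves no graded area")
    sy0 = _snap((H - mh) / 2, step)
    sy1 = sy0 + mh
    grades = [g for g in GRADES if layout.get(g, 0) > 0]
    order = list(_rng(seed, 0).permutation(grades))
    # cumulative band edges proportional to coverage within the graded area
    edges = [0.0]
    cum = 0.0
    for g in order:
        cum += layout[g] / (1 - margin)
        edges.append(_snap(W * cum, step))
    edges[-1] = W  # guard rounding at the far edge
    rows = []
    for i, g in enumerate(order):
        x0, x1 = xmin + edges[i], xmin + edges[i + 1]
        if x1 - x0 <= 0:
            continue
        pieces = ([box(x0, ymin, x1, ymin + sy0), box(x0, ymin + sy1, x1, ymax)]
                  if mh > 0 else [box(x0, ymin, x1, ymax)])
        for j, geom in enumerate(p for p in pieces if p.area > 0):
            rows.append({"area_id": f"{g}-{j}", "geometry": geom, "grade": g})
    return pd.DataFrame(rows).sort_values(["grade", "area_id"], ignore_index=True)


def _dominant_tracts(cells: pd.DataFrame, tracts: pd.DataFrame) -> pd.Series:
    """Tract id with the largest overlap for each grid cell (nearest tract
    for cells that do not touch the lattice)."""
    from shapely.strtree import STRtree

    geoms = list(tracts.geometry)
    tree = STRtree(geoms)
    out = []
    for geom in cells.geometry:
        idx = tree.query(geom)
        best, best_area = None, 0.0
        for i in idx:
            a = geom.intersection(geoms[i]).area
            if a > best_area:
                best, best_area = i, a
        if best is None:
            best = int(tree.nearest(geom))
        out.append(tracts.tract_id.iloc[best])
    return pd.Series(out, index=cells.index)


def generate_pollution_grid(tracts: pd.DataFrame, scores: pd.DataFrame,
                            years: tuple[int, int], truth: SyntheticTruth,
                            cell_m: float = 1000.0,
                            extent: tuple[float, float, float, float] | None = None,
                            origin: tuple[float, float] = (0.0, 0.0),
                            pollutant: str = "no2",
                            seed: int | None = None) -> PollutionGrid:
    """Simulate daily pollutant values on a regular grid.

    The daily value of cell *g* on day *t* of year *y* is::

        intercept[c] + slope[c] * (y - y0) + A * sin(2*pi*doy/365) + u_tract + eps

    where *c* is the redlining category of the cell's dominant tract (the
    tract overlapping it most), ``u_tract ~ N(0, tract_re_sd²)`` is shared by
    all cells dominated by the same tract, and ``eps ~ N(0, noise_sd²)`` is
    iid per cell-day.  ``extent`` may fall short of the tract lattice to
    exercise coverage-shortfall handling downstream.
    """
    y_start, y_end = years
    if y_end < y_start:
        raise ValueError("empty year range")
    seed = truth.seed if seed is None else seed
    if extent is None:
        xs = [g.bounds for g in tracts.geometry]
        extent = (min(b[0] for b in xs), min(b[1] for b in xs),
                  max(b[2] for b in xs), max(b[3] for b in xs))
    x0g, y0g = origin
    xmin, ymin, xmax, ymax = extent
    nix = int(np.ceil((xmax - x0g) / cell_m))
    niy = int(np.ceil((ymax - y0g) / cell_m))
    cells = []
    for iy in range(niy):
        for ix in range(nix):
            cx0, cy0 = x0g + ix * cell_m, y0g + iy * cell_m
            if cx0 >= xmax or cy0 >= ymax or cx0 + cell_m <= xmin or cy0 + cell_m <= ymin:
                continue
            cells.append({"cell_id": f"g{ix:03d}{iy:03d}",
                          "geometry": box(cx0, cy0, cx0 + cell_m, cy0 + cell_m)})
    cells = pd.DataFrame(cells)

    cat = scores.set_index("tract_id")["category"]
    dom = _dominant_tracts(cells, tracts)
    cell_cat = dom.map(cat)

    re_rng = _rng(seed, 1)
    tract_ids = list(tracts.tract_id)
    u = pd.Series(re_rng.normal(0.0, truth.tract_re_sd, len(tract_ids)),
                  index=tract_ids)

    dates = pd.date_range(f"{y_start}-01-01", f"{y_end}-12-31", freq="D")
    yearfrac = (dates.year - y_start).to_numpy(float)
    seasonal = truth.seasonal_amplitude * np.sin(2 * np.pi * dates.dayofyear.to_numpy() / 365.0)

    icpt = cell_cat.map(truth.category_intercepts).to_numpy(float)
    slope = cell_cat.map(truth.category_slopes).to_numpy(float)
    base = icpt + u.loc[dom].to_numpy()  # per cell

    noise_rng = _rng(seed, 2)
    nd, nc = len(dates), len(cells)
    vals = (base[None, :] + slope[None, :] * yearfrac[:, None] + seasonal[:, None]
            + (noise_rng.normal(0.0, truth.noise_sd, (nd, nc)) if truth.noise_sd > 0
               else 0.0))
    values = pd.DataFrame({
        "cell_id": np.tile(cells.cell_id.to_numpy(), nd),
        "date": np.repeat(dates.to_numpy(), nc),
        "value": vals.ravel(),
    })
    return PollutionGrid(pollutant=pollutant, cells=cells, values=values)


def inject_aberrant_values(grid: PollutionGrid, window: tuple[str, str],
                           delta: float, frac_cells: float,
                           seed: int = 0) -> PollutionGrid:
    """Add ``delta`` to the daily values of a random cell subset within
    ``window`` (inclusive ISO dates), emulating the kind of sustained
    aberrant dips observed in modeled pollution surfaces.

    Returns a copy whose ``injected_mask`` records exactly the perturbed
    rows, so screening recovery can be asserted against ground truth.
    """
    if not 0 < frac_cells <= 1:
        raise ValueError("frac_cells must lie in (0, 1]")
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    dates = pd.to_datetime(grid.values["date"])
    span = (dates.min(), dates.max())
    if start > end:
        raise ValueError("empty window")
    if start > span[1] or end < span[0]:
        raise ValueError("window outside grid span")
    rng = np.random.default_rng(seed)
    cell_ids = grid.cells.cell_id.to_numpy()
    k = max(1, int(round(frac_cells * len(cell_ids))))
    chosen = set(rng.choice(cell_ids, size=k, replace=False))
    mask = (grid.values.cell_id.isin(chosen) & (dates >= start) & (dates <= end)).to_numpy()
    values = grid.values.copy()
    values.loc[mask, "value"] = values.loc[mask, "value"] + delta
    return PollutionGrid(pollutant=grid.pollutant, cells=grid.cells.copy(),
                         values=values, injected_mask=mask)


def generate_census_tables(scores: pd.DataFrame, truth: SyntheticTruth,
                           seed: int = 0, missing_rate: float = 0.0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw census and SVI tables whose variables co-vary with category.

    Census values are Normal draws from the category/period-specific truth
    (``census_effects[var][cat] = (early_mean, late_mean, sd)``); SVI draws
    are clamped to [0, 1].  ``missing_rate`` blanks census values at random.
    Returns ``(census, svi)`` long tables with a ``period`` column in
    {"early", "late"}.
    """
    if len(scores) == 0:
        raise ValueError("scores table is empty")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = _rng(seed, 3)
    cats = scores.set_index("tract_id")["category"]
    rows = []
    for var, eff in truth.census_effects.items():
        for period_i, period in enumerate(("early", "late")):
            means = cats.map({c: eff[c][period_i] for c in eff})
            sds = cats.map({c: eff[c][2] for c in eff})
            vals = rng.normal(means.to_numpy(float), sds.to_numpy(float))
            if var.startswith("pct_"):
                vals = np.clip(vals, 0.0, 100.0)
            for tid, v in zip(cats.index, vals):
                rows.append({"tract_id": tid, "period": period, "variable": var,
                             "value": v})
    census = pd.DataFrame(rows)
    if missing_rate > 0:
        drop = rng.random(len(census)) < missing_rate
        census.loc[drop, "value"] = np.nan

    svi_rows = []
    for period_i, period in enumerate(("early", "late")):
        means = cats.map({c: truth.svi_effects[c][period_i] for c in truth.svi_effects})
        sds = cats.map({c: truth.svi_effects[c][2] for c in truth.svi_effects})
        vals = np.clip(rng.normal(means.to_numpy(float), sds.to_numpy(float)), 0.0, 1.0)
        for tid, v in zip(cats.index, vals):
            svi_rows.append({"tract_id": tid, "period": period, "svi": v})
    svi = pd.DataFrame(svi_rows)
    return census, svi


def generate_annual_panel(truth: SyntheticTruth, n_per_category: int,
                          years: tuple[int, int], seed: int = 0,
                          categories: tuple[str, ...] | None = None,
                          resid_sd: float | None = None,
                          re_sd: float | None = None,
                          pollutant: str = "no2",
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw tract-year annual means directly from the trend model.

    A shortcut past the daily grid for statistical simulations: each tract
    *i* in category *c* contributes ``y_it = intercept[c] + slope[c]*(t-t0)
    + u_i + e_it`` with ``u_i ~ N(0, re_sd²)`` and ``e_it ~ N(0, resid_sd²)``.
    Returns ``(panel, scores)`` ready for :func:`holcair.trends.fit_trend`.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    cats = tuple(categories) if categories is not None else tuple(truth.category_intercepts)
    resid_sd = truth.noise_sd if resid_sd is None else resid_sd
    re_sd = truth.tract_re_sd if re_sd is None else re_sd
    rng = np.random.default_rng(seed)
    y0, y1 = years
    yrs = np.arange(y0, y1 + 1)
    rows, score_rows = [], []
    for c in cats:
        for i in range(n_per_category):
            tid = f"{c}{i:04d}"
            score_rows.append({"tract_id": tid, "category": c})
            u = rng.normal(0.0, re_sd) if re_sd > 0 else 0.0
            e = rng.normal(0.0, resid_sd, len(yrs)) if resid_sd > 0 else np.zeros(len(yrs))
            mu = (truth.category_intercepts[c]
                  + truth.category_slopes[c] * (yrs - y0) + u + e)
            for y, v in zip(yrs, mu):
                rows.append({"tract_id": tid, "year": int(y), "pollutant": pollutant,
                             "mean": v, "n_days": 365})
    return pd.DataFrame(rows), pd.DataFrame(score_rows)


def generate_hole_city(nx: int, ny: int, n_ungraded: int, cell_m: float = 1000.0,
                       grade: str = "D", seed: int = 0,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A lattice city whose HOLC map covers everything except an interior
    pocket of exactly ``n_ungraded`` tracts.

    Because the pocket sits inside the graded area, the convex hull of the
    graded polygons contains every tract, so downstream selection keeps all
    ``nx*ny`` tracts and exactly ``n_ungraded`` of them score 0 — handy for
    checking category-share arithmetic against known counts.
    """
    if not 0 <= n_ungraded <= nx * ny - 1:
        raise ValueError("n_ungraded must leave at least one graded tract")
    tracts = generate_tracts(nx, ny, cell_m, seed)
    extent = box(0, 0, nx * cell_m, ny * cell_m)
    if n_ungraded == 0:
        graded_geom = extent
    else:
        full_rows, rem = divmod(n_ungraded, nx)
        r0 = max(0, ny // 2 - 1)
        hole = box(0, r0 * cell_m, nx * cell_m, (r0 + full_rows) * cell_m)
        if rem:
            hole = hole.union(box(0, (r0 + full_rows) * cell_m, rem * cell_m,
                                  (r0 + full_rows + 1) * cell_m))
        graded_geom = extent.difference(hole)
    graded = pd.DataFrame([{"area_id": f"{grade}-0", "geometry": graded_geom,
                            "grade": grade}])
    return tracts, graded


def generate_city(nx: int = 10, ny: int = 10, cell_m: float = 1000.0,
                  years: tuple[int, int] = (2000, 2016),
                  truth: SyntheticTruth | None = None,
                  grid_cell_m: float | None = None,
                  grid_origin: tuple[float, float] = (0.0, 0.0),
                  pollutant: str = "no2",
                  missing_rate: float = 0.0,
                  seed: int | None = None) -> SyntheticCity:
    """Generate a complete synthetic city (tracts, HOLC map, pollution grid,
    census and SVI tables) from one master seed."""
    from .redlining_score import score_city

    truth = truth if truth is not None else SyntheticTruth()
    seed = truth.seed if seed is None else seed
    tracts = generate_tracts(nx, ny, cell_m, seed)
    graded = generate_holc_map(tracts, truth.grade_layout, seed)
    scores = score_city(tracts, graded)
    grid = generate_pollution_grid(
        tracts, scores, years, truth,
        cell_m=grid_cell_m if grid_cell_m is not None else cell_m,
        origin=grid_origin, pollutant=pollutant, seed=seed)
    census, svi = generate_census_tables(scores, truth, seed, missing_rate)
    return SyntheticCity(tracts=tracts, graded_areas=graded, pollution=grid,
                         census=census, svi=svi, truth=truth.replace(seed=seed))
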