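"""Tract-level historical-redlining scoring from HOLC grade polygons.

The Home Owners' Loan Corporation (HOLC) graded 1930s urban neighborhoods
A ("best") through D ("hazardous", i.e. redlined).  Because HOLC polygons
do not align with modern census tracts, each tract receives a continuous
redlining score: the fraction of its land area under each grade, weighted
by the numeric grade (A=1 ... D=4) and summed.  Scores are binned back to
categories — (0,1] → A, (1,2] → B, (2,3] → C, (3,4] → D — and tracts with
no graded area at all score 0 and form an extra "ungraded" category.

The study boundary is the convex hull of the graded polygons; the analysis
covers every tract intersecting that hull with positive area.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

log = logging.getLogger(__name__)

GRADE_NUMBER = {"A": 1, "B": 2, "C": 3, "D": 4}
CATEGORY_ORDER = ("A", "B", "C", "D", "ungraded")

#: Intersections smaller than this (m²) are treated as slivers and dropped.
DEFAULT_SLIVER_M2 = 1.0


class GeometryError(ValueError):
    """Raised for invalid or degenerate input geometry."""


def _check_geom(geom: BaseGeometry, owner: str) -> None:
    if geom is None or geom.is_empty:
        raise GeometryError(f"empty geometry for {owner}")
    if not geom.is_valid:
        raise GeometryError(f"invalid (self-intersecting?) geometry for {owner}")


def compute_boundary(graded_areas: pd.DataFrame) -> BaseGeometry:
    """Convex hull of the union of all graded polygons (the study boundary)."""
    if len(graded_areas) == 0:
        raise ValueError("no graded areas supplied")
    for aid, geom in zip(graded_areas.area_id, graded_areas.geometry):
        _check_geom(geom, f"graded area {aid!r}")
    hull = unary_union(list(graded_areas.geometry)).convex_hull
    if hull.is_empty or hull.area == 0:
        raise GeometryError("graded areas are degenerate; hull has zero area")
    return hull


def select_tracts(tracts: pd.DataFrame, boundary: BaseGeometry,
                  sliver_m2: float = DEFAULT_SLIVER_M2) -> pd.DataFrame:
    """Tracts intersecting the boundary with positive area, order preserved.

    Positive-area means intersection area above the sliver tolerance, so a
    tract sharing only an edge with the boundary is excluded.
    """
    keep = [geom.intersection(boundary).area > sliver_m2 for geom in tracts.geometry]
    return tracts.loc[keep].reset_index(drop=True)


def _grade_unions(graded_areas: pd.DataFrame) -> dict[str, BaseGeometry]:
    """Dissolve graded polygons into one (multi)polygon per grade."""
    out = {}
    for grade, grp in graded_areas.groupby("grade"):
        if grade not in GRADE_NUMBER:
            raise ValueError(f"unknown HOLC grade {grade!r}")
        for aid, geom in zip(grp.area_id, grp.geometry):
            _check_geom(geom, f"graded area {aid!r}")
        out[grade] = unary_union(list(grp.geometry))
    return out


def grade_fractions(tract_geometry: BaseGeometry, land_area: float,
                    graded_areas: pd.DataFrame | dict,
                    sliver_m2: float = DEFAULT_SLIVER_M2,
                    tract_id: str = "?") -> dict[str, float]:
    """Fraction of a tract's land area covered by each HOLC grade.

    ``graded_areas`` may be the graded-area table or a precomputed
    per-grade union from :func:`_grade_unions` (used by :func:`score_city`
    to avoid re-dissolving per tract).  Overlapping grades (digitization
    artifacts) can push the fraction sum above 1; fractions are then
    rescaled to 1 with a data-quality warning.
    """
    _check_geom(tract_geometry, f"tract {tract_id!r}")
    if land_area <= 0:
        raise ValueError(f"tract {tract_id!r} has non-positive land_area")
    unions = graded_areas if isinstance(graded_areas, dict) else _grade_unions(graded_areas)
    fractions = {}
    for grade, union in unions.items():
        area = tract_geometry.intersection(union).area
        if area >= sliver_m2:
            fractions[grade] = area / land_area
    total = sum(fractions.values())
    if total > 1 + 1e-9:
        log.warning("tract %s: graded fractions sum to %.6f > 1 "
                    "(overlapping grade polygons?); rescaling", tract_id, total)
        fractions = {g: f / total for g, f in fractions.items()}
    return fractions


def weighted_score(fractions: dict[str, float]) -> float:
    """Continuous redlining score: sum of grade fraction × numeric grade.

    An empty map (no graded coverage) scores 0.
    """
    return float(sum(f * GRADE_NUMBER[g] for g, f in fractions.items()))


def categorize(score: float) -> str:
    """Bin a continuous score into its redlining category.

    0 → ungraded; (0,1] → A; (1,2] → B; (2,3] → C; (3,4] → D
    (intervals left-open, right-closed).
    """
    if not 0 <= score <= 4:
        raise ValueError(f"score {score} outside [0, 4]")
    if score == 0:
        return "ungraded"
    for upper, cat in zip((1, 2, 3, 4), "ABCD"):
        if score <= upper:
            return cat
    raise AssertionError("unreachable")


def score_city(tracts: pd.DataFrame, graded_areas: pd.DataFrame,
               sliver_m2: float = DEFAULT_SLIVER_M2) -> pd.DataFrame:
    """Full scoring pipeline: boundary → tract selection → score → category.

    Returns one row per selected tract with columns ``tract_id``,
    ``frac_A`` … ``frac_D``, ``score`` and ``category``.  Use
    :func:`score_summary` for the per-category counts and shares.
    """
    if len(tracts) == 0:
        raise ValueError("no tracts supplied")
    boundary = compute_boundary(graded_areas)
    selected = select_tracts(tracts, boundary, sliver_m2)
    unions = _grade_unions(graded_areas)
    rows = []
    for t in selected.itertuples(index=False):
        fr = grade_fractions(t.geometry, t.land_area, unions, sliver_m2, t.tract_id)
        score = weighted_score(fr)
        rows.append({"tract_id": t.tract_id,
                     **{f"frac_{g}": fr.get(g, 0.0) for g in "ABCD"},
                     "score": score, "category": categorize(score)})
    return pd.DataFrame(rows)


def score_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-category tract counts and percentage shares (one decimal)."""
    n = len(scores)
    counts = scores.category.value_counts()
    rows = [{"category": c, "n": int(counts.get(c, 0)),
             "share_pct": round(100.0 * counts.get(c, 0) / n, 1)}
            for c in CATEGORY_ORDER]
    return pd.DataFrame(rows)
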