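"""Data preparation for areal panels.

Implements the full preparation chain an area-level registry analysis
needs: postcode-to-area count allocation through a correspondence table,
location quotients for group concentration, indirectly standardised
expected counts, guideline-based exposure categorisation, lag features,
exposure-residual decorrelation of collinear pollutants, calendar-year
filtering, and aggregation to a coarser lattice (for modifiable-areal-unit
sensitivity checks).
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .lattice import AreaLattice
from .spatial import queen_contiguity

logger = logging.getLogger(__name__)

__all__ = [
    "read_correspondence",
    "allocate_postcode_counts",
    "location_quotient",
    "expected_counts",
    "categorize_exposures",
    "lag_features",
    "exposure_residual",
    "filter_years",
    "coarsen_lattice",
    "irsad_decile_to_quintile",
]

EXPOSURE_COLS = ["ndvi", "pm25", "no2", "lst"]


def read_correspondence(path: str) -> pd.DataFrame:
    """Read a postcode->area correspondence CSV (postcode, area, weight)."""
    df = pd.read_csv(path, dtype={"postcode": str, "area": str})
    _validate_correspondence(df)
    return df


def _validate_correspondence(corr: pd.DataFrame) -> None:
    sums = corr.groupby("postcode")["weight"].sum()
    bad = sums[(sums - 1.0).abs() > 1e-9]
    if len(bad):
        raise ValueError(f"correspondence weights do not sum to 1 for postcodes: {list(bad.index)}")
    if (corr["weight"] < 0).any() or (corr["weight"] > 1).any():
        raise ValueError("correspondence weights must lie in [0, 1]")


def allocate_postcode_counts(
    postcode_counts: Mapping[str, int],
    corr: pd.DataFrame,
    mode: str = "fractional",
    seed: int | None = None,
) -> pd.Series:
    """Allocate postcode-level counts to areas via correspondence weights.

    ``fractional`` distributes each count proportionally (real-valued,
    expected-value allocation); ``multinomial`` draws integer splits with
    the weights as probabilities.  The grand total is conserved exactly in
    both modes.
    """
    _validate_correspondence(corr)
    known = set(corr["postcode"])
    missing = sorted(set(postcode_counts) - known)
    if missing:
        raise KeyError(f"postcodes absent from correspondence table: {missing}")
    areas = sorted(corr["area"].unique())
    out = pd.Series(0.0, index=areas)
    grouped = {p: g for p, g in corr.groupby("postcode")}
    rng = np.random.default_rng(seed)
    for pc, count in postcode_counts.items():
        g = grouped[pc]
        if mode == "fractional":
            out[g["area"].to_numpy()] += count * g["weight"].to_numpy()
        elif mode == "multinomial":
            draws = rng.multinomial(int(count), g["weight"].to_numpy())
            out[g["area"].to_numpy()] += draws
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if mode == "multinomial":
        out = out.astype(int)
    return out


def location_quotient(
    group_count: pd.Series, total_count: pd.Series
) -> pd.DataFrame:
    """Location quotient per area and its high-concentration flag.

    LQ_a = (group_a / total_a) / (sum(group) / sum(total)); areas with a
    zero denominator get a missing LQ; LQ >= 1 flags high concentration.
    """
    group_count, total_count = group_count.align(total_count, join="inner")
    if ((total_count < group_count) | (group_count < 0)).any():
        raise ValueError("require 0 <= group_count <= total_count per area")
    g_tot, t_tot = float(group_count.sum()), float(total_count.sum())
    if g_tot <= 0:
        raise ValueError("reference proportion undefined: all group counts are zero")
    ref = g_tot / t_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        lq = (group_count / total_count) / ref
    lq[total_count == 0] = np.nan
    return pd.DataFrame({"lq": lq, "high": lq >= 1.0})


def expected_counts(panel: pd.DataFrame, per_year: bool = False) -> pd.DataFrame:
    """Indirectly standardised expected counts E_it = P_it * (sum Y / sum P).

    The reference rate pools the whole panel by default (the formula's
    subscripts run over areas and years jointly); ``per_year=True`` uses
    year-specific rates instead.  Either way sum(E) == sum(Y).
    """
    if panel[["cases", "births"]].isna().any().any():
        raise ValueError("cases and births must be present for all rows")
    out = panel.copy()
    if per_year:
        rate = panel.groupby("year").apply(
            lambda g: g["cases"].sum() / g["births"].sum(), include_groups=False
        )
        out["expected"] = out["births"] * out["year"].map(rate)
    else:
        tot_p = panel["births"].sum()
        if tot_p == 0:
            raise ValueError("total births is zero")
        out["expected"] = out["births"] * (panel["cases"].sum() / tot_p)
    return out


def categorize_exposures(panel: pd.DataFrame, tertile_interpolation: str = "linear") -> pd.DataFrame:
    """Categorise exposures with guideline cut-offs.

    Greenness: low (< 0.2), moderate [0.2, 0.6), high (>= 0.6); negative
    NDVI (water/sensor artefacts) is treated as missing.  Air pollution:
    high strictly above the 2021 WHO annual guideline values (5 ug/m3
    PM2.5, 10 ppb NO2).  Temperature: tertiles of the pooled panel
    distribution, tie interpolation configurable.
    """
    out = panel.copy()
    ndvi = out["ndvi"].where(out["ndvi"] >= 0)
    out["ndvi"] = ndvi
    gc = pd.Series(pd.NA, index=out.index, dtype="object")
    gc[ndvi < 0.2] = "low"
    gc[(ndvi >= 0.2) & (ndvi < 0.6)] = "moderate"
    gc[ndvi >= 0.6] = "high"
    out["greenness_class"] = gc
    out["pm25_class"] = np.where(out["pm25"] > 5.0, "high", "low")
    out["no2_class"] = np.where(out["no2"] > 10.0, "high", "low")
    q1, q2 = np.nanquantile(out["lst"], [1 / 3, 2 / 3], method=tertile_interpolation)
    tt = pd.Series(pd.NA, index=out.index, dtype="object")
    lst = out["lst"]
    tt[lst <= q1] = "T1"
    tt[(lst > q1) & (lst <= q2)] = "T2"
    tt[lst > q2] = "T3"
    out["temp_tertile"] = tt
    for c in ("pm25", "no2"):
        out.loc[out[c].isna(), f"{c}_class"] = pd.NA
    return out


def lag_features(panel: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Single-lag and moving-lag exposure features.

    ``lag1_x(t) = x(t-1)`` and ``lag0_x(t) = (x(t-1) + x(t)) / 2``; rows for
    the first panel year are dropped since their preceding year is
    unobserved.
    """
    columns = columns or [c for c in EXPOSURE_COLS if c in panel.columns]
    years = np.sort(panel["year"].unique())
    if len(years) < 2:
        raise ValueError("lag features need at least two years")
    if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
        raise ValueError("panel years must be contiguous")
    out = panel.sort_values(["area_id", "year"], kind="stable").copy()
    g = out.groupby("area_id", sort=False)
    for c in columns:
        prev = g[c].shift(1)
        out[f"lag1_{c}"] = prev
        out[f"lag0_{c}"] = (prev + out[c]) / 2.0
    return out[out["year"] > years[0]].reset_index(drop=True)


def exposure_residual(panel: pd.DataFrame, target: str, conditioning: str) -> pd.DataFrame:
    """Residualise one exposure on another (OLS with intercept).

    The residual column ``{target}_res`` is orthogonal to the conditioning
    exposure, giving a decorrelated stand-in for collinear pollutants.
    """
    x = panel[conditioning].to_numpy(dtype=float)
    y = panel[target].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete rows")
    if np.ptp(x[ok]) == 0:
        raise ValueError(f"conditioning column {conditioning!r} is constant")
    slope, intercept = np.polyfit(x[ok], y[ok], 1)
    out = panel.copy()
    res = np.full(len(panel), np.nan)
    res[ok] = y[ok] - (intercept + slope * x[ok])
    out[f"{target}_res"] = res
    return out


def filter_years(panel: pd.DataFrame, exclude: set[int]) -> pd.DataFrame:
    """Drop rows whose year falls in ``exclude`` (e.g. pandemic years)."""
    out = panel[~panel["year"].isin(exclude)].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("excluding all years leaves an empty panel")
    return out


def coarsen_lattice(
    panel: pd.DataFrame,
    lattice: AreaLattice,
    grouping: Mapping[str, str] | None = None,
    block: int = 2,
) -> tuple[pd.DataFrame, AreaLattice]:
    """Aggregate panel and lattice to super-areas (coarser spatial scale).

    Counts are summed; continuous exposures are births-weighted means; the
    super-area adjacency contains a pair whenever any member areas were
    adjacent.  Totals of cases and births are conserved exactly.  With no
    explicit grouping, grid lattices are grouped into ``block x block``
    tiles by geometry centroid.
    """
    if grouping is None:
        if lattice.geometries is None:
            raise ValueError("grouping required when the lattice has no geometries")
        grouping = {}
        for aid, geom in zip(lattice.area_ids, lattice.geometries):
            cx, cy = geom.centroid.x, geom.centroid.y
            grouping[aid] = f"B{int(cy // block):03d}_{int(cx // block):03d}"
    missing = set(lattice.area_ids) - set(grouping)
    if missing:
        raise ValueError(f"grouping does not cover areas: {sorted(missing)[:5]}")

    w = queen_contiguity(lattice)
    idx = lattice.index()
    members: dict[str, list[str]] = {}
    for aid in lattice.area_ids:
        members.setdefault(grouping[aid], []).append(aid)
    super_ids = sorted(members)

    # connectivity warning per super-area
    nbrs = w.neighbors()
    for sid, mem in members.items():
        mset = {idx[a] for a in mem}
        seen = {next(iter(mset))}
        stack = [next(iter(mset))]
        while stack:
            cur = stack.pop()
            for nb in nbrs[cur]:
                if nb in mset and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != mset:
            logger.warning("coarsen_lattice: super-area %s is disconnected", sid)

    df = panel.copy()
    df["_super"] = df["area_id"].map(grouping)
    wcols = [c for c in ["ndvi", "pm25", "no2", "lst", "migrant_lq", "median_age",
                         "pop_density", "ses_quintile"] if c in df.columns]

    def _agg(g: pd.DataFrame) -> pd.Series:
        bw = g["births"].to_numpy(dtype=float)
        row = {"cases": g["cases"].sum(), "births": g["births"].sum()}
        for c in wcols:
            row[c] = float(np.average(g[c], weights=bw))
        return pd.Series(row)

    agg = (
        df.groupby(["_super", "year"])
        .apply(_agg, include_groups=False)
        .reset_index()
        .rename(columns={"_super": "area_id"})
    )
    agg["cases"] = agg["cases"].astype(int)
    agg["births"] = agg["births"].astype(int)
    if "ses_quintile" in agg.columns:
        agg["ses_quintile"] = agg["ses_quintile"].round().clip(1, 5).astype(int)
    if "migrant_lq" in agg.columns:
        agg["migrant_high"] = agg["migrant_lq"] >= 1.0

    pair_set = set()
    inv = {aid: grouping[aid] for aid in lattice.area_ids}
    for a, b in w.pairs:
        sa, sb = inv[lattice.area_ids[a]], inv[lattice.area_ids[b]]
        if sa != sb:
            pair_set.add(tuple(sorted((sa, sb))))
    urb = []
    states = []
    for sid in super_ids:
        mem_ix = [idx[a] for a in members[sid]]
        urb.append(
            pd.Series([lattice.urbanicity[i] for i in mem_ix]).mode().iloc[0]
        )
        states.append(pd.Series([lattice.state_label[i] for i in mem_ix]).mode().iloc[0])
    geoms = None
    if lattice.geometries is not None:
        from shapely.ops import unary_union

        geoms = [
            unary_union([lattice.geometries[idx[a]] for a in members[sid]])
            for sid in super_ids
        ]
    coarse = AreaLattice(
        area_ids=super_ids,
        geometries=geoms,
        adjacency=sorted(pair_set),
        urbanicity=urb,
        state_label=states,
    )
    return agg, coarse


def irsad_decile_to_quintile(decile: pd.Series | np.ndarray) -> np.ndarray:
    """Recode socioeconomic-index deciles 1-10 to quintiles 1-5
    (deciles 1-2 -> quintile 1, ..., deciles 9-10 -> quintile 5)."""
    d = np.asarray(decile, dtype=float)
    if np.nanmin(d) < 1 or np.nanmax(d) > 10:
        raise ValueError("deciles must lie in 1..10")
    return np.ceil(d / 2.0).astype(int)
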