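"""Term language shared by the simulator and the fitted models.

Covariates are referenced by term names.  A term is either a raw panel
column, a derived quantity (e.g. ``ndvi_per01`` — greenness per 0.10 NDVI,
the reporting unit used throughout), a categorical expansion ``C(col)``
(dummy-coded against the first level), or an interaction ``a:b`` (the
element-wise product of the expanded columns of ``a`` and ``b``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_design", "term_columns"]

# reference-first level orders for known categoricals
_LEVEL_ORDERS = {
    "greenness_class": ["low", "moderate", "high"],
    "pm25_class": ["low", "high"],
    "no2_class": ["low", "high"],
    "temp_tertile": ["T1", "T2", "T3"],
    "ses_quintile": [1, 2, 3, 4, 5],
    "urbanicity": ["major_city", "regional"],
}

_DERIVED = {
    "ndvi_per01": lambda df: df["ndvi"] / 0.10,
    "pop_density_log": lambda df: np.log1p(df["pop_density"]),
    "pm25_high": lambda df: (df["pm25"] > 5.0).astype(float),
    "no2_high": lambda df: (df["no2"] > 10.0).astype(float),
    "ses_low": lambda df: (df["ses_quintile"] == 1).astype(float),
    "ses_high": lambda df: (df["ses_quintile"] == 5).astype(float),
    "regional": lambda df: (df["urbanicity"] == "regional").astype(float),
}


def _expand_single(panel: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    if term.startswith("C(") and term.endswith(")"):
        col = term[2:-1]
        levels = _LEVEL_ORDERS.get(col)
        vals = panel[col]
        if levels is None:
            levels = sorted(vals.dropna().unique().tolist())
        cols = []
        names = []
        for lv in levels[1:]:
            x = (vals == lv).astype(float).to_numpy()
            x[vals.isna().to_numpy()] = np.nan
            cols.append(x)
            names.append(f"{col}[{lv}]")
        return np.column_stack(cols), names
    if term in _DERIVED and term not in panel.columns:
        x = _DERIVED[term](panel).to_numpy(dtype=float)
        return x[:, None], [term]
    if term not in panel.columns:
        raise KeyError(f"unknown term {term!r}")
    x = panel[term]
    if x.dtype == bool:
        x = x.astype(float)
    return x.to_numpy(dtype=float)[:, None], [term]


def term_columns(panel: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    """Expand one term (possibly an interaction) to columns and names."""
    parts = term.split(":")
    x, names = _expand_single(panel, parts[0])
    for part in parts[1:]:
        x2, names2 = _expand_single(panel, part)
        cols, nm = [], []
        for i, na in enumerate(names):
            for j, nb in enumerate(names2):
                cols.append(x[:, i] * x2[:, j])
                nm.append(f"{na}:{nb}")
        x, names = np.column_stack(cols), nm
    return x, names


def build_design(panel: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Build an (n_rows, p) design matrix (no intercept column) and names."""
    blocks, names = [], []
    for term in terms:
        x, nm = term_columns(panel, term)
        blocks.append(x)
        names.extend(nm)
    if not blocks:
        return np.empty((len(panel), 0)), []
    x = np.column_stack(blocks)
    if len(set(names)) != len(names):
        raise ValueError("duplicate design columns")
    return x, names
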