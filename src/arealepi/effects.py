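"""Effect modification, E-values, and the sensitivity-analysis suite.

Effect modification is assessed by refitting the full model with product
terms (exposure x modifier) and summarising stratum-specific adjusted risk
ratios draw-wise: within each posterior draw the stratum log-RR is the sum
of the exposure main effect and the stratum's interaction coefficient, so
the reported CrIs are exact posterior functionals, not delta
approximations.

E-values quantify unmeasured confounding: the minimum risk-ratio strength
an unmeasured confounder would need with both exposure and outcome to
explain an observed association away (VanderWeele's closed form
RR* + sqrt(RR*(RR*-1)) with RR* the association moved above 1).
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import preprocess
from .model import ArealRiskModel, ArealRiskResults
from .spatial import ScaledICAR, queen_contiguity, scaled_icar

logger = logging.getLogger(__name__)

__all__ = [
    "EffectModificationResult",
    "EValueReport",
    "stratum_arr",
    "e_value",
    "SensitivityConfig",
    "SensitivityBundle",
    "run_sensitivity_suite",
]


@dataclass
class EffectModificationResult:
    exposure: str
    modifier: str
    reference: str
    table: pd.DataFrame  # stratum, arr, lo, hi, significant

    def __str__(self) -> str:
        return (
            f"Effect modification of {self.exposure} by {self.modifier} "
            f"(reference: {self.reference})\n{self.table}"
        )


def stratum_arr(
    fit: ArealRiskResults, exposure: str, modifier: str
) -> EffectModificationResult:
    """Stratum-specific ARRs from a model containing product terms.

    ``exposure`` is a design-column name (e.g. ``pm25_high``); ``modifier``
    a term (e.g. ``C(ses_quintile)`` or ``migrant_high``).  The reference
    stratum uses the exposure main effect alone; each non-reference stratum
    adds its interaction coefficient within every draw before
    exponentiating.
    """
    names = fit.model.exog_names
    if exposure not in names:
        raise KeyError(f"exposure column {exposure!r} not in the fitted model")
    mod_col = modifier[2:-1] if modifier.startswith("C(") else modifier
    inter = [
        nm for nm in names
        if nm.startswith(f"{exposure}:") and (mod_col in nm.split(":", 1)[1])
    ]
    if not inter:
        raise KeyError(
            f"no interaction draws for exposure {exposure!r} and modifier {modifier!r}"
        )
    base = fit.coef_draws(exposure)
    levels = [nm.split(":", 1)[1] for nm in inter]
    if modifier.startswith("C("):
        from .design import _LEVEL_ORDERS

        order = _LEVEL_ORDERS.get(mod_col)
        ref_label = f"{mod_col}[{order[0]}]" if order else f"{mod_col}[reference]"
    else:
        ref_label = f"{mod_col}=0"
    rows = [_summarise_rr(base, f"{ref_label} (ref)")]
    for nm, lv in zip(inter, levels):
        rows.append(_summarise_rr(base + fit.coef_draws(nm), lv))
    table = pd.DataFrame(rows).set_index("stratum")
    return EffectModificationResult(
        exposure=exposure, modifier=modifier, reference=ref_label, table=table
    )


def _summarise_rr(log_rr: np.ndarray, label: str) -> dict:
    rr = np.exp(log_rr)
    lo, hi = np.percentile(rr, [2.5, 97.5])
    return {
        "stratum": label,
        "arr": float(rr.mean()),
        "lo": float(lo),
        "hi": float(hi),
        "significant": bool(lo > 1.0 or hi < 1.0),
    }


# ---------------------------------------------------------------------------
# E-values
# ---------------------------------------------------------------------------

@dataclass
class EValueReport:
    arr: float
    ci_limit: float | None
    e_value_point: float
    e_value_ci: float | None


def _evalue_scalar(rr: float) -> float:
    rr_star = max(rr, 1.0 / rr)
    return rr_star + math.sqrt(rr_star * (rr_star - 1.0))


def e_value(arr: float, ci_low: float | None = None, ci_high: float | None = None) -> EValueReport:
    """E-value for a risk ratio and (optionally) its interval.

    The interval E-value uses the CI limit closer to the null after the
    reciprocal transform; an interval crossing 1 needs no confounding and
    reports 1.
    """
    if arr <= 0:
        raise ValueError("risk ratio must be positive")
    ev_point = _evalue_scalar(arr)
    if ci_low is None or ci_high is None:
        return EValueReport(arr=arr, ci_limit=None, e_value_point=ev_point, e_value_ci=None)
    if ci_low <= 0 or not (ci_low <= arr <= ci_high):
        raise ValueError("require 0 < ci_low <= arr <= ci_high")
    if ci_low <= 1.0 <= ci_high:
        return EValueReport(arr=arr, ci_limit=1.0, e_value_point=ev_point, e_value_ci=1.0)
    limit = ci_high if arr < 1.0 else ci_low  # the limit closer to 1
    return EValueReport(
        arr=arr, ci_limit=float(limit), e_value_point=ev_point,
        e_value_ci=_evalue_scalar(float(limit)),
    )


# ---------------------------------------------------------------------------
# Sensitivity suite
# ---------------------------------------------------------------------------

@dataclass
class SensitivityConfig:
    """Toggles for the six sensitivity analyses."""

    categorical_exposures: bool = False
    covid_exclusion: bool = False
    covid_years: tuple[int, ...] = (2020, 2021)
    exposure_residual: bool = False
    lags: bool = False
    e_values: bool = False
    maup: bool = False
    maup_block: int = 2


@dataclass
class SensitivityBundle:
    base: ArealRiskResults
    fits: dict[str, ArealRiskResults] = field(default_factory=dict)
    e_values: dict[str, EValueReport] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    table: pd.DataFrame | None = None
    coarse_lattice: object | None = None

    def to_dir(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        if self.coarse_lattice is not None:
            from .lattice import write_gal
            from .spatial import queen_contiguity as _qc

            nbrs = _qc(self.coarse_lattice).neighbors()
            ids = self.coarse_lattice.area_ids
            write_gal(
                ids,
                {a: [ids[j] for j in nbrs[i]] for i, a in enumerate(ids)},
                os.path.join(outdir, "coarse_adjacency.gal"),
            )
        index = {"analyses": ["base"] + sorted(self.fits), "errors": self.errors}
        self.base.arr().to_csv(os.path.join(outdir, "arr_base.csv"))
        for name, res in self.fits.items():
            res.arr().to_csv(os.path.join(outdir, f"arr_{name}.csv"))
        if self.table is not None:
            self.table.to_csv(os.path.join(outdir, "comparison.csv"), index=False)
        if self.e_values:
            with open(os.path.join(outdir, "e_values.json"), "w") as fh:
                json.dump(
                    {k: vars(v) for k, v in self.e_values.items()}, fh, indent=2
                )
        with open(os.path.join(outdir, "index.json"), "w") as fh:
            json.dump(index, fh, indent=2)


def run_sensitivity_suite(
    panel: pd.DataFrame,
    lattice,
    base_terms: Sequence[str],
    config: SensitivityConfig,
    icar: ScaledICAR | None = None,
    temporal: str = "linear",
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> SensitivityBundle:
    """Run the base model plus every enabled sensitivity analysis.

    Each sensitivity refits the same model family on a transformed input:
    WHO/vegetation-class categorical exposures, pandemic-year exclusion,
    pollutant residualisation, single (lag1) and moving (lag0) exposure
    lags, and coarse-scale aggregation (the modifiable-areal-unit check).
    E-values are computed from the base fit.  A failing analysis is
    recorded and the suite continues.
    """
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("seed", seed)
    if icar is None:
        icar = scaled_icar(queen_contiguity(lattice))
    area_ids = list(lattice.area_ids)

    def _fit(df: pd.DataFrame, terms: Sequence[str], icar_=None, areas=None, **kw):
        model = ArealRiskModel(
            df, terms, spatial="bym2", temporal=temporal,
            icar=icar_ or icar, area_ids=areas or area_ids,
        )
        return model.fit(**{**fit_kwargs, **kw})

    bundle = SensitivityBundle(base=_fit(panel, base_terms))
    rows = _arr_rows(bundle.base, "base")

    def _try(name: str, fn) -> None:
        try:
            res = fn()
            bundle.fits[name] = res
            rows.extend(_arr_rows(res, name))
        except Exception as exc:  # recorded, suite continues
            logger.warning("sensitivity %s failed: %s", name, exc)
            bundle.errors[name] = str(exc)

    if config.categorical_exposures:
        def _categorical():
            df = preprocess.categorize_exposures(panel)
            cat_terms = ["C(greenness_class)", "pm25_high", "no2_high", "C(temp_tertile)"]
            keep = [t for t in base_terms
                    if t not in ("ndvi_per01", "pm25", "no2", "lst")]
            return _fit(df, cat_terms + keep)
        _try("categorical", _categorical)

    if config.covid_exclusion:
        def _covid():
            df = preprocess.filter_years(panel, set(config.covid_years))
            df = preprocess.expected_counts(df)
            logger.info("COVID exclusion: %d rows over %d years",
                        len(df), df["year"].nunique())
            return _fit(df, base_terms)
        _try("covid_exclusion", _covid)

    if config.exposure_residual:
        def _residual():
            df = preprocess.exposure_residual(panel, "pm25", "no2")
            df = preprocess.exposure_residual(df, "no2", "pm25")
            terms = ["pm25_res", "no2_res"] + [
                t for t in base_terms if t not in ("pm25", "no2")
            ]
            return _fit(df, terms)
        _try("exposure_residual", _residual)

    if config.lags:
        def _lag(kind: str):
            df = preprocess.lag_features(panel)
            df = preprocess.expected_counts(df)
            remap = {"ndvi_per01": "ndvi", "pm25": "pm25", "no2": "no2", "lst": "lst"}
            terms = []
            for t in base_terms:
                src = remap.get(t)
                if src is not None:
                    lag_col = f"{kind}_{src}"
                    terms.append(f"{lag_col}_per01" if t == "ndvi_per01" else lag_col)
                    if t == "ndvi_per01":
                        df[f"{lag_col}_per01"] = df[lag_col] / 0.10
                else:
                    terms.append(t)
            return _fit(df, terms)
        _try("lag1", lambda: _lag("lag1"))
        _try("lag0", lambda: _lag("lag0"))

    if config.maup:
        def _maup():
            coarse_panel, coarse_lattice = preprocess.coarsen_lattice(
                panel, lattice, block=config.maup_block
            )
            coarse_panel = preprocess.expected_counts(coarse_panel)
            coarse_icar = scaled_icar(queen_contiguity(coarse_lattice))
            bundle.coarse_lattice = coarse_lattice
            return _fit(
                coarse_panel, base_terms, icar_=coarse_icar,
                areas=list(coarse_lattice.area_ids),
            )
        _try("maup", _maup)

    if config.e_values:
        arr_table = bundle.base.arr()
        for term, row in arr_table.iterrows():
            bundle.e_values[term] = e_value(row["arr"], row["lo"], row["hi"])

    bundle.table = pd.DataFrame(rows)
    return bundle


def _arr_rows(res: ArealRiskResults, analysis: str) -> list[dict]:
    out = []
    for term, row in res.arr().iterrows():
        out.append(
            {
                "analysis": analysis,
                "term": term,
                "arr": row["arr"],
                "lo": row["lo"],
                "hi": row["hi"],
            }
        )
    return out
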