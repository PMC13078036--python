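"""Bayesian areal count models: non-spatial GLMM and BYM2 spatiotemporal.

The model ladder shared by area-level disease-mapping analyses:

* ``NegBinGLMM`` — negative-binomial regression with IID area and IID year
  random effects (the non-spatial baseline);
* ``BYM2Model`` — the spatiotemporal model with a BYM2 combined spatial
  random effect (scaled-ICAR structured part with mixing fraction phi plus
  an IID part, one common SD) and either a linear trend in centred year or
  a first-order random-walk year effect.

Both observe cases Y_it with a log expected-count offset log E_it:

    log mu_it = log E_it + beta0 + X_it beta + b_i + delta * t_c   (linear)
    b_i = sigma * ( sqrt(1-phi) v_i + sqrt(phi) u*_i )

with u* the scaled ICAR field (sum-to-zero within components) and v IID
standard normal.  Estimation is full MCMC (NUTS) on the joint posterior;
results expose adjusted risk ratios exp(beta) with credible intervals,
WAIC/DIC for model comparison and convergence diagnostics.  Covariates are
standardised internally for sampling geometry and coefficient draws are
returned on the original covariate scale (an exact linear change of
variables, not an approximation).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from . import _loglik
from ._loglik import ParamLayout, logp_grad
from ._nuts import sample_nuts
from .design import build_design
from .spatial import ScaledICAR

logger = logging.getLogger(__name__)

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "ArealRiskModel",
    "NegBinGLMM",
    "BYM2Model",
    "ArealRiskResults",
    "ConvergenceError",
    "compare_models",
    "single_pollutant_fits",
    "ADJUSTMENT_TERMS",
]

_SPATIAL = {"none": 0, "iid_area": 1, "bym2": 2}
_TEMPORAL = {"none": 0, "iid_year": 1, "linear": 2, "rw1": 3}

#: sociodemographic adjustment set used by the single-pollutant models:
#: median age, migrant concentration, population density, neighbourhood SES
ADJUSTMENT_TERMS = ["median_age", "migrant_high", "pop_density_log", "C(ses_quintile)"]


class ConvergenceError(RuntimeError):
    """Raised when chains fail the R-hat threshold and the model is strict."""


@dataclass
class PriorConfig:
    """Hyperprior settings (penalised-complexity-style defaults).

    ``sigma_rate`` is the exponential rate for the combined random-effect
    SD, calibrated so P(SD > 1) = 0.01; ``phi_beta_b`` the second Beta
    shape for the mixing fraction, calibrated so P(phi < 0.5) = 2/3.
    """

    beta_sd: float = 5.0
    intercept_sd: float = 5.0
    delta_sd: float = 5.0
    sigma_rate: float = -math.log(0.01)  # P(sigma > 1) = 0.01
    sg_rate: float = -math.log(0.01)
    sd_rate: float = -math.log(0.01)
    phi_beta_b: float = math.log(3.0) / math.log(2.0)  # P(phi < 0.5) = 2/3
    r_shape: float = 2.0
    r_rate: float = 0.1


@dataclass
class ModelSpec:
    """Declarative model definition (mirrors the YAML config block)."""

    likelihood: str = "negative_binomial"
    fixed_effects: list[str] = dc_field(default_factory=lambda: ["ndvi_per01"])
    spatial: str = "bym2"
    temporal: str = "linear"
    area_slope: bool = False
    interactions: list[tuple[str, str]] = dc_field(default_factory=list)
    chains: int = 2
    draws: int = 500
    warmup: int = 500
    seed: int = 0
    target_accept: float = 0.8

    @property
    def terms(self) -> list[str]:
        out = list(self.fixed_effects)
        out += [f"{a}:{b}" for a, b in self.interactions]
        return out


class ArealRiskModel:
    """Areal count regression model (data + specification; fit() samples).

    Parameters
    ----------
    panel : DataFrame
        One row per (area_id, year) with ``cases``, ``expected`` and the
        covariate columns the terms refer to.
    terms : list of str
        Design terms (see :mod:`arealepi.design`): raw columns, derived
        names like ``ndvi_per01`` (greenness per 0.10 NDVI), categorical
        expansions ``C(col)`` and interactions ``a:b``.
    likelihood : {"negative_binomial", "poisson"}
    spatial : {"none", "iid_area", "bym2"}
    temporal : {"none", "iid_year", "linear", "rw1"}
    icar : ScaledICAR, required for spatial="bym2"
    area_ids : explicit area order (must match the ICAR construction order);
        defaults to sorted unique panel areas.
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        terms: Sequence[str],
        likelihood: str = "negative_binomial",
        spatial: str = "bym2",
        temporal: str = "linear",
        icar: ScaledICAR | None = None,
        area_ids: Sequence[str] | None = None,
        area_slope: bool = False,
        priors: PriorConfig | None = None,
    ) -> None:
        if spatial not in _SPATIAL:
            raise ValueError(f"unknown spatial structure {spatial!r}")
        if temporal not in _TEMPORAL:
            raise ValueError(f"unknown temporal structure {temporal!r}")
        if likelihood not in ("negative_binomial", "poisson"):
            raise ValueError(f"unknown likelihood {likelihood!r}")
        if spatial == "bym2":
            if icar is None:
                raise ValueError("spatial='bym2' requires a ScaledICAR (scaled precision)")
            if np.isnan(icar.scale).all() and icar.n_components:
                raise ValueError("ICAR precision is unscaled")
        self.terms = list(terms)
        self.likelihood = likelihood
        self.spatial = spatial
        self.temporal = temporal
        self.area_slope = bool(area_slope)
        self.icar = icar
        self.priors = priors or PriorConfig()

        df = panel.copy()
        x_raw, names = build_design(df, self.terms)
        keep = ~np.isnan(x_raw).any(axis=1)
        keep &= df["cases"].notna().to_numpy() & df["expected"].notna().to_numpy()
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d incomplete rows (complete-case analysis)", dropped)
        df = df.loc[keep].reset_index(drop=True)
        x_raw = x_raw[keep]
        if len(df) == 0:
            raise ValueError("no complete rows left")
        if (df["expected"] <= 0).any():
            raise ValueError("non-positive expected counts (offset must be positive)")
        for j, nm in enumerate(names):
            if np.ptp(x_raw[:, j]) == 0:
                raise ValueError(f"degenerate covariate with zero variance: {nm!r}")

        if area_ids is None:
            area_ids = sorted(df["area_id"].unique())
        self.area_ids = list(area_ids)
        if spatial == "bym2" and icar.n != len(self.area_ids):
            raise ValueError(
                f"ICAR built for {icar.n} areas but panel has {len(self.area_ids)}"
            )
        codes = pd.Categorical(df["area_id"], categories=self.area_ids).codes
        if (codes < 0).any():
            raise ValueError("panel contains areas missing from area_ids")

        years = np.sort(df["year"].unique())
        if temporal == "rw1" and len(years) < 3:
            raise ValueError("rw1 temporal structure needs at least 3 years")
        if temporal == "linear" and len(years) < 2:
            raise ValueError("linear temporal structure needs at least 2 years")

        self.panel = df
        self.exog_names = names
        self._x_mean = x_raw.mean(axis=0)
        self._x_scale = x_raw.std(axis=0, ddof=0)
        self._xs = np.ascontiguousarray((x_raw - self._x_mean) / self._x_scale)
        self._y = df["cases"].to_numpy(dtype=np.float64)
        self._log_e = np.log(df["expected"].to_numpy(dtype=np.float64))
        self._area = np.ascontiguousarray(codes, dtype=np.int64)
        self._years = years
        self._yearix = np.ascontiguousarray(
            np.searchsorted(years, df["year"].to_numpy()), dtype=np.int64
        )
        self._t_by_year = (years - years.mean()).astype(np.float64)

        self.n_areas = len(self.area_ids)
        self.n_years = len(years)
        self.nobs = len(df)
        self.layout = ParamLayout(
            p=len(names),
            n=self.n_areas,
            T=self.n_years,
            spatial=_SPATIAL[spatial],
            temporal=_TEMPORAL[temporal],
            area_slope=self.area_slope,
            use_nb=(likelihood == "negative_binomial"),
        )

        if spatial == "bym2":
            comp_of = icar.comp_labels.astype(np.int64).copy()
            sizes = np.bincount(comp_of, minlength=icar.n_components)
            # relabel non-singleton components compactly; islands get -1
            keep_comps = np.flatnonzero(sizes > 1)
            remap = -np.ones(icar.n_components, dtype=np.int64)
            remap[keep_comps] = np.arange(len(keep_comps))
            self._comp_of = remap[comp_of]
            self._comp_size = sizes[keep_comps].astype(np.float64)
            self._e_i = np.ascontiguousarray(icar.pairs[:, 0], dtype=np.int64)
            self._e_j = np.ascontiguousarray(icar.pairs[:, 1], dtype=np.int64)
            self._e_w = np.ascontiguousarray(icar.edge_scales(), dtype=np.float64)
        else:
            self._comp_of = np.zeros(self.n_areas, dtype=np.int64)
            self._comp_size = np.ones(1, dtype=np.float64)
            self._e_i = np.empty(0, dtype=np.int64)
            self._e_j = np.empty(0, dtype=np.int64)
            self._e_w = np.empty(0, dtype=np.float64)

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        panel: pd.DataFrame,
        terms: Sequence[str],
        lattice=None,
        **kwargs,
    ) -> "ArealRiskModel":
        """Build a model from a panel and (optionally) a lattice, deriving
        Queen contiguity and the scaled ICAR precision when needed."""
        if lattice is not None and kwargs.get("spatial", "bym2") == "bym2" and (
            kwargs.get("icar") is None
        ):
            from .spatial import queen_contiguity, scaled_icar

            kwargs["icar"] = scaled_icar(queen_contiguity(lattice))
            kwargs.setdefault("area_ids", list(lattice.area_ids))
        return cls(panel, terms, **kwargs)

    @classmethod
    def from_spec(cls, panel: pd.DataFrame, spec: ModelSpec, **kwargs) -> "ArealRiskModel":
        return cls(
            panel,
            spec.terms,
            likelihood=spec.likelihood,
            spatial=spec.spatial,
            temporal=spec.temporal,
            area_slope=spec.area_slope,
            **kwargs,
        )

    # -- log posterior -------------------------------------------------------

    def _logp_args(self, temper: float) -> tuple:
        lay, pr = self.layout, self.priors
        beta_sd = (pr.beta_sd * self._x_scale).astype(np.float64)
        return (
            self._y, self._log_e, self._xs, self._area, self._yearix, self._t_by_year,
            self._e_i, self._e_j, self._e_w, self._comp_of, self._comp_size,
            lay.n, lay.T, len(self._comp_size),
            lay.spatial, lay.temporal, lay.use_nb, lay.area_slope,
            lay.i_delta, lay.i_gamma, lay.i_lsg, lay.i_d, lay.i_lsd,
            lay.i_u, lay.i_v, lay.i_lphi, lay.i_lsig, lay.i_lr,
            beta_sd, pr.intercept_sd, pr.delta_sd, pr.sigma_rate, pr.sg_rate,
            pr.sd_rate, pr.phi_beta_b, pr.r_shape, pr.r_rate, float(temper),
        )

    def make_logp(self, temper: float = 1.0):
        """Return ``f(theta) -> (logp, grad)`` for the joint posterior."""
        args = self._logp_args(temper)
        dim = self.layout.dim

        def f(theta: np.ndarray) -> tuple[float, np.ndarray]:
            grad = np.empty(dim)
            lp = logp_grad(theta, grad, *args)
            return lp, grad

        return f

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        draws: int = 500,
        warmup: int = 500,
        chains: int = 2,
        seed: int = 0,
        target_accept: float = 0.8,
        on_unconverged: str | None = None,
        temper: float = 1.0,
        rhat_threshold: float = 1.05,
    ) -> "ArealRiskResults":
        """Sample the posterior with NUTS and return results.

        ``on_unconverged`` is ``"raise"`` (default for non-spatial models)
        or ``"flag"`` (default for BYM2): with ``"flag"`` the results are
        still returned, marked unconverged.
        """
        if on_unconverged is None:
            on_unconverged = "flag" if self.spatial == "bym2" else "raise"
        f = self.make_logp(temper=temper)
        seqs = np.random.SeedSequence(seed).spawn(chains)
        raw = np.empty((chains, draws, self.layout.dim))
        divergences = 0
        depths = []
        for c in range(chains):
            rng = np.random.default_rng(seqs[c])
            theta0 = self.layout.initial_point(rng)
            res = sample_nuts(
                f, theta0, warmup, draws, rng, target_accept=target_accept
            )
            raw[c] = res.draws
            divergences += int(res.divergent.sum())
            depths.append(res.tree_depth.mean())
        results = ArealRiskResults(self, raw, divergences=divergences, seed=seed)
        if results.rhat_max > rhat_threshold:
            msg = (
                f"chains not converged: max R-hat {results.rhat_max:.3f} > "
                f"{rhat_threshold} (divergences: {divergences})"
            )
            if on_unconverged == "raise":
                raise ConvergenceError(msg)
            logger.warning(msg)
            results.converged = False
        return results


class NegBinGLMM(ArealRiskModel):
    """Non-spatial negative-binomial GLMM: IID area + IID year effects."""

    def __init__(self, panel, terms, **kwargs):
        kwargs.setdefault("spatial", "iid_area")
        kwargs.setdefault("temporal", "iid_year")
        kwargs.setdefault("likelihood", "negative_binomial")
        super().__init__(panel, terms, **kwargs)


class BYM2Model(ArealRiskModel):
    """Spatiotemporal BYM2 model (linear trend by default; rw1 optional)."""

    def __init__(self, panel, terms, icar, **kwargs):
        kwargs.setdefault("spatial", "bym2")
        kwargs.setdefault("temporal", "linear")
        super().__init__(panel, terms, icar=icar, **kwargs)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

class ArealRiskResults:
    """Posterior summaries for a fitted areal risk model.

    Holds per-draw arrays for every reported parameter (original covariate
    scale), pointwise log-likelihoods, WAIC/DIC, and convergence
    diagnostics.  Draw arrays have shape (chains, draws) or
    (chains, draws, k).
    """

    def __init__(self, model: ArealRiskModel, raw: np.ndarray, divergences: int, seed: int):
        self.model = model
        self.raw = raw
        self.divergences = int(divergences)
        self.seed = int(seed)
        self.converged = True
        lay = model.layout
        c, s, _ = raw.shape
        self.n_chains, self.n_draws = c, s

        beta_std = raw[:, :, 1 : 1 + lay.p]
        scale = model._x_scale
        self.coef_draws_ = beta_std / scale  # original covariate scale
        self.intercept_draws_ = raw[:, :, 0] - beta_std @ (model._x_mean / scale)
        self.draws: dict[str, np.ndarray] = {"intercept": self.intercept_draws_}
        for j, nm in enumerate(model.exog_names):
            self.draws[nm] = self.coef_draws_[:, :, j]
        if lay.i_delta >= 0:
            self.draws["trend_per_year"] = raw[:, :, lay.i_delta]
        if lay.i_gamma >= 0:
            gam = raw[:, :, lay.i_gamma : lay.i_gamma + lay.T]
            gbar = gam.mean(axis=2, keepdims=True)
            self.draws["year_effect"] = gam - gbar  # exact sum-to-zero by projection
            self.draws["intercept"] = self.draws["intercept"] + gbar[:, :, 0]
            self.intercept_draws_ = self.draws["intercept"]
            self.draws["sd_year"] = np.exp(raw[:, :, lay.i_lsg])
        if lay.i_lsig >= 0:
            self.draws["sd_combined"] = np.exp(raw[:, :, lay.i_lsig])
        if lay.i_lphi >= 0:
            self.draws["phi"] = 1.0 / (1.0 + np.exp(-raw[:, :, lay.i_lphi]))
        if lay.i_lr >= 0:
            self.draws["nb_size"] = np.exp(raw[:, :, lay.i_lr])
        if lay.i_lsd >= 0:
            self.draws["sd_area_trend"] = np.exp(raw[:, :, lay.i_lsd])

        # spatial fields
        self._b_draws = self._compute_b(raw)
        if lay.spatial == _loglik.SPATIAL_BYM2:
            u = raw[:, :, lay.i_u : lay.i_u + lay.n].copy()
            comp = model._comp_of
            for cc in range(len(model._comp_size)):
                mask = comp == cc
                u[:, :, mask] -= u[:, :, mask].mean(axis=2, keepdims=True)
            u[:, :, comp < 0] = 0.0
            self.draws["u_star"] = u

        self._eta_draws = self._compute_eta(raw)
        self._loglik = self._pointwise_loglik()
        self._information_criteria()
        self._convergence()

    # -- linear predictor and likelihood ------------------------------------

    def _compute_b(self, raw: np.ndarray) -> np.ndarray:
        lay, m = self.model.layout, self.model
        c, s, _ = raw.shape
        if lay.spatial == _loglik.SPATIAL_NONE:
            return np.zeros((c, s, lay.n))
        sigma = np.exp(raw[:, :, lay.i_lsig])[:, :, None]
        if lay.spatial == _loglik.SPATIAL_IID:
            return sigma * raw[:, :, lay.i_u : lay.i_u + lay.n]
        u = raw[:, :, lay.i_u : lay.i_u + lay.n]
        v = raw[:, :, lay.i_v : lay.i_v + lay.n]
        phi = 1.0 / (1.0 + np.exp(-raw[:, :, lay.i_lphi]))[:, :, None]
        b = sigma * (np.sqrt(1 - phi) * v + np.sqrt(phi) * u)
        island = m._comp_of < 0
        if island.any():
            b[:, :, island] = (sigma * v)[:, :, island]
        return b

    def _compute_eta(self, raw: np.ndarray) -> np.ndarray:
        lay, m = self.model.layout, self.model
        c, s, _ = raw.shape
        flat = raw.reshape(c * s, -1)
        eta = m._log_e[None, :] + flat[:, [0]] + flat[:, 1 : 1 + lay.p] @ m._xs.T
        eta += self._b_draws.reshape(c * s, lay.n)[:, m._area]
        tc = m._t_by_year[m._yearix]
        if lay.i_delta >= 0:
            eta += flat[:, [lay.i_delta]] * tc[None, :]
        if lay.i_gamma >= 0:
            eta += flat[:, lay.i_gamma : lay.i_gamma + lay.T][:, m._yearix]
        if lay.i_d >= 0:
            sdd = np.exp(flat[:, [lay.i_lsd]])
            eta += sdd * flat[:, lay.i_d : lay.i_d + lay.n][:, m._area] * tc[None, :]
        return eta  # (chains*draws, nobs)

    def _pointwise_loglik(self) -> np.ndarray:
        y = self.model._y[None, :]
        eta = self._eta_draws
        mu = np.exp(eta)
        if self.model.likelihood == "negative_binomial":
            r = self.draws["nb_size"].reshape(-1, 1)
            return (
                gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                + r * (np.log(r) - np.log(r + mu))
                + y * (eta - np.log(r + mu))
            )
        return y * eta - mu - gammaln(y + 1)

    def _information_criteria(self) -> None:
        ll = self._loglik
        s = ll.shape[0]
        lppd = float(np.sum(logsumexp(ll, axis=0) - math.log(s)))
        p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
        self.lppd, self.p_waic = lppd, p_waic
        self.waic = -2.0 * (lppd - p_waic)
        dbar = float(np.mean(-2.0 * ll.sum(axis=1)))
        # plug-in deviance at the posterior mean of (eta, r)
        eta_hat = self._eta_draws.mean(axis=0)
        mu_hat = np.exp(eta_hat)
        y = self.model._y
        if self.model.likelihood == "negative_binomial":
            r_hat = float(self.draws["nb_size"].mean())
            ll_hat = float(
                np.sum(
                    gammaln(y + r_hat) - gammaln(r_hat) - gammaln(y + 1)
                    + r_hat * (np.log(r_hat) - np.log(r_hat + mu_hat))
                    + y * (eta_hat - np.log(r_hat + mu_hat))
                )
            )
        else:
            ll_hat = float(np.sum(y * eta_hat - mu_hat - gammaln(y + 1)))
        d_hat = -2.0 * ll_hat
        self.p_dic = dbar - d_hat
        self.dic = d_hat + 2.0 * self.p_dic

    def _convergence(self) -> None:
        import arviz as az

        rhats, esss = [], []
        for nm, arr in self.draws.items():
            if arr.ndim == 2:
                rhats.append(float(az.rhat(arr)))
                esss.append(float(az.ess(arr)))
        self.rhat_max = float(np.nanmax(rhats))
        self.ess_min = float(np.nanmin(esss))

    # -- accessors -----------------------------------------------------------

    def coef_draws(self, name: str) -> np.ndarray:
        """Flat (chains*draws,) draws of a named scalar parameter."""
        arr = self.draws[name]
        if arr.ndim != 2:
            raise ValueError(f"{name!r} is not a scalar parameter")
        return arr.reshape(-1)

    @property
    def params(self) -> pd.Series:
        return self.summary_frame()["mean"]

    def fitted_mean(self) -> np.ndarray:
        """Posterior mean of mu_it, aligned to the model's panel rows."""
        return np.exp(self._eta_draws).mean(axis=0)

    @property
    def loglik_draws(self) -> np.ndarray:
        """Pointwise log-likelihoods, shape (chains*draws, nobs)."""
        return self._loglik

    def data_key(self) -> str:
        df = self.model.panel
        h = hashlib.sha256()
        h.update(df["area_id"].astype(str).str.cat(sep=",").encode())
        h.update(df["year"].astype(str).str.cat(sep=",").encode())
        h.update(np.ascontiguousarray(self.model._y).tobytes())
        return h.hexdigest()

    # -- summaries -----------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        import arviz as az

        rows = []
        for nm, arr in self.draws.items():
            if arr.ndim != 2:
                continue
            flat = arr.reshape(-1)
            rows.append(
                {
                    "parameter": nm,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": np.percentile(flat, 2.5),
                    "median": np.percentile(flat, 50),
                    "q97.5": np.percentile(flat, 97.5),
                    "rhat": float(az.rhat(arr)),
                    "ess": float(az.ess(arr)),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def arr(self, terms: Sequence[str] | None = None) -> pd.DataFrame:
        """Adjusted risk ratios exp(beta) with 95% credible intervals."""
        terms = list(terms) if terms is not None else list(self.model.exog_names)
        rows = []
        for nm in terms:
            rr = np.exp(self.coef_draws(nm))
            rows.append(
                {
                    "term": nm,
                    "arr": rr.mean(),
                    "lo": np.percentile(rr, 2.5),
                    "hi": np.percentile(rr, 97.5),
                }
            )
        df = pd.DataFrame(rows).set_index("term")
        df["significant"] = (df["lo"] > 1.0) | (df["hi"] < 1.0)
        return df

    def summary(self) -> str:
        m = self.model
        lines = [
            "Areal risk model — posterior summary",
            "=" * 68,
            f"likelihood: {m.likelihood}   spatial: {m.spatial}   temporal: {m.temporal}",
            f"areas: {m.n_areas}   years: {m.n_years}   observations: {m.nobs}",
            f"chains: {self.n_chains} x {self.n_draws} draws   divergences: {self.divergences}",
            f"max R-hat: {self.rhat_max:.3f}   min ESS: {self.ess_min:.0f}"
            + ("" if self.converged else "   [NOT CONVERGED]"),
            f"WAIC: {self.waic:.1f} (p_waic {self.p_waic:.1f})   DIC: {self.dic:.1f} "
            f"(p_dic {self.p_dic:.1f})",
            "-" * 68,
        ]
        with pd.option_context("display.width", 110, "display.float_format", "{:.4f}".format):
            lines.append(str(self.summary_frame()))
            lines.append("-" * 68)
            lines.append("Adjusted risk ratios (exp(coef), 95% CrI):")
            lines.append(str(self.arr()))
        return "\n".join(lines)

    # -- diagnostics ---------------------------------------------------------

    def dispersion_test(self, n_sim: int = 250, seed: int | None = None):
        from .diagnostics import dispersion_test

        if self.model.likelihood != "poisson":
            raise ValueError("dispersion test applies to the Poisson fit")
        return dispersion_test(self.model._y, self.fitted_mean(), n_sim=n_sim, seed=seed)

    def zero_inflation_test(self, n_sim: int = 250, seed: int | None = None):
        from .diagnostics import zero_inflation_test

        r = float(self.draws["nb_size"].mean()) if "nb_size" in self.draws else None
        return zero_inflation_test(
            self.model._y, self.fitted_mean(), r=r, n_sim=n_sim, seed=seed
        )

    def stratum_arr(self, exposure: str, modifier: str):
        from .effects import stratum_arr

        return stratum_arr(self, exposure, modifier)

    def pearson_residuals(self, by_area: bool = False) -> np.ndarray:
        """Pearson residuals at the posterior mean (variance from the
        fitted likelihood); optionally averaged per area for Moran's I."""
        mu = self.fitted_mean()
        if self.model.likelihood == "negative_binomial":
            r = float(self.draws["nb_size"].mean())
            var = mu + mu * mu / r
        else:
            var = mu
        res = (self.model._y - mu) / np.sqrt(var)
        if not by_area:
            return res
        out = np.zeros(self.model.n_areas)
        cnt = np.zeros(self.model.n_areas)
        np.add.at(out, self.model._area, res)
        np.add.at(cnt, self.model._area, 1.0)
        return out / np.maximum(cnt, 1.0)

    def save(self, path: str) -> None:
        """Persist draws and metadata to an .npz archive."""
        payload = {f"draws/{k}": v for k, v in self.draws.items()}
        payload["meta/divergences"] = np.array([self.divergences])
        payload["meta/waic_dic"] = np.array([self.waic, self.dic, self.lppd, self.p_waic])
        payload["meta/rhat_ess"] = np.array([self.rhat_max, self.ess_min])
        np.savez_compressed(path, **payload)


# ---------------------------------------------------------------------------
# Model comparison and single-pollutant models
# ---------------------------------------------------------------------------

def compare_models(
    fits: Sequence[ArealRiskResults], names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Rank fitted models by WAIC (ascending), DIC alongside.

    All fits must be on identical data rows; a WAIC/DIC ranking
    disagreement is logged.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    keys = {f.data_key() for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were made on differing data rows")
    if names is None:
        names = [
            f"{f.model.spatial}/{f.model.temporal}/{f.model.likelihood}" for f in fits
        ]
    df = pd.DataFrame(
        {
            "model": list(names),
            "waic": [f.waic for f in fits],
            "dic": [f.dic for f in fits],
            "converged": [f.converged for f in fits],
        }
    ).sort_values("waic").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if not df["dic"].is_monotonic_increasing:
        logger.info("WAIC and DIC rankings disagree:\n%s", df)
    return df


def single_pollutant_fits(
    panel: pd.DataFrame,
    icar: ScaledICAR,
    area_ids: Sequence[str] | None = None,
    temporal: str = "linear",
    pollutants: tuple[str, str] = ("pm25", "no2"),
    extra_terms: Sequence[str] | None = None,
    fit_kwargs: dict | None = None,
) -> dict[str, ArealRiskResults]:
    """Fit one BYM2 model per pollutant (PM2.5 and NO2 are too collinear to
    enter jointly), each adjusted for greenness, temperature and the
    sociodemographic set."""
    fit_kwargs = dict(fit_kwargs or {})
    base = ["ndvi_per01", "lst"] + (list(extra_terms) if extra_terms else ADJUSTMENT_TERMS)
    out: dict[str, ArealRiskResults] = {}
    for pol in pollutants:
        terms = [pol] + [t for t in base if t != pol]
        model = ArealRiskModel(
            panel, terms, spatial="bym2", temporal=temporal, icar=icar, area_ids=area_ids
        )
        out[pol] = model.fit(**fit_kwargs)
        n_pol = sum(t in pollutants for t in terms)
        assert n_pol == 1, "single-pollutant fit must contain exactly one pollutant"
    return out
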