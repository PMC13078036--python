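"""Inference-engine contracts: offset behaviour, constraints, information
criteria, prior recovery, and the structural edge cases."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln, logsumexp
from scipy.stats import kstest

from arealepi import (
    ArealRiskModel,
    BYM2Model,
    NegBinGLMM,
    compare_models,
    expected_counts,
    single_pollutant_fits,
)

TERMS = ["ndvi_per01", "no2", "lst"]
FIT_KW = dict(draws=300, warmup=300, chains=2)


@pytest.fixture(scope="module")
def bym2_fit_small(sim_small):
    model = BYM2Model(
        sim_small.panel, TERMS, icar=sim_small.icar,
        area_ids=sim_small.lattice.area_ids,
    )
    return model.fit(seed=11, **FIT_KW)


class TestStructure:
    def test_posterior_intervals_ordered_and_arr_positive(self, bym2_fit_small):
        sf = bym2_fit_small.summary_frame()
        assert (sf["q2.5"] <= sf["median"]).all()
        assert (sf["median"] <= sf["q97.5"]).all()
        arr = bym2_fit_small.arr()
        assert (arr["arr"] > 0).all()

    def test_sum_to_zero_constraints_hold_on_draws(self, bym2_fit_small):
        u = bym2_fit_small.draws["u_star"]
        assert np.abs(u.sum(axis=2)).max() < 1e-6

    def test_year_effects_sum_to_zero_rw1(self, sim_small):
        model = BYM2Model(
            sim_small.panel, TERMS, icar=sim_small.icar,
            area_ids=sim_small.lattice.area_ids, temporal="rw1",
        )
        res = model.fit(seed=5, **FIT_KW)
        gam = res.draws["year_effect"]
        assert gam.shape[2] == 7
        assert np.abs(gam.sum(axis=2)).max() < 1e-6

    def test_single_year_panel_reduces_to_spatial_only(self, sim_small):
        one_year = sim_small.panel[sim_small.panel["year"] == 2019]
        one_year = expected_counts(one_year)
        model = ArealRiskModel(
            one_year, TERMS, spatial="bym2", temporal="none",
            icar=sim_small.icar, area_ids=sim_small.lattice.area_ids,
        )
        res = model.fit(seed=1, draws=200, warmup=200, chains=2)
        assert "trend_per_year" not in res.draws
        assert "year_effect" not in res.draws
        assert "u_star" in res.draws

    def test_rw1_needs_three_years(self, sim_small):
        two = sim_small.panel[sim_small.panel["year"].isin([2016, 2017])]
        with pytest.raises(ValueError, match="rw1"):
            ArealRiskModel(
                expected_counts(two), TERMS, spatial="bym2", temporal="rw1",
                icar=sim_small.icar, area_ids=sim_small.lattice.area_ids,
            )


class TestErrors:
    def test_nonpositive_offset_rejected(self, sim_small):
        panel = sim_small.panel.copy()
        panel.loc[panel.index[0], "expected"] = 0.0
        with pytest.raises(ValueError, match="offset"):
            NegBinGLMM(panel, TERMS)

    def test_degenerate_covariate_named_in_error(self, sim_small):
        panel = sim_small.panel.copy()
        panel["flatline"] = 1.0
        with pytest.raises(ValueError, match="flatline"):
            NegBinGLMM(panel, TERMS + ["flatline"])

    def test_bym2_requires_icar(self, sim_small):
        with pytest.raises(ValueError, match="ScaledICAR"):
            ArealRiskModel(sim_small.panel, TERMS, spatial="bym2")

    def test_mismatched_icar_size_rejected(self, sim_small, sim_medium):
        with pytest.raises(ValueError, match="areas"):
            ArealRiskModel(
                sim_medium.panel, TERMS, spatial="bym2", icar=sim_small.icar,
                area_ids=sim_medium.lattice.area_ids,
            )


class TestOffset:
    def test_scaling_expected_shifts_intercept_only(self, sim_small):
        """Multiplying all E by k shifts beta0 by -log k; ARRs unchanged
        (rate invariance of the offset formulation)."""
        k = 4.0
        base = NegBinGLMM(sim_small.panel, TERMS).fit(seed=21, **FIT_KW)
        scaled_panel = sim_small.panel.copy()
        scaled_panel["expected"] = scaled_panel["expected"] * k
        scaled = NegBinGLMM(scaled_panel, TERMS).fit(seed=21, **FIT_KW)
        a_int = base.coef_draws("intercept")
        b_int = scaled.coef_draws("intercept")
        d_int = b_int.mean() - a_int.mean()
        # intercept mixes slowly in the GLMM (it trades off against the
        # year-effect mean); judge the shift against its own MC error
        mc_se = math.hypot(a_int.std(), b_int.std()) / math.sqrt(50)
        assert d_int == pytest.approx(-math.log(k), abs=max(4 * mc_se, 0.05))
        for term in TERMS:
            a = base.coef_draws(term)
            b = scaled.coef_draws(term)
            mc_se = math.hypot(a.std() / math.sqrt(200), b.std() / math.sqrt(200))
            assert abs(a.mean() - b.mean()) < max(5 * mc_se, 0.02)


class TestInformationCriteria:
    def test_waic_matches_independent_formula(self, bym2_fit_small):
        """lppd - p_waic recomputed from saved pointwise log-likelihoods."""
        ll = bym2_fit_small.loglik_draws
        s = ll.shape[0]
        lppd = np.sum(logsumexp(ll, axis=0) - np.log(s))
        p_waic = np.sum(ll.var(axis=0, ddof=1))
        assert bym2_fit_small.waic == pytest.approx(-2 * (lppd - p_waic), abs=1e-8)

    def test_pointwise_loglik_matches_direct_nb_evaluation(self, bym2_fit_small):
        """Spot-check one draw against a direct NB pmf computation."""
        res = bym2_fit_small
        y = res.model._y
        eta = res._eta_draws[0]
        r = res.draws["nb_size"].reshape(-1)[0]
        mu = np.exp(eta)
        direct = (
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
        assert np.allclose(res.loglik_draws[0], direct, atol=1e-8)

    def test_same_seed_identical_waic(self, sim_small):
        a = NegBinGLMM(sim_small.panel, TERMS).fit(seed=33, **FIT_KW)
        b = NegBinGLMM(sim_small.panel, TERMS).fit(seed=33, **FIT_KW)
        assert a.waic == b.waic

    def test_compare_models_requires_same_rows(self, sim_small, bym2_fit_small):
        sub = expected_counts(sim_small.panel[sim_small.panel["year"] > 2016])
        other = NegBinGLMM(sub, TERMS).fit(
            seed=1, draws=150, warmup=150, on_unconverged="flag"
        )
        with pytest.raises(ValueError, match="differing"):
            compare_models([bym2_fit_small, other])


class TestPriorPredictive:
    def test_tempered_posterior_reproduces_phi_prior(self, sim_small):
        """With the likelihood switched off the sampler must return the
        prior: phi ~ Beta(1, log3/log2), checked by KS distance."""
        model = BYM2Model(
            sim_small.panel, ["ndvi_per01"], icar=sim_small.icar,
            area_ids=sim_small.lattice.area_ids,
        )
        res = model.fit(
            seed=8, draws=2000, warmup=500, chains=2, temper=0.0,
            on_unconverged="flag",
        )
        phi = res.coef_draws("phi")
        b = math.log(3) / math.log(2)
        ks = kstest(phi, lambda q: 1 - (1 - q) ** b)
        assert ks.statistic < 0.1

    def test_phi_prior_median_calibration(self):
        # P(phi < 0.5) = 2/3 under Beta(1, log3/log2)
        b = math.log(3) / math.log(2)
        assert 1 - 0.5**b == pytest.approx(2 / 3)


class TestNestedConsistency:
    def test_no_spatial_signal_matches_glmm(self):
        """sigma -> 0 truth: BYM2 shrinks its combined SD and the fixed
        effects agree with the non-spatial GLMM within Monte-Carlo error."""
        from arealepi import SyntheticTruth, simulate_panel

        truth = SyntheticTruth(sigma_spatial=1e-6, seed=77)
        sim = simulate_panel(n_side=5, truth=truth)
        panel = expected_counts(sim.panel)
        bym = BYM2Model(
            panel, TERMS, icar=sim.icar, area_ids=sim.lattice.area_ids
        ).fit(seed=2, **FIT_KW)
        glmm = NegBinGLMM(panel, TERMS, temporal="linear").fit(
            seed=2, on_unconverged="flag", **FIT_KW
        )
        assert np.percentile(bym.coef_draws("sd_combined"), 50) < 0.1
        for term in TERMS:
            a = bym.coef_draws(term)
            g = glmm.coef_draws(term)
            mc_se = math.hypot(a.std(), g.std())
            assert abs(a.mean() - g.mean()) < max(3 * mc_se, 0.02)


def test_permuted_covariate_interval_covers_null(sim_small):
    """Breaking the exposure-outcome link by permuting the covariate: the
    null ARR of 1 sits inside the 95% CrI in nearly all replicates."""
    rng = np.random.default_rng(123)
    covered = 0
    for rep in range(10):
        panel = sim_small.panel.copy()
        panel["ndvi"] = rng.permutation(panel["ndvi"].to_numpy())
        res = NegBinGLMM(panel, ["ndvi_per01", "no2"]).fit(
            seed=rep, on_unconverged="flag", **FIT_KW
        )
        row = res.arr(["ndvi_per01"]).iloc[0]
        covered += row["lo"] <= 1.0 <= row["hi"]
    assert covered >= 9


def test_single_pollutant_fits_contract(sim_small):
    fits = single_pollutant_fits(
        sim_small.panel, sim_small.icar, area_ids=sim_small.lattice.area_ids,
        fit_kwargs=dict(draws=150, warmup=200, chains=2, seed=4,
                        on_unconverged="flag"),
    )
    assert set(fits) == {"pm25", "no2"}
    for pol, res in fits.items():
        other = "no2" if pol == "pm25" else "pm25"
        assert pol in res.model.exog_names
        assert other not in res.model.exog_names
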