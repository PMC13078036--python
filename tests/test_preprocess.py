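"""Preparation-chain arithmetic: allocation, LQ, expected counts,
categorisation cut-offs, lags, residualisation, filtering, coarsening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from arealepi import (
    allocate_postcode_counts,
    categorize_exposures,
    coarsen_lattice,
    expected_counts,
    exposure_residual,
    filter_years,
    generate_lattice,
    irsad_decile_to_quintile,
    lag_features,
    location_quotient,
    queen_contiguity,
)


def _corr(rows):
    return pd.DataFrame(rows, columns=["postcode", "area", "weight"])


# ---------------------------------------------------------------------------
# Postcode allocation
# ---------------------------------------------------------------------------

class TestAllocation:
    def test_fractional_split_is_linear(self):
        corr = _corr([("P1", "A", 0.6), ("P1", "B", 0.4)])
        out = allocate_postcode_counts({"P1": 10}, corr)
        assert out["A"] == pytest.approx(6.0)
        assert out["B"] == pytest.approx(4.0)

    def test_whole_postcode_goes_to_single_area(self):
        corr = _corr([("P1", "A", 1.0), ("P2", "B", 1.0)])
        out = allocate_postcode_counts({"P1": 7, "P2": 3}, corr)
        assert out["A"] == 7 and out["B"] == 3

    def test_multinomial_mean_matches_binomial(self):
        corr = _corr([("P1", "A", 0.6), ("P1", "B", 0.4)])
        rng_seeds = range(10000)
        total = 0.0
        for s in rng_seeds:
            total += allocate_postcode_counts({"P1": 10}, corr, mode="multinomial", seed=s)["A"]
        assert abs(total / len(rng_seeds) - 6.0) < 0.1

    def test_totals_conserved_both_modes(self):
        corr = _corr([("P1", "A", 0.3), ("P1", "B", 0.7), ("P2", "B", 1.0)])
        counts = {"P1": 13, "P2": 8}
        frac = allocate_postcode_counts(counts, corr)
        multi = allocate_postcode_counts(counts, corr, mode="multinomial", seed=0)
        assert frac.sum() == pytest.approx(21.0, abs=1e-9)
        assert multi.sum() == 21

    def test_unknown_postcode_listed_in_error(self):
        corr = _corr([("P1", "A", 1.0)])
        with pytest.raises(KeyError, match="P9"):
            allocate_postcode_counts({"P1": 1, "P9": 2}, corr)

    def test_bad_weights_rejected(self):
        corr = _corr([("P1", "A", 0.5), ("P1", "B", 0.4)])
        with pytest.raises(ValueError, match="sum to 1"):
            allocate_postcode_counts({"P1": 1}, corr)


# ---------------------------------------------------------------------------
# Location quotient
# ---------------------------------------------------------------------------

class TestLocationQuotient:
    def test_quoted_ratio_arithmetic(self):
        out = location_quotient(
            pd.Series({"a": 20, "b": 80}), pd.Series({"a": 100, "b": 900})
        )
        assert out.loc["a", "lq"] == pytest.approx(2.0)
        assert bool(out.loc["a", "high"])

    def test_identical_composition_gives_unit_lq_everywhere(self):
        g = pd.Series({"a": 5, "b": 50, "c": 500})
        t = pd.Series({"a": 10, "b": 100, "c": 1000})
        out = location_quotient(g, t)
        assert np.allclose(out["lq"], 1.0)
        assert out["high"].all()  # LQ >= 1 rule is inclusive

    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 100)).filter(
                lambda gt: gt[0] <= gt[1]
            ),
            min_size=2,
            max_size=12,
        ).filter(lambda rows: sum(g for g, _ in rows) > 0)
    )
    def test_population_weighted_mean_is_one(self, rows):
        g = pd.Series([g for g, _ in rows])
        t = pd.Series([t for _, t in rows])
        out = location_quotient(g, t)
        w = t / t.sum()
        assert np.nansum(out["lq"] * w) == pytest.approx(1.0)

    def test_zero_total_area_gets_missing(self):
        out = location_quotient(pd.Series({"a": 2, "b": 0}), pd.Series({"a": 10, "b": 0}))
        assert np.isnan(out.loc["b", "lq"])

    def test_all_zero_group_rejected(self):
        with pytest.raises(ValueError):
            location_quotient(pd.Series({"a": 0}), pd.Series({"a": 10}))


# ---------------------------------------------------------------------------
# Expected counts
# ---------------------------------------------------------------------------

class TestExpectedCounts:
    def test_printed_formula_two_areas(self):
        panel = pd.DataFrame(
            {"area_id": ["a", "b"], "year": [2016, 2016],
             "cases": [15, 25], "births": [100, 300]}
        )
        out = expected_counts(panel)
        assert out["expected"].tolist() == pytest.approx([10.0, 30.0])

    def test_single_row_collapses_to_observed(self):
        panel = pd.DataFrame(
            {"area_id": ["a"], "year": [2016], "cases": [12], "births": [90]}
        )
        assert expected_counts(panel)["expected"].iloc[0] == pytest.approx(12.0)

    def test_conservation_identity(self, sim_medium):
        out = expected_counts(sim_medium.panel)
        assert out["expected"].sum() == pytest.approx(
            out["cases"].sum(), rel=1e-9
        )

    def test_per_year_option_conserves_within_each_year(self, sim_small):
        out = expected_counts(sim_small.panel, per_year=True)
        by_year = out.groupby("year")[["expected", "cases"]].sum()
        assert np.allclose(by_year["expected"], by_year["cases"])

    def test_zero_births_rejected(self):
        panel = pd.DataFrame(
            {"area_id": ["a"], "year": [2016], "cases": [0], "births": [0]}
        )
        with pytest.raises(ValueError):
            expected_counts(panel)


# ---------------------------------------------------------------------------
# Exposure categorisation
# ---------------------------------------------------------------------------

class TestCategorisation:
    @pytest.mark.parametrize(
        "ndvi,expected",
        [
            (0.39, "moderate"),  # the national median sits in the moderate band
            (0.19999, "low"),
            (0.2, "moderate"),  # boundary belongs to the closed-left interval
            (0.59999, "moderate"),
            (0.6, "high"),  # ">= 0.6" rule
            (0.95, "high"),
        ],
    )
    def test_greenness_boundaries(self, ndvi, expected):
        panel = pd.DataFrame(
            {"ndvi": [ndvi], "pm25": [5.0], "no2": [5.0], "lst": [20.0]}
        )
        assert categorize_exposures(panel)["greenness_class"].iloc[0] == expected

    def test_negative_ndvi_becomes_missing(self):
        panel = pd.DataFrame(
            {"ndvi": [-0.05], "pm25": [5.0], "no2": [5.0], "lst": [20.0]}
        )
        out = categorize_exposures(panel)
        assert pd.isna(out["greenness_class"].iloc[0])
        assert pd.isna(out["ndvi"].iloc[0])

    @pytest.mark.parametrize(
        "pm25,cls", [(7.64, "high"), (5.0, "low"), (5.0001, "high"), (4.2, "low")]
    )
    def test_pm25_who_cutoff_strictly_above(self, pm25, cls):
        panel = pd.DataFrame({"ndvi": [0.4], "pm25": [pm25], "no2": [5.0], "lst": [20.0]})
        assert categorize_exposures(panel)["pm25_class"].iloc[0] == cls

    @pytest.mark.parametrize(
        "no2,cls", [(5.92, "low"), (10.0, "low"), (10.0001, "high"), (14.0, "high")]
    )
    def test_no2_who_cutoff_strictly_above(self, no2, cls):
        panel = pd.DataFrame({"ndvi": [0.4], "pm25": [5.0], "no2": [no2], "lst": [20.0]})
        assert categorize_exposures(panel)["no2_class"].iloc[0] == cls

    def test_temperature_tertiles_balanced(self, sim_small):
        out = categorize_exposures(sim_small.panel)
        counts = out["temp_tertile"].value_counts()
        assert set(counts.index) == {"T1", "T2", "T3"}
        assert counts.max() - counts.min() <= 2


# ---------------------------------------------------------------------------
# Lags
# ---------------------------------------------------------------------------

class TestLags:
    def test_single_and_moving_lag_definitions(self):
        panel = pd.DataFrame(
            {"area_id": ["a", "a"], "year": [2016, 2017],
             "ndvi": [4.0, 6.0], "cases": [1, 1], "births": [10, 10]}
        )
        out = lag_features(panel, columns=["ndvi"])
        assert len(out) == 1  # first year dropped
        assert out["lag1_ndvi"].iloc[0] == 4.0
        assert out["lag0_ndvi"].iloc[0] == 5.0

    def test_constant_series_lags_equal_value(self):
        panel = pd.DataFrame(
            {"area_id": ["a"] * 4, "year": [2016, 2017, 2018, 2019],
             "ndvi": [0.3] * 4}
        )
        out = lag_features(panel, columns=["ndvi"])
        assert (out["lag1_ndvi"] == 0.3).all()
        assert (out["lag0_ndvi"] == 0.3).all()

    def test_seven_year_panel_keeps_six(self, sim_small):
        out = lag_features(sim_small.panel)
        assert out["year"].nunique() == 6
        assert len(out) == sim_small.lattice.n * 6

    def test_single_year_rejected(self):
        panel = pd.DataFrame({"area_id": ["a"], "year": [2016], "ndvi": [0.3]})
        with pytest.raises(ValueError):
            lag_features(panel, columns=["ndvi"])


# ---------------------------------------------------------------------------
# Exposure residualisation
# ---------------------------------------------------------------------------

class TestExposureResidual:
    def test_residual_orthogonal_to_conditioning(self, sim_small):
        out = exposure_residual(sim_small.panel, "pm25", "no2")
        corr = np.corrcoef(out["pm25_res"], out["no2"])[0, 1]
        assert abs(corr) < 1e-8

    def test_self_residual_is_zero(self, sim_small):
        panel = sim_small.panel.copy()
        panel["pm25_copy"] = panel["pm25"]
        out = exposure_residual(panel, "pm25_copy", "pm25")
        assert np.allclose(out["pm25_copy_res"], 0.0, atol=1e-10)

    def test_orthogonal_noise_recovered_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        eps = rng.standard_normal(200)
        # construct noise exactly orthogonal to the span of [1, x]
        basis = np.column_stack([np.ones(200), x])
        coef, *_ = np.linalg.lstsq(basis, eps, rcond=None)
        eps = eps - basis @ coef
        panel = pd.DataFrame({"cond": x, "target": 2.0 * x + eps})
        out = exposure_residual(panel, "target", "cond")
        assert np.allclose(out["target_res"], eps, atol=1e-8)

    def test_constant_conditioning_rejected(self):
        panel = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="constant"):
            exposure_residual(panel, "a", "b")


# ---------------------------------------------------------------------------
# Year filtering
# ---------------------------------------------------------------------------

class TestFilterYears:
    def test_pandemic_exclusion_keeps_five_years(self, sim_small):
        out = filter_years(sim_small.panel, {2020, 2021})
        assert out["year"].nunique() == 5
        assert len(out) == sim_small.lattice.n * 5

    def test_empty_exclusion_is_identity(self, sim_small):
        out = filter_years(sim_small.panel, set())
        pd.testing.assert_frame_equal(out, sim_small.panel.reset_index(drop=True))

    def test_excluding_everything_rejected(self, sim_small):
        with pytest.raises(ValueError):
            filter_years(sim_small.panel, set(range(2000, 2040)))


# ---------------------------------------------------------------------------
# Coarsening (modifiable areal unit)
# ---------------------------------------------------------------------------

class TestCoarsen:
    def test_single_superarea_total_conservation(self, sim_small):
        grouping = {a: "ALL" for a in sim_small.lattice.area_ids}
        agg, coarse = coarsen_lattice(sim_small.panel, sim_small.lattice, grouping)
        assert coarse.n == 1
        assert len(agg) == 7
        assert agg["cases"].sum() == sim_small.panel["cases"].sum()
        assert agg["births"].sum() == sim_small.panel["births"].sum()

    def test_identity_grouping_preserves_counts(self, sim_small):
        grouping = {a: a for a in sim_small.lattice.area_ids}
        agg, coarse = coarsen_lattice(sim_small.panel, sim_small.lattice, grouping)
        assert coarse.n == sim_small.lattice.n
        merged = agg.merge(
            sim_small.panel, on=["area_id", "year"], suffixes=("_agg", "")
        )
        assert (merged["cases_agg"] == merged["cases"]).all()
        assert np.allclose(merged["ndvi_agg"], merged["ndvi"])

    def test_2x2_blocks_on_4x4_grid_adjacency_by_member_pairs(self, sim_small):
        lat = generate_lattice(4)
        sim4 = {a: a for a in lat.area_ids}
        panel = sim_small.panel[sim_small.panel["area_id"].isin(lat.area_ids)]
        # default centroid blocking: 4 super-areas in a 2x2 layout
        agg, coarse = coarsen_lattice(panel, lat, block=2)
        assert coarse.n == 4
        # brute-force member-pair rule
        w_fine = queen_contiguity(lat)
        grouping = {}
        for aid, geom in zip(lat.area_ids, lat.geometries):
            grouping[aid] = f"B{int(geom.centroid.y // 2):03d}_{int(geom.centroid.x // 2):03d}"
        expected = set()
        for i, j in w_fine.pairs:
            sa, sb = grouping[lat.area_ids[i]], grouping[lat.area_ids[j]]
            if sa != sb:
                expected.add(tuple(sorted((sa, sb))))
        assert set(map(tuple, coarse.adjacency)) == expected
        assert len(expected) == 6  # all four blocks mutually adjacent

    def test_incomplete_grouping_rejected(self, sim_small):
        grouping = {a: "S" for a in sim_small.lattice.area_ids[:-1]}
        with pytest.raises(ValueError, match="cover"):
            coarsen_lattice(sim_small.panel, sim_small.lattice, grouping)


def test_irsad_recode_deciles_to_quintiles():
    deciles = np.arange(1, 11)
    out = irsad_decile_to_quintile(pd.Series(deciles))
    assert out.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
    with pytest.raises(ValueError):
        irsad_decile_to_quintile(np.array([0]))
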