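"""Transect analysis: tallies, summaries and the weighted loess trend."""

import numpy as np
import pandas as pd
import pytest

from coversad import (
    FitOptions,
    GradientConfig,
    fit_transect,
    parameter_trend,
    richness_cover_summary,
    selection_tally,
    simulate_transect,
)


@pytest.fixture(scope="module")
def weibull_constant_results():
    """Transect with constant Weibull truth (shape 1.5, scale 0.08)."""
    cfg = GradientConfig(
        model="weibull",
        theta=lambda e: np.array([1.5, 0.08]),
        richness=lambda e: 40,
        seed=0,
    )
    table = simulate_transect(cfg)
    return table, fit_transect(table, models=["weibull"])


class TestFitTransect:
    def test_single_plot_transect(self):
        table = simulate_transect(GradientConfig(seed=1)).query("plot_id == 'E2000_P1'")
        res = fit_transect(table)
        assert set(res.comparisons) == {"E2000_P1"}
        tally = selection_tally(res)
        assert tally.loc["total"].sum() == len(
            res.comparisons["E2000_P1"].plausible_set()
        )

    def test_exponential_truth_tallies_exponential_first(self):
        table = simulate_transect(GradientConfig(seed=0))
        res = fit_transect(table)
        tally = selection_tally(res)
        totals = tally.loc["total"]
        assert totals.idxmax() == "exponential"
        assert res.failures == {}

    def test_tally_cells_bounded_by_plots_per_belt(self):
        table = simulate_transect(GradientConfig(seed=2))
        res = fit_transect(table)
        tally = selection_tally(res).drop(index=["total", "fraction"])
        plots_per_belt = (
            table.groupby("elevation_m")["plot_id"].nunique().sort_index()
        )
        for elev, row in tally.iterrows():
            assert row.max() <= plots_per_belt.loc[float(elev)]
        # grand total per model equals the number of plots where plausible
        recomputed = dict.fromkeys(tally.columns, 0)
        for cmp in res.comparisons.values():
            for m in cmp.plausible_set():
                recomputed[m] += 1
        tot = selection_tally(res).loc["total"]
        assert all(tot[m] == recomputed[m] for m in recomputed)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            fit_transect(pd.DataFrame(columns=["plot_id", "elevation_m", "species_id", "cover"]))


class TestRichnessCoverSummary:
    def test_hand_computed_belt(self):
        rows = []
        for pid, n in [("p1", 10), ("p2", 20), ("p3", 30)]:
            for j in range(n):
                rows.append({"plot_id": pid, "elevation_m": 3000.0,
                             "species_id": f"s{j}", "cover": 0.02})
        out = richness_cover_summary(pd.DataFrame(rows))
        assert out.loc[3000.0, "richness_mean"] == 20
        assert out.loc[3000.0, "richness_min"] == 10
        assert out.loc[3000.0, "richness_max"] == 30

    def test_mean_within_min_max_everywhere(self):
        table = simulate_transect(GradientConfig(seed=3))
        out = richness_cover_summary(table)
        assert (out["richness_min"] <= out["richness_mean"]).all()
        assert (out["richness_mean"] <= out["richness_max"]).all()


class TestParameterTrend:
    def test_constant_truth_recovered_within_two_se(self, weibull_constant_results):
        _, res = weibull_constant_results
        trend = parameter_trend(res, "weibull", "shape")
        ok = np.isfinite(trend.value)
        assert ok.all()
        assert np.all(np.abs(trend.value[ok] - 1.5) <= 2 * trend.se[ok])

    def test_grid_sorted_and_positive_weights(self, weibull_constant_results):
        _, res = weibull_constant_results
        trend = parameter_trend(res, "weibull", "scale")
        assert np.all(np.diff(trend.grid) > 0)
        assert np.all(trend.weights > 0)

    def test_unimodal_shape_peak_recovered(self):
        cfg = GradientConfig(
            model="weibull",
            theta=lambda e: np.array([1.2 + 0.8 * np.exp(-(((e - 3500) / 400) ** 2)), 0.08]),
            richness=lambda e: 60,
            seed=0,
        )
        res = fit_transect(simulate_transect(cfg), models=["weibull"])
        trend = parameter_trend(res, "weibull", "shape", span=0.5)
        peak = trend.grid[np.nanargmax(trend.value)]
        assert abs(peak - 3500) <= 300

    def test_huge_se_plot_is_effectively_omitted(self, weibull_constant_results):
        _, res = weibull_constant_results
        base = parameter_trend(res, "weibull", "shape")
        # blow up one plot's SE: weight -> ~0, trend must barely move
        victim = next(iter(res.comparisons))
        fit = res.comparisons[victim].fits["weibull"]
        orig = fit.se.copy()
        fit.se = np.array([1e6, orig[1]])
        try:
            inflated = parameter_trend(res, "weibull", "shape")
        finally:
            fit.se = orig
        import copy
        res2 = copy.deepcopy(res)
        del res2.comparisons[victim]
        omitted = parameter_trend(res2, "weibull", "shape")
        assert np.nanmax(np.abs(inflated.value - omitted.value)) <= 1e-4

    def test_invariance_to_plot_order_and_se_rescaling(self, weibull_constant_results):
        _, res = weibull_constant_results
        base = parameter_trend(res, "weibull", "shape")
        reordered = type(res)(
            comparisons=dict(reversed(list(res.comparisons.items()))),
            meta=res.meta, scale=res.scale, failures=res.failures,
        )
        perm = parameter_trend(reordered, "weibull", "shape")
        assert np.allclose(base.value, perm.value, atol=1e-10)
        import copy
        scaled = copy.deepcopy(res)
        for cmp in scaled.comparisons.values():
            cmp.fits["weibull"].se = cmp.fits["weibull"].se * 7.0
        resc = parameter_trend(scaled, "weibull", "shape")
        assert np.allclose(base.value, resc.value, atol=1e-10)
        assert np.allclose(base.se, resc.se, atol=1e-10)

    def test_too_few_usable_fits_raises_with_count(self):
        cfg = GradientConfig(
            belt_elevations=(2000.0, 2100.0),
            top_belt_plots=3,
            model="weibull",
            theta=lambda e: np.array([1.5, 0.08]),
            richness=lambda e: 30,
            seed=0,
        )
        res = fit_transect(simulate_transect(cfg), models=["weibull"])
        # only keep 2 plots
        for pid in list(res.comparisons)[2:]:
            del res.comparisons[pid]
        with pytest.raises(ValueError, match="got 2"):
            parameter_trend(res, "weibull", "shape")

    def test_unknown_parameter_raises(self, weibull_constant_results):
        _, res = weibull_constant_results
        with pytest.raises(KeyError, match="no parameter"):
            parameter_trend(res, "weibull", "rate")
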