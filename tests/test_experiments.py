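"""Parameter studies: sampling, mean/CV, energy sweeps, knee, maintenance."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ultrasens import (
    EnergyConvention,
    EnergySweep,
    MWCParameters,
    curve_from_params,
    decreasing_proportion,
    energy_sweep,
    hill_goldbeter_koshland,
    hill_heatmap,
    knee,
    maintenance_sweep,
    mean_cv_experiment,
    optimal_site_number,
    sample_activation_parameters,
)


class TestSampling:
    def test_deterministic_given_seed(self):
        a = sample_activation_parameters(4, 1e-4, 0.9, 50, seed=42)
        b = sample_activation_parameters(4, 1e-4, 0.9, 50, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_support(self):
        draws = sample_activation_parameters(3, 1e-4, 0.9, 1000, seed=0)
        assert draws.min() >= 1e-4 and draws.max() <= 0.9

    def test_log_uniform_distribution(self):
        draws = sample_activation_parameters(1, 1e-4, 0.9, 100_000, seed=1).ravel()
        ks = stats.kstest(np.log(draws),
                          stats.uniform(np.log(1e-4), np.log(0.9) - np.log(1e-4)).cdf)
        assert ks.statistic < 0.01

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            sample_activation_parameters(2, 0.9, 1e-4, 10, seed=0)


class TestMeanCV:
    def test_zero_cv_draw_equals_mean_surrogate(self):
        df = mean_cv_experiment("mwc", [4], 0.01, 0.0100001, 3, seed=5, L=1000.0)
        # essentially equal sites: H and H_at_mean coincide to solver precision
        sub = df[df["defined"]]
        assert len(sub)
        assert np.allclose(sub["H"], sub["H_at_mean"], atol=1e-6)

    def test_mwc_hill_depends_on_mean_not_spread(self):
        df = mean_cv_experiment("mwc", [6], 1e-4, 0.9, 500, seed=7, L=1000.0)
        per_draw = df.drop_duplicates(["n", "draw"])
        strong = per_draw[(per_draw["mean"] < 1e-2) & per_draw["defined"]]
        assert len(strong) >= 5
        gaps = (strong["H"] - strong["H_at_mean"]).abs()
        assert gaps.quantile(0.95) < 0.1

    def test_independent_hill_depends_on_spread(self):
        # same mean contribution, very different variability
        from ultrasens import IndependentParameters
        even = IndependentParameters.uniform(3, 1000.0, d=1000.0)
        skew = IndependentParameters(n=3, v=(10.0, 10.0, 2980.0), k=(1, 1, 1),
                                     d=1000.0)
        h_even = hill_goldbeter_koshland(curve_from_params(even)).H
        h_skew = hill_goldbeter_koshland(curve_from_params(skew)).H
        assert abs(h_even - h_skew) > 0.1

    def test_undefined_rows_flagged_not_dropped(self):
        # weak activation near c=0.9 makes H undefined at L=1000 for n=2
        df = mean_cv_experiment("mwc", [2], 0.7, 0.9, 20, seed=3, L=1000.0)
        assert (~df["defined"]).any()
        assert len(df) == 20 * 2   # one row per draw and site, nothing dropped


class TestEnergySweep:
    def test_rows_sorted_with_strictly_increasing_energy(self):
        sw = energy_sweep(3, 1000.0, points=120)
        dg = sw.rows["dG_tot"].to_numpy()
        assert np.all(np.diff(dg) > 0)
        cs = sw.rows["c"].to_numpy()
        assert np.all(np.diff(cs) > 0)

    def test_reference_point_n3(self):
        conv = EnergyConvention()
        sw = energy_sweep(3, 1000.0, points=150)
        i = (sw.rows["c"] - 0.01).abs().idxmin()
        row = sw.rows.loc[i]
        assert row["dG_tot"] == pytest.approx(3 * conv.rt * math.log(row["c"]), rel=1e-12)
        est = hill_goldbeter_koshland(
            curve_from_params(MWCParameters.uniform(3, 0.01, L=1000.0)))
        assert est.H == pytest.approx(2.40, abs=0.005)

    def test_two_site_plateau_at_strong_activation(self):
        sw = energy_sweep(2, 1000.0, points=150)
        assert sw.rows["H"].iloc[0] == pytest.approx(1.92, abs=0.01)

    def test_weakest_activation_minimizes_H_and_H_nonincreasing_in_c(self):
        sw = energy_sweep(4, 1000.0, points=150)
        h = sw.rows["H"].to_numpy()
        assert h[-1] == pytest.approx(h.min(), abs=1e-9)
        assert np.all(np.diff(h) < 1e-9)


class TestKnee:
    @pytest.mark.parametrize("n,expected", [(2, 1.80), (8, 4.21)])
    def test_reference_knee_hill_values(self, n, expected):
        kn = knee(energy_sweep(n, 1000.0, points=1000))
        assert kn.knee_H == pytest.approx(expected, abs=0.05)
        assert kn.per_site_energy == pytest.approx(kn.knee_energy / n, rel=1e-12)

    def test_invariant_under_temperature_convention(self):
        cold = knee(energy_sweep(3, 1000.0, points=400,
                                 convention=EnergyConvention(t=280.0)))
        hot = knee(energy_sweep(3, 1000.0, points=400,
                                convention=EnergyConvention(t=320.0)))
        assert cold.knee_H == pytest.approx(hot.knee_H, abs=1e-12)
        # energies scale with rt
        assert cold.knee_energy / 280.0 == pytest.approx(
            hot.knee_energy / 320.0, rel=1e-12)

    def test_affine_curve_is_degenerate(self):
        e = np.linspace(-10, -1, 120)
        rows = pd.DataFrame({"c": np.exp(e), "dG_tot": e, "H": 2.0 * e + 30.0,
                             "defined": True})
        kn = knee(EnergySweep(rows=rows, n=2, L=1000.0,
                              convention=EnergyConvention()))
        assert kn.degenerate
        assert kn.secant_deviation < 1e-9

    def test_needs_enough_defined_rows(self):
        rows = pd.DataFrame({"c": [0.1, 0.2], "dG_tot": [-2.0, -1.0],
                             "H": [2.0, 1.5], "defined": [True, True]})
        with pytest.raises(ValueError, match="at least 3"):
            knee(EnergySweep(rows=rows, n=2, L=1000.0,
                             convention=EnergyConvention()))


class TestMaintenance:
    def test_zero_cost_reduces_to_plain_sweep(self):
        df = maintenance_sweep([3], 1000.0, 0.0, points=120)
        sw = energy_sweep(3, 1000.0, points=120)
        np.testing.assert_allclose(df["adjusted_energy"], sw.rows["dG_tot"])
        np.testing.assert_allclose(df["H"], sw.rows["H"])

    def test_optimal_site_count_at_reference_budget(self):
        opt = optimal_site_number([2, 3, 4, 6, 8], 1000.0, 4.0, -20.0)
        best = opt[opt["optimal"]]
        assert int(best["n"].iloc[0]) == 3
        # too many sites cannot even pay their upkeep from the budget
        assert not opt[opt["n"] >= 6]["feasible"].any()

    def test_optimal_n_nonincreasing_in_maintenance_cost(self):
        budget = -20.0
        opts = []
        for mc in (2.0, 4.0, 8.0):
            opt = optimal_site_number([2, 3, 4, 6, 8], 1000.0, mc, budget)
            opts.append(int(opt[opt["optimal"]]["n"].iloc[0]))
        assert opts == sorted(opts, reverse=True)


class TestHeatmap:
    def test_mwc_hill_rises_toward_strong_activation(self):
        hm = hill_heatmap("mwc", (1e-4, 0.9), (1e-4, 0.9), grid_size=10,
                          n=2, L=1000.0)
        assert hm.H[0, 0] > hm.H[6, 6]
        assert hm.defined[0, 0]

    def test_mwc_undefined_cells_masked(self):
        hm = hill_heatmap("mwc", (1e-4, 0.9), (1e-4, 0.9), grid_size=10,
                          n=2, L=1000.0)
        assert (~hm.defined).any()          # weak-activation corner
        assert np.isnan(hm.H[~hm.defined]).all()

    def test_fixed_sites_make_grid_consistent_with_single_point(self):
        hm = hill_heatmap("mwc", (0.01, 0.9), (0.01, 0.9), grid_size=10,
                          n=8, L=1000.0, fixed_c=0.01)
        est = hill_goldbeter_koshland(
            curve_from_params(MWCParameters.uniform(8, 0.01, L=1000.0)))
        assert hm.H[0, 0] == pytest.approx(est.H, rel=1e-9)

    def test_independent_linear_locus_has_unit_hill(self):
        hm = hill_heatmap("independent", (10, 1e8), (10, 1e8), grid_size=13,
                          n=2, d=1000.0)
        assert hm.contour is not None and len(hm.contour)
        for i, x1 in enumerate(hm.axis1):
            x2 = 1000.0 ** 2 / x1
            j = int(np.argmin(np.abs(np.log(hm.axis2) - np.log(x2))))
            if abs(math.log(hm.axis2[j]) - math.log(x2)) < 1e-9 and hm.defined[i, j]:
                assert hm.H[i, j] == pytest.approx(1.0, abs=0.1)

    def test_long_format_export(self):
        hm = hill_heatmap("mwc", (1e-4, 0.9), (1e-4, 0.9), grid_size=10,
                          n=2, L=1000.0)
        df = hm.to_frame()
        assert list(df.columns) == ["axis1", "axis2", "H", "defined"]
        assert len(df) == 100


class TestDecreasingProportion:
    def test_seed_stability_within_sampling_noise(self):
        a = decreasing_proportion("mwc", [4], [1000.0], 100, 1e-4, 0.9, seed=1)
        b = decreasing_proportion("mwc", [4], [1000.0], 100, 1e-4, 0.9, seed=2)
        assert abs(a["proportion"].iloc[0] - b["proportion"].iloc[0]) < 0.1

    def test_two_site_mwc_has_exceptions(self):
        df = decreasing_proportion("mwc", [2], [1000.0], 300, 1e-4, 0.9, seed=11)
        assert df["proportion"].iloc[0] < 1.0
        assert df["defined_count"].iloc[0] <= 300

    def test_undefined_draws_accounted(self):
        # weak-activation draws at L=1000, n=2 produce undefined H
        df = decreasing_proportion("mwc", [2], [1000.0], 200, 0.5, 0.9, seed=4)
        assert df["defined_count"].iloc[0] < 200
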