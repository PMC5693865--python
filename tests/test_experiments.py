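"""Factorial runner, difference maps, global totals and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

import plantresp as pr
from plantresp.experiments import CARBON_G_PER_MOL, SECONDS_PER_YEAR
from plantresp.leaf import SchemeTag


def _constant_world(t=25.0, sw=0.0, lai=5.0, gpp=10.0):
    """One-cell domain with constant forcing and a pure-broadleaf canopy."""
    dom = pr.make_grid(pr.GridConfig(n_lat=1, n_lon=1, lat_min=-1.25,
                                     lat_max=1.25))
    n_days = 4
    clim = pr.ForcingFields(air_temp=np.full((n_days, 1, 1), t),
                            t_growth=np.full((n_days, 1, 1), t),
                            irradiance=np.full((n_days, 1, 1), sw))
    lai_arr = np.zeros((5, 1, 1))
    frac = np.zeros((5, 1, 1))
    i_bt = list(pr.PFT_NAMES).index("broadleaf_tree")
    lai_arr[i_bt] = lai
    frac[i_bt] = 1.0
    veg = pr.VegetationFields(lai=lai_arr, frac=frac,
                              beta=np.ones((1, 1)),
                              gpp=np.full((n_days, 1, 1), gpp))
    return dom, clim, veg


def test_single_cell_constant_forcing_equals_direct_call(broadleaf):
    dom, clim, veg = _constant_world()
    res = pr.run_factorial(dom, clim, veg)
    direct = pr.whole_plant(
        broadleaf, pr.LeafEnvironment(25.0, 25.0, 0.0),
        pr.VegetationState(lai=5.0, beta=1.0, gpp=10.0),
        pr.Scheme(SchemeTag.NEW_RD25_BC))
    d = res.data["NEW_RD25_BC"]
    for f in ("rd", "rdc", "rpm", "rpg", "rp", "npp"):
        assert d[f][0, 0] == pytest.approx(getattr(direct, f), rel=1e-12)


def test_new_baseline_ratio_carries_through_canopy():
    dom, clim, veg = _constant_world()
    res = pr.run_factorial(dom, clim, veg)
    ratio = res.data["NEW_RD25"]["rd"][0, 0] / res.data["STANDARD"]["rd"][0, 0]
    assert ratio == pytest.approx(1.136 / 0.4157, abs=2e-3)
    ratio_c = res.data["NEW_RD25"]["rdc"][0, 0] / res.data["STANDARD"]["rdc"][0, 0]
    assert ratio_c == pytest.approx(ratio, rel=1e-12)


def test_factorial_run_is_deterministic(small_world):
    dom, clim, veg = small_world
    a = pr.run_factorial(dom, clim, veg)
    b = pr.run_factorial(dom, clim, veg)
    for s in a.schemes:
        for f, x in a.data[s].items():
            np.testing.assert_array_equal(x, b.data[s][f])


def test_conservation_and_attribution_identity(small_result):
    res = small_result
    for s in res.schemes:
        d = res.data[s]
        np.testing.assert_allclose(d["rp"], d["rpm"] + d["rpg"],
                                   rtol=0, atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(d["npp"], res.gpp - d["rp"],
                                   rtol=0, atol=1e-12, equal_nan=True)
    steps = (pr.difference_map(res, res, "rp", "NEW_RD25", "STANDARD")
             + pr.difference_map(res, res, "rp", "NEW_RD25_BC", "NEW_RD25")
             + pr.difference_map(res, res, "rp", "NEW_RD25_BC_ACCLIM",
                                 "NEW_RD25_BC"))
    total = pr.difference_map(res, res, "rp", "NEW_RD25_BC_ACCLIM", "STANDARD")
    np.testing.assert_allclose(steps, total, rtol=0, atol=1e-12)


def test_difference_map_antisymmetry_and_validation(small_result):
    res = small_result
    d_ab = pr.difference_map(res, res, "rp", "NEW_RD25", "STANDARD")
    d_ba = pr.difference_map(res, res, "rp", "STANDARD", "NEW_RD25")
    np.testing.assert_allclose(d_ab, -d_ba, rtol=0, atol=0)
    zero = pr.difference_map(res, res, "rp", "STANDARD", "STANDARD")
    assert np.nanmax(np.abs(zero)) == 0.0
    with pytest.raises(KeyError):
        pr.difference_map(res, res, "nope", "STANDARD", "NEW_RD25")
    other = pr.make_grid(pr.GridConfig(n_lat=4, n_lon=4))
    clim = pr.generate_climate(other, pr.ClimateScenario(n_days=3), seed=0)
    veg = pr.generate_vegetation(other, seed=0, climate=clim)
    small = pr.run_factorial(other, clim, veg)
    with pytest.raises(ValueError):
        pr.difference_map(small_result, small, "rp", "STANDARD", "STANDARD")


def test_acclimation_sign_through_difference_maps(broadleaf):
    """Warm-acclimated cells respire less than the fixed-25 scheme; cold-
    acclimated cells more (sign of -r2(T_G - 25) through the linear chain)."""
    for t, sign in ((35.0, -1.0), (15.0, 1.0)):
        dom, clim, veg = _constant_world(t=t)
        res = pr.run_factorial(dom, clim, veg)
        d = pr.difference_map(res, res, "rp", "NEW_RD25_BC_ACCLIM",
                              "NEW_RD25_BC")
        assert np.sign(d[0, 0]) == sign


def test_global_total_unit_arithmetic(small_result, small_world):
    dom = small_world[0]
    # uniform 1 umol m^-2 s^-1 over 1 m^2 is 378.4 gC/yr before Gt scaling
    assert CARBON_G_PER_MOL * 1e-6 * SECONDS_PER_YEAR == pytest.approx(378.432)
    one_cell = pr.make_grid(pr.GridConfig(n_lat=1, n_lon=1, lat_min=0.0,
                                          lat_max=1.0))
    data = {"STANDARD": {f: np.ones((1, 1)) for f in
                         ("rd", "rdc", "rpm", "rpg", "rp", "npp",
                          "sigma_rd", "sigma_rdc", "sigma_rp")}}
    res = pr.GriddedResult(lat=one_cell.lat, lon=one_cell.lon, data=data,
                           gpp=np.ones((1, 1)))
    expected = float(one_cell.area[0, 0]) * 378.432 * 1e-15
    assert pr.global_total(res, one_cell, "rp") == pytest.approx(expected, rel=1e-12)
    # linearity: doubling fluxes doubles totals
    res2 = pr.GriddedResult(lat=one_cell.lat, lon=one_cell.lon,
                            data={"STANDARD": {k: 2 * v for k, v in
                                               data["STANDARD"].items()}},
                            gpp=res.gpp)
    assert pr.global_total(res2, one_cell, "rp") == pytest.approx(
        2 * expected, rel=1e-12)
    assert pr.global_total(small_result, dom, "rp", "STANDARD") > 0


def test_missing_pft_parameters_rejected(small_world, pfts):
    dom, clim, veg = small_world
    partial = {k: v for k, v in pfts.items() if k != "shrub"}
    with pytest.raises(ValueError, match="shrub"):
        pr.run_factorial(dom, clim, veg, pfts=partial)


# ---------------------------------------------------------------------------
# Parameter recovery


def test_recovery_exact_at_zero_noise(pfts):
    survey = pr.generate_leaf_survey(n=400, noise_std=0.0, seed=3)
    fit = pr.recover_globresp_params(survey)
    assert fit.r1 == pytest.approx(0.2061, abs=1e-8)
    assert fit.r2 == pytest.approx(0.0402, abs=1e-8)
    for name, r0 in fit.r0.items():
        assert r0 == pytest.approx(pfts[name].r0, abs=1e-8)


def test_recovery_matches_normal_equations_oracle():
    """statsmodels fit agrees with a direct normal-equations solve."""
    survey = pr.generate_leaf_survey(n=500, noise_std=0.3, seed=9)
    fit = pr.recover_globresp_params(survey)
    names = sorted(survey["pft"].unique())
    dummies = pd.get_dummies(survey["pft"], dtype=float)[names].to_numpy()
    X = np.column_stack([dummies, survey["n_la"], survey["t_growth"]])
    beta = np.linalg.solve(X.T @ X, X.T @ survey["rd25"].to_numpy())
    assert fit.r1 == pytest.approx(beta[-2], rel=1e-9)
    assert fit.r2 == pytest.approx(-beta[-1], rel=1e-9)


def test_recovery_within_three_standard_errors(pfts):
    survey = pr.generate_leaf_survey(n=1000, noise_std=0.3, seed=17)
    fit = pr.recover_globresp_params(survey)
    assert abs(fit.r1 - 0.2061) <= 3 * fit.se_r1
    assert abs(fit.r2 - 0.0402) <= 3 * fit.se_r2


def test_recovery_bias_shrinks_with_sample_size():
    errs = []
    for n in (100, 1000, 10000):
        fit = pr.recover_globresp_params(
            pr.generate_leaf_survey(n=n, noise_std=0.3, seed=23))
        errs.append(abs(fit.r2 - 0.0402))
    assert errs[2] < errs[0]


def test_single_pft_subset_recovers_its_intercept(pfts):
    survey = pr.generate_leaf_survey(n=800, noise_std=0.1, seed=5)
    sub = survey[survey["pft"] == "shrub"]
    fit = pr.recover_globresp_params(sub)
    assert list(fit.r0) == ["shrub"]
    assert fit.r0["shrub"] == pytest.approx(pfts["shrub"].r0, abs=0.1)


def test_constant_growth_temperature_is_unidentifiable():
    survey = pr.generate_leaf_survey(n=200, noise_std=0.1, seed=1,
                                     tg_range=(25.0, 25.0))
    with pytest.raises(ValueError, match="rank"):
        pr.recover_globresp_params(survey)
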