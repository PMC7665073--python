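"""Hedonic pricing: scaling, freight, mixed-effects fits, prediction."""

import warnings

import numpy as np
import pandas as pd
import pytest

from algafeed import (
    FreightSpec,
    HedonicMealRegressor,
    InvalidInputError,
    MealNutrients,
    OilFattyAcids,
    PanelSimConfig,
    fit_hedonic_meal,
    fit_hedonic_oil,
    freight_adjust,
    oil_to_whole_cell,
    predict_price,
    scale_variables,
    simulate_panel,
)
from algafeed.hedonic import _REGRESSORS


def _noiseless(model, seed=3):
    return simulate_panel(
        PanelSimConfig(model=model, resid_sd=0.0, random_sd=(0, 0, 0), seed=seed)
    )


def test_scale_variables():
    df = pd.DataFrame({"x": [10.0, 20.0, 30.0]})
    out = scale_variables(df, {"x": (20.0, 10.0)})
    assert out["x"].tolist() == [-1.0, 0.0, 1.0]
    ident = scale_variables(df, {"x": (0.0, 1.0)})
    assert ident["x"].tolist() == df["x"].tolist()
    with pytest.raises(InvalidInputError):
        scale_variables(df, {"y": (0.0, 1.0)})
    with pytest.raises(InvalidInputError):
        scale_variables(df, {"x": (0.0, 0.0)})


def test_freight_adjust():
    spec = FreightSpec(
        modal_shares={"rail": 1.0}, distances={"rail": 1000.0}, rates={"rail": 0.05}
    )
    assert freight_adjust(400.0, spec) == pytest.approx(450.0)
    zero = FreightSpec(
        modal_shares={"rail": 1.0}, distances={"rail": 1000.0}, rates={"rail": 0.0}
    )
    assert freight_adjust(400.0, zero) == 400.0
    two = FreightSpec(
        modal_shares={"rail": 0.5, "truck": 0.5},
        distances={"rail": 500.0, "truck": 500.0, "ocean": 10000.0},
        rates={"rail": 0.04, "truck": 0.04, "ocean": 0.01},
    )
    # equal rate*distance d=20 per mode -> price + 20 + ocean 100
    assert freight_adjust(400.0, two) == pytest.approx(400.0 + 20.0 + 100.0)
    with pytest.raises(InvalidInputError):
        FreightSpec(modal_shares={"rail": 0.7}, distances={}, rates={})


def test_freight_monotone_in_rates():
    base = FreightSpec(
        modal_shares={"rail": 1.0}, distances={"rail": 800.0}, rates={"rail": 0.03}
    )
    higher = FreightSpec(
        modal_shares={"rail": 1.0}, distances={"rail": 800.0}, rates={"rail": 0.06}
    )
    assert freight_adjust(100.0, higher) > freight_adjust(100.0, base)


def test_oil_to_whole_cell():
    assert oil_to_whole_cell(1.0, 0.54) == pytest.approx(0.54)
    assert oil_to_whole_cell(3.3, 1.0) == pytest.approx(3.3)
    assert oil_to_whole_cell(4.407, 0.54) == pytest.approx(2.38, abs=0.005)
    with pytest.raises(InvalidInputError):
        oil_to_whole_cell(1.0, 0.0)
    with pytest.raises(InvalidInputError):
        oil_to_whole_cell(1.0, 1.2)


@pytest.mark.parametrize("model,fitter", [
    ("meal", fit_hedonic_meal), ("oil", fit_hedonic_oil)
])
def test_noiseless_panel_exact_beta_recovery(model, fitter):
    panel, truth = _noiseless(model)
    est = fitter(panel)
    for k, v in truth.beta.items():
        assert est.coef_[k] == pytest.approx(v, rel=1e-6)
    assert est.sigma_resid_ == pytest.approx(0.0, abs=1e-6)


def test_noiseless_interpolation_identity():
    """Predicting at a training commodity's composition returns its
    generating price exactly."""
    panel, _ = _noiseless("meal")
    est = fit_hedonic_meal(panel)
    row = panel.iloc[0]
    pred = predict_price(
        est, {v: row[v] for v in ("cp", "ee", "met", "lys")}
    )
    assert pred == pytest.approx(row["price"], rel=1e-8)


def test_prediction_is_straight_line_evaluation_of_formula():
    """predict_price must equal an independent hand evaluation of the
    quadratic form at the scaled probe."""
    panel, _ = simulate_panel(PanelSimConfig(model="meal", seed=8))
    est = fit_hedonic_meal(panel)
    probe = {"cp": 45.0, "ee": 3.0, "met": 1.2, "lys": 2.5}
    z = {v: (probe[v] - est.scaling_[v][0]) / est.scaling_[v][1] for v in probe}
    by_hand = (
        est.coef_["intercept"]
        + est.coef_["cp_sq"] * z["cp"] ** 2
        + est.coef_["met_sq"] * z["met"] ** 2
        + est.coef_["lys_sq"] * z["lys"] ** 2
        + est.coef_["ee"] * z["ee"]
    )
    assert predict_price(est, probe) == pytest.approx(by_hand, rel=1e-12)
    # specific-year prediction adds that year's realized coefficients
    year = est.years_[0]
    re = est.random_effects_[year]
    by_hand_y = by_hand + re["intercept"] + re["cp"] * z["cp"] + re["ee"] * z["ee"]
    assert predict_price(est, probe, year_effects=year) == pytest.approx(
        by_hand_y, rel=1e-12
    )


def test_all_zero_scaled_probe_returns_intercept():
    panel, _ = _noiseless("meal")
    est = fit_hedonic_meal(panel)
    probe = {v: est.scaling_[v][0] for v in ("cp", "ee", "met", "lys")}
    assert predict_price(est, probe) == pytest.approx(
        est.coef_["intercept"], rel=1e-9
    )


def test_identical_compositions_rejected_as_singular():
    panel, _ = _noiseless("oil")
    for v in ("epa", "fa14_0", "fa16_1n7", "fa16_0"):
        panel[v] = 10.0
    with pytest.raises(InvalidInputError, match="singular|constant"):
        fit_hedonic_oil(panel)


def test_single_year_falls_back_to_fixed_effects():
    panel, _ = _noiseless("meal")
    panel = panel[panel["year"] == 2010].copy()
    with pytest.warns(UserWarning, match="single-year"):
        est = fit_hedonic_meal(panel)
    assert est.method_ == "ols"
    assert all(
        v == 0.0 for re in est.random_effects_.values() for v in re.values()
    )


def test_extrapolation_warns_not_errors():
    panel, _ = simulate_panel(PanelSimConfig(model="meal", seed=9))
    est = fit_hedonic_meal(panel)
    far = {"cp": 99.0, "ee": 99.0, "met": 0.0, "lys": 0.0}
    with pytest.warns(UserWarning, match="extrapolation"):
        val = predict_price(est, far)
    assert np.isfinite(val)


def test_scaling_injection_reparameterization():
    """With supplied (center, scale) on linear terms only, the fitted
    mean function at a probe is invariant to the parameterization."""
    panel, _ = simulate_panel(PanelSimConfig(model="meal", seed=10))
    est_auto = fit_hedonic_meal(panel)
    custom = {
        "cp": (40.0, 12.0),
        "ee": (5.0, 3.0),
        "met": (1.5, 0.6),
        "lys": (3.0, 1.4),
    }
    est_custom = fit_hedonic_meal(panel, scaling=custom)
    probe = {"cp": 50.0, "ee": 4.0, "met": 1.8, "lys": 3.5}
    # quadratic reparameterization is not exactly nested (no linear CP
    # term), so agreement is approximate but close at an interior probe
    p1 = predict_price(est_auto, probe)
    p2 = predict_price(est_custom, probe)
    assert p2 == pytest.approx(p1, rel=0.15)


def test_serialization_round_trip():
    panel, _ = simulate_panel(PanelSimConfig(model="oil", seed=11))
    est = fit_hedonic_oil(panel)
    payload = est.to_dict()
    est2 = _REGRESSORS[payload["model"]].from_dict(payload)
    probe = OilFattyAcids(epa=8.0, fa14_0=6.0, fa16_1n7=3.0, fa16_0=25.0)
    assert predict_price(est2, probe) == pytest.approx(
        predict_price(est, probe), rel=1e-12
    )


def test_composition_dataclasses_validate():
    with pytest.raises(InvalidInputError):
        MealNutrients(cp=120.0, ee=1.0, met=1.0, lys=1.0)
    with pytest.raises(InvalidInputError):
        OilFattyAcids(epa=-1.0, fa14_0=1.0, fa16_1n7=1.0, fa16_0=1.0)


def test_sklearn_protocol():
    est = HedonicMealRegressor()
    params = est.get_params()
    assert set(params) == {"scaling", "reml", "cov_structure"}
    est.set_params(reml=True)
    assert est.reml is True
    with pytest.raises(InvalidInputError):
        est.predict(pd.DataFrame())  # not fitted


def test_predict_per_year_distribution():
    panel, _ = simulate_panel(PanelSimConfig(model="meal", seed=12))
    est = fit_hedonic_meal(panel)
    probe = {"cp": 45.0, "ee": 3.0, "met": 1.2, "lys": 2.5}
    per_year = est.predict_per_year(probe)
    assert len(per_year) == 10
    marginal = predict_price(est, probe)
    # year effects are centered, so the per-year spread brackets marginal
    assert per_year.min() - 1e-9 <= marginal <= per_year.max() + 1e-9 or (
        abs(per_year.mean() - marginal) < 3 * per_year.std()
    )
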