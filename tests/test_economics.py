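"""Feed cost, ECR and bootstrap machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algafeed import (
    Formulation,
    InvalidInputError,
    TrialSimConfig,
    bootstrap_median_ci,
    ecr,
    ecr_table,
    feed_cost,
    simulate_trial,
)


def _single(diet="d", ing="x"):
    return Formulation(diet, {ing: 100.0})


def test_feed_cost_single_and_mix():
    assert feed_cost(_single(), {"x": 2.5}) == pytest.approx(2.5)
    f = Formulation("d", {"a": 50.0, "b": 50.0})
    assert feed_cost(f, {"a": 1.0, "b": 3.0}) == pytest.approx(2.0)


def test_feed_cost_constructed_fixture_reproduces_068():
    """A formulation-like mix with a price set built to land on 0.68."""
    f = Formulation(
        "100NS",
        {
            "n_oculata": 8.0,
            "schizochytrium": 6.2,
            "corn_gluten": 30.0,
            "soybean_meal": 30.0,
            "wheat_flour": 20.0,
            "other": 5.8,
        },
    )
    prices = {
        "n_oculata": 0.44,
        "schizochytrium": 2.38,
        "corn_gluten": 0.55,
        "soybean_meal": 0.47,
        "wheat_flour": 0.25,
        # balancing price: (0.68 - 0.53876) / 0.058
        "other": 2.4351724137931035,
    }
    assert feed_cost(f, prices) == pytest.approx(0.68, abs=5e-4)


def test_feed_cost_unpriced_ingredient_named():
    f = Formulation("d", {"a": 50.0, "mystery": 50.0})
    with pytest.raises(InvalidInputError, match="mystery"):
        feed_cost(f, {"a": 1.0})


def test_feed_cost_elementwise_over_samples():
    f = Formulation("d", {"a": 50.0, "b": 50.0})
    out = feed_cost(f, {"a": np.array([1.0, 2.0]), "b": np.array([3.0, 4.0])})
    assert np.allclose(out, [2.0, 3.0])


def test_feed_cost_monotone_in_prices(rng):
    f = Formulation("d", {"a": 40.0, "b": 60.0})
    base = feed_cost(f, {"a": 1.0, "b": 2.0})
    assert feed_cost(f, {"a": 1.5, "b": 2.0}) > base
    assert feed_cost(f, {"a": 1.0, "b": 2.5}) > base


@pytest.mark.parametrize(
    "fcr_val,price,expected",
    [(1.61, 0.64, 1.03), (1.40, 0.68, 0.95), (1.57, 0.72, 1.13), (1.60, 0.70, 1.12)],
)
def test_ecr_reproduces_published_products(fcr_val, price, expected):
    assert round(ecr(fcr_val, price), 2) == pytest.approx(expected, abs=1e-9)


@settings(max_examples=50, derandomize=True)
@given(
    f=st.floats(min_value=0.1, max_value=5.0),
    p=st.floats(min_value=0.1, max_value=5.0),
    a=st.floats(min_value=0.1, max_value=10.0),
)
def test_ecr_bilinear(f, p, a):
    assert ecr(a * f, p) == pytest.approx(a * ecr(f, p), rel=1e-12)
    assert ecr(f, a * p) == pytest.approx(a * ecr(f, p), rel=1e-12)


def test_ecr_degenerate_inputs():
    with pytest.raises(InvalidInputError):
        ecr(1.5, 0.0)
    with pytest.raises(InvalidInputError):
        ecr(0.0, 0.5)


def test_formulation_sum_constraint():
    with pytest.raises(InvalidInputError):
        Formulation("d", {"a": 50.0, "b": 30.0})
    with pytest.raises(InvalidInputError):
        Formulation("d", {"a": 110.0, "b": -10.0})
    Formulation("d", {"a": 60.0, "b": 40.5})  # within 1 g tolerance


def test_bootstrap_constant_sample_collapses():
    with pytest.warns(UserWarning, match="constant sample"):
        assert bootstrap_median_ci([5.0, 5.0, 5.0, 5.0], seed=1) == (5.0, 5.0, 5.0)


def test_bootstrap_two_point_sample_warns_unstable():
    with pytest.warns(UserWarning):
        med, lo, hi = bootstrap_median_ci([1.0, 2.0], seed=2)
    assert lo <= med <= hi


def test_bootstrap_reproducible_bit_for_bit(rng):
    sample = rng.normal(size=50)
    a = bootstrap_median_ci(sample, n_reps=2000, seed=7)
    b = bootstrap_median_ci(sample, n_reps=2000, seed=7)
    assert a == b
    c = bootstrap_median_ci(sample, n_reps=2000, seed=8)
    assert a != c


def test_bootstrap_input_validation():
    with pytest.raises(InvalidInputError):
        bootstrap_median_ci([1.0], seed=1)
    with pytest.raises(InvalidInputError):
        bootstrap_median_ci([1.0, 2.0, 3.0], n_reps=10, seed=1)


def _fixture_economy():
    tanks = simulate_trial(TrialSimConfig(seed=31))
    rng = np.random.default_rng(5)
    base = {
        "fishmeal": 1.54,
        "n_oculata": 0.44,
        "schizochytrium": 2.38,
        "fish_oil": 1.70,
        "bulk": 0.45,
    }
    prices = {k: v * rng.lognormal(0.0, 0.1, 10) for k, v in base.items()}
    forms = [
        Formulation("reference", {"fishmeal": 7.46, "fish_oil": 3.2, "bulk": 89.34}),
        Formulation("33NS", {"fishmeal": 2.38, "n_oculata": 3.0,
                             "schizochytrium": 6.2, "bulk": 88.42}),
        Formulation("66NS", {"fishmeal": 0.8, "n_oculata": 5.5,
                             "schizochytrium": 6.2, "bulk": 87.5}),
        Formulation("100NS", {"n_oculata": 8.0, "schizochytrium": 6.2,
                              "bulk": 85.8}),
    ]
    return forms, prices, tanks


def test_ecr_table_end_to_end():
    forms, prices, tanks = _fixture_economy()
    estimates, anova = ecr_table(forms, prices, tanks, seed=11, n_reps=2000)
    assert [e.diet for e in estimates] == ["reference", "33NS", "66NS", "100NS"]
    for e in estimates:
        assert e.feed_cost_ci[0] <= e.feed_cost_median <= e.feed_cost_ci[1]
        assert e.ecr_ci[0] <= e.ecr_median <= e.ecr_ci[1]
        # point ECR consistent with fcr x point feed cost
        assert e.ecr_point == pytest.approx(
            e.fcr_mean * sum(
                inc / 100.0 * np.median(prices[ing])
                for ing, inc in forms[[f.diet for f in forms].index(e.diet)]
                .inclusion.items()
            ),
            rel=1e-9,
        )
    assert anova.f_value > 0
    assert set(anova.tukey_letters) == {e.diet for e in estimates}


def test_ecr_disaggregation_sums_to_total():
    forms, prices, tanks = _fixture_economy()
    estimates, _ = ecr_table(forms, prices, tanks, seed=3, n_reps=2000)
    for e in estimates:
        assert sum(e.contributions.values()) == pytest.approx(
            e.ecr_point, abs=1e-12
        )


def test_ecr_table_identical_diets_share_letter():
    tanks = simulate_trial(
        TrialSimConfig(
            diet_sgr={"a": 0.8, "b": 0.8},
            diet_fcr={"a": 1.5, "b": 1.5},
            w0_sd=0.0,
            growth_noise_sd=0.01,
            feed_noise_sd=0.0,
            mortality_rate=0.0,
            seed=17,
        )
    )
    forms = [Formulation(d, {"x": 100.0}) for d in ("a", "b")]
    estimates, anova = ecr_table(forms, {"x": 0.5}, tanks, seed=4, n_reps=2000)
    assert estimates[0].feed_cost_median == estimates[1].feed_cost_median
    assert len(set(anova.tukey_letters.values())) == 1


def test_ecr_table_requires_replicates():
    forms, prices, tanks = _fixture_economy()
    with pytest.raises(InvalidInputError, match="replicates"):
        ecr_table(forms, prices, tanks[:1], seed=1, n_reps=2000)
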