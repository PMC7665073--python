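"""Feed cost, economic conversion ratio (ECR), and bootstrap uncertainty.

Feed cost is the inclusion-weighted sum of ingredient prices
(USD/kg feed); the ECR is FCR x feed price (USD per kg of fish weight
gain), the feed component of production cost.  Ingredient prices may be
point values or samples of (annual) price observations, in which case
feed cost and ECR acquire nonparametric bootstrap distributions and
BCa ("adjusted percentile") 95% intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import InvalidInputError
from .stats import AnovaResult, anova_oneway
from .trial import TankRecord, fcr as _fcr, weight_gain as _wg

__all__ = [
    "Formulation",
    "EcrEstimate",
    "feed_cost",
    "ecr",
    "bootstrap_median_ci",
    "ecr_table",
]

# ingredient -> USD/kg point value or 1-d sample of price observations
IngredientPriceSet = dict[str, "float | np.ndarray"]


@dataclass(frozen=True)
class Formulation:
    """Diet recipe: ingredient inclusion in g per 100 g of diet."""

    diet: str
    inclusion: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.inclusion.values()):
            raise InvalidInputError(f"diet {self.diet}: negative inclusion")
        total = sum(self.inclusion.values())
        if abs(total - 100.0) > 1.0:
            raise InvalidInputError(
                f"diet {self.diet}: inclusions sum to {total:.2f} g/100 g "
                "(expected 100 +/- 1)"
            )


@dataclass(frozen=True)
class EcrEstimate:
    """Per-diet economics: feed cost and ECR medians with 95% CIs, FCR
    mean +/- SE over tanks, and the per-ingredient ECR decomposition
    (built from median ingredient prices and mean FCR, so contributions
    sum exactly to ``ecr_point``)."""

    diet: str
    feed_cost_median: float
    feed_cost_ci: tuple[float, float]
    fcr_mean: float
    fcr_se: float
    ecr_median: float
    ecr_ci: tuple[float, float]
    ecr_point: float
    contributions: dict[str, float] = field(repr=False)


def _point_price(price) -> float:
    arr = np.asarray(price, dtype=float)
    return float(np.median(arr)) if arr.ndim else float(arr)


def feed_cost(f: Formulation, prices: IngredientPriceSet):
    """Feed cost (USD/kg): sum of (inclusion/100) x ingredient price.

    Scalar prices give a scalar cost; sample-vector prices are combined
    element-wise (vectors must share length) and give a cost vector.
    """
    active = {k: v for k, v in f.inclusion.items() if v > 0}
    missing = sorted(set(active) - set(prices))
    if missing:
        raise InvalidInputError(
            f"diet {f.diet}: unpriced ingredients {missing}"
        )
    for ing in active:
        if np.any(np.asarray(prices[ing], dtype=float) <= 0):
            raise InvalidInputError(f"diet {f.diet}: non-positive price for {ing!r}")
    total = 0.0
    for ing, inc in active.items():
        total = total + (inc / 100.0) * np.asarray(prices[ing], dtype=float)
    return total if np.ndim(total) else float(total)


def ecr(fcr_value: float, diet_price: float) -> float:
    """Economic conversion ratio (USD/kg fish): FCR x feed price."""
    if fcr_value <= 0 or diet_price <= 0:
        raise InvalidInputError("FCR and diet price must be positive")
    return fcr_value * diet_price


def bootstrap_median_ci(
    sample,
    n_reps: int = 10_000,
    seed: int | None = None,
    confidence: float = 0.95,
) -> tuple[float, float, float]:
    """Median with BCa (bias-corrected accelerated, "adjusted
    percentile") bootstrap confidence interval.

    Deterministic given ``seed``.  A constant sample collapses the CI to
    the point; near-degenerate samples (<= 2 distinct values) keep the
    BCa machinery but carry an instability warning, since the jackknife
    acceleration is then poorly determined.
    """
    arr = np.asarray(sample, dtype=float)
    if arr.size < 2:
        raise InvalidInputError("need at least 2 observations")
    if n_reps < 1000:
        raise InvalidInputError("need at least 1000 bootstrap replicates")
    med = float(np.median(arr))
    if np.ptp(arr) == 0:
        warnings.warn("constant sample: CI collapses to the point", stacklevel=2)
        return med, med, med
    if np.unique(arr).size <= 2:
        warnings.warn(
            "<= 2 distinct values: BCa acceleration estimate is unstable",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.bootstrap(
            (arr,),
            np.median,
            n_resamples=n_reps,
            confidence_level=confidence,
            method="BCa",
            rng=np.random.default_rng(seed),
        )
    lo, hi = res.confidence_interval
    if not np.isfinite(lo) or not np.isfinite(hi):
        # BCa bias correction degenerates when nearly all resampled
        # medians tie; fall back to plain percentiles
        warnings.warn(
            "BCa interval degenerate; falling back to percentile method",
            stacklevel=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.bootstrap(
                (arr,),
                np.median,
                n_resamples=n_reps,
                confidence_level=confidence,
                method="percentile",
                rng=np.random.default_rng(seed),
            )
        lo, hi = res.confidence_interval
    return med, float(lo), float(hi)


def _cost_samples(
    f: Formulation,
    prices: IngredientPriceSet,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap the feed cost by resampling each ingredient's price
    observations and recomputing its median per replicate."""
    cost = np.zeros(n_reps)
    for ing, inc in f.inclusion.items():
        if inc <= 0:
            continue
        arr = np.asarray(prices[ing], dtype=float)
        if arr.ndim == 0 or arr.size == 1:
            cost += (inc / 100.0) * float(np.asarray(arr).reshape(-1)[0])
        else:
            idx = rng.integers(0, arr.size, size=(n_reps, arr.size))
            cost += (inc / 100.0) * np.median(arr[idx], axis=1)
    return cost


def ecr_table(
    formulations: list[Formulation],
    prices: IngredientPriceSet,
    tanks: list[TankRecord],
    seed: int,
    n_reps: int = 10_000,
    alpha: float = 0.05,
) -> tuple[list[EcrEstimate], AnovaResult]:
    """Per-diet feed cost, FCR and ECR with bootstrap CIs, plus an
    ANOVA/Tukey comparison of ECR across diets.

    The ECR bootstrap couples each feed-cost replicate with a resampled
    tank FCR, propagating both price and between-tank uncertainty.  The
    ANOVA uses the tank as replicate unit: per-tank ECR = tank FCR x
    median feed cost of its diet.
    """
    rng = np.random.default_rng(seed)
    point_prices = {k: _point_price(v) for k, v in prices.items()}
    estimates: list[EcrEstimate] = []
    ecr_by_diet: dict[str, list[float]] = {}
    for f in formulations:
        diet_tanks = [t for t in tanks if t.diet == f.diet]
        if len(diet_tanks) < 2:
            raise InvalidInputError(
                f"diet {f.diet}: need >= 2 tank replicates, got {len(diet_tanks)}"
            )
        fcrs = np.array(
            [_fcr(t.feed_intake, _wg(t.w_final, t.w_initial)) for t in diet_tanks]
        )
        fcr_mean = float(fcrs.mean())
        fcr_se = float(fcrs.std(ddof=1) / np.sqrt(len(fcrs)))

        cost = _cost_samples(f, prices, n_reps, rng)
        cost_med = float(np.median(cost))
        if np.ptp(cost) == 0:
            cost_ci = (cost_med, cost_med)
        else:
            cost_ci = tuple(np.percentile(cost, [2.5, 97.5]).tolist())

        ecr_samples = cost * fcrs[rng.integers(0, len(fcrs), size=n_reps)]
        ecr_med = float(np.median(ecr_samples))
        if np.ptp(ecr_samples) == 0:
            ecr_ci = (ecr_med, ecr_med)
        else:
            ecr_ci = tuple(np.percentile(ecr_samples, [2.5, 97.5]).tolist())

        contributions = {
            ing: (inc / 100.0) * point_prices[ing] * fcr_mean
            for ing, inc in f.inclusion.items()
            if inc > 0
        }
        estimates.append(
            EcrEstimate(
                diet=f.diet,
                feed_cost_median=cost_med,
                feed_cost_ci=cost_ci,
                fcr_mean=fcr_mean,
                fcr_se=fcr_se,
                ecr_median=ecr_med,
                ecr_ci=ecr_ci,
                ecr_point=float(sum(contributions.values())),
                contributions=contributions,
            )
        )
        ecr_by_diet[f.diet] = (fcrs * cost_med).tolist()

    anova = anova_oneway(ecr_by_diet, alpha=alpha)
    return estimates, anova
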