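"""Synthetic-data generators mirroring the study design.

Each generator is the measurable inverse of its analysis stage: it draws
"true" quantities, pushes them through the inverted analysis formulas,
and adds realistic noise — so a zero-noise simulation followed by the
analysis recovers the truths exactly, and noisy runs exercise the whole
pipeline with the statistical structure the methods assume.

Defaults reproduce the study conditions: a 4-diet x 3-tank x 40-fish
tilapia trial (initial weight 34.5 +/- 2.06 g, 184 days), a 2010-2019
commodity price panel (12 meals / 7 oils) generated from the hedonic
mixed-effects models, and triplicate pH-stat titrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digestibility import IntestineTitration, StomachTitration
from .errors import InvalidInputError
from .hedonic import MEAL_SPEC, OIL_SPEC, HedonicFit
from .trial import TankRecord

__all__ = [
    "TrialSimConfig",
    "PanelSimConfig",
    "TitrationSimConfig",
    "simulate_trial",
    "simulate_panel",
    "simulate_titration",
]

# trial truths default to the observed diet-level outcomes:
# SGR in %/day, FCR dimensionless
_DEFAULT_DIET_SGR = {"reference": 0.62, "33NS": 0.81, "66NS": 0.74, "100NS": 0.87}
_DEFAULT_DIET_FCR = {"reference": 1.61, "33NS": 1.57, "66NS": 1.60, "100NS": 1.40}


@dataclass
class TrialSimConfig:
    """Feeding-trial generator settings (defaults = study design)."""

    tanks_per_diet: int = 3
    fish_per_tank: int = 40
    w0_mean: float = 34.5  # g
    w0_sd: float = 2.06  # g, between-tank spread of mean initial weight
    diet_sgr: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DIET_SGR)
    )
    diet_fcr: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DIET_FCR)
    )
    duration_days: float = 184.0
    mortality_rate: float = 0.06  # per-fish probability over the trial
    growth_noise_sd: float = 0.08  # lognormal sd on the tank growth factor
    feed_noise_sd: float = 0.05  # lognormal sd on tank feed intake
    protein_frac: float = 0.37  # dietary crude protein fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tanks_per_diet < 1 or self.fish_per_tank < 1:
            raise InvalidInputError("counts must be positive")
        if self.w0_mean <= 0 or self.w0_sd < 0 or self.duration_days <= 0:
            raise InvalidInputError("weights and duration must be positive")
        if not 0.0 <= self.mortality_rate < 1.0:
            raise InvalidInputError("mortality_rate must be in [0, 1)")
        if set(self.diet_sgr) != set(self.diet_fcr):
            raise InvalidInputError("diet_sgr and diet_fcr must share diets")
        if any(v <= 0 for v in self.diet_fcr.values()):
            raise InvalidInputError("true FCR must be positive")


def simulate_trial(cfg: TrialSimConfig) -> list[TankRecord]:
    """Generate tank records by inverting the growth formulas.

    Final weight comes from the diet's true SGR
    (``w_final = w0 * exp(sgr * days / 100)``) with lognormal tank noise;
    feed intake from true FCR x gain with its own lognormal noise;
    survivors by binomial thinning.
    """
    rng = np.random.default_rng(cfg.seed)
    tanks: list[TankRecord] = []
    for diet, true_sgr in cfg.diet_sgr.items():
        true_fcr = cfg.diet_fcr[diet]
        for k in range(cfg.tanks_per_diet):
            w0 = cfg.w0_mean + rng.normal(0.0, cfg.w0_sd) if cfg.w0_sd else cfg.w0_mean
            w0 = max(w0, 1e-3)
            growth_factor = float(np.exp(true_sgr * cfg.duration_days / 100.0))
            if cfg.growth_noise_sd:
                growth_factor *= float(np.exp(rng.normal(0.0, cfg.growth_noise_sd)))
            w_final = w0 * growth_factor
            gain = w_final - w0
            feed = true_fcr * gain
            if cfg.feed_noise_sd:
                feed *= float(np.exp(rng.normal(0.0, cfg.feed_noise_sd)))
            n0 = cfg.fish_per_tank
            n_final = (
                n0 - int(rng.binomial(n0, cfg.mortality_rate))
                if cfg.mortality_rate
                else n0
            )
            tanks.append(
                TankRecord(
                    tank_id=f"{diet}-T{k + 1}",
                    diet=diet,
                    n_initial=n0,
                    n_final=n_final,
                    w_initial=float(w0),
                    w_final=float(w_final),
                    feed_intake=float(feed),
                    protein_fed=float(feed * cfg.protein_frac),
                    duration_days=cfg.duration_days,
                )
            )
    return tanks


# generating fixed effects on the standardized composition scale, USD/tonne
_DEFAULT_MEAL_BETA = {
    "intercept": 520.0,
    "cp_sq": 55.0,
    "met_sq": 35.0,
    "lys_sq": 25.0,
    "ee": 30.0,
}
_DEFAULT_OIL_BETA = {
    "intercept": 950.0,
    "epa_sq": 90.0,
    "fa14_0_sq": 40.0,
    "fa16_1n7_sq": 30.0,
    "fa14_0": 45.0,
    "fa16_0": -55.0,
}
# raw composition spans (% mass for meals, % TFA for oils) wide enough to
# cover the novel microalgal ingredients, so pricing them is interpolation
_DEFAULT_MEAL_RANGES = {
    "cp": (20.0, 70.0),
    "ee": (0.5, 12.0),
    "met": (0.3, 3.0),
    "lys": (0.8, 6.0),
}
_DEFAULT_OIL_RANGES = {
    "epa": (0.0, 18.0),
    "fa14_0": (0.0, 15.0),
    "fa16_1n7": (0.0, 12.0),
    "fa16_0": (5.0, 45.0),
}

_PRICE_FLOOR = 10.0  # USD/tonne


@dataclass
class PanelSimConfig:
    """Commodity price panel generator settings.

    ``random_sd`` gives the SDs of the year-level (intercept, slope_1,
    slope_2) random coefficients; ``resid_sd`` the Gaussian residual SD,
    both in USD/tonne on the standardized composition scale.
    ``resid_sd=None`` (default) uses 5% of the panel's mean model price.
    """

    model: str = "meal"
    n_commodities: int | None = None  # default 12 meal / 7 oil
    years: tuple[int, int] = (2010, 2019)
    beta: dict[str, float] | None = None
    random_sd: tuple[float, float, float] = (30.0, 15.0, 15.0)
    resid_sd: float | None = None  # None -> 5% of mean model price
    composition_ranges: dict[str, tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("meal", "oil"):
            raise InvalidInputError(f"unknown model {self.model!r}")
        if self.n_commodities is None:
            self.n_commodities = 12 if self.model == "meal" else 7
        if self.n_commodities < 2:
            raise InvalidInputError("need >= 2 commodities")
        if self.years[1] < self.years[0]:
            raise InvalidInputError("years range reversed")
        if any(s < 0 for s in self.random_sd) or (
            self.resid_sd is not None and self.resid_sd < 0
        ):
            raise InvalidInputError("SDs must be >= 0")
        if self.beta is None:
            self.beta = dict(
                _DEFAULT_MEAL_BETA if self.model == "meal" else _DEFAULT_OIL_BETA
            )
        if self.composition_ranges is None:
            self.composition_ranges = dict(
                _DEFAULT_MEAL_RANGES if self.model == "meal" else _DEFAULT_OIL_RANGES
            )


def simulate_panel(cfg: PanelSimConfig) -> tuple[pd.DataFrame, HedonicFit]:
    """Generate a price panel from the hedonic model's forward form.

    Compositions are drawn uniformly within ``composition_ranges`` (one
    vector per commodity, constant over years); year-level random
    coefficients from centered normals; prices from the exact model mean
    plus Gaussian residual noise.  Returns the long panel (columns
    commodity, year, price + compositions) and the generating
    coefficients as a :class:`HedonicFit` for recovery testing — its
    ``scaling`` is the panel-mean/SD standardization a default fit will
    reproduce.
    """
    spec = MEAL_SPEC if cfg.model == "meal" else OIL_SPEC
    rng = np.random.default_rng(cfg.seed)
    years = list(range(cfg.years[0], cfg.years[1] + 1))

    comp = {}
    for v in spec.variables:
        lo, hi = cfg.composition_ranges[v]
        if hi < lo:
            raise InvalidInputError(f"range for {v!r} reversed")
        comp[v] = rng.uniform(lo, hi, cfg.n_commodities)
        if np.ptp(comp[v]) == 0:
            raise InvalidInputError(
                f"degenerate composition range for {v!r}: design unidentifiable"
            )

    # population SD matches the analysis-side auto-scaling, which sees
    # each commodity repeated once per year
    scaling = {
        v: (float(np.mean(comp[v])), float(np.std(comp[v])))
        for v in spec.variables
    }
    scaled = {v: (comp[v] - c) / s for v, (c, s) in scaling.items()}

    sd0, sd1, sd2 = cfg.random_sd
    random: dict[int, dict[str, float]] = {}
    for t in years:
        random[t] = {
            "intercept": float(rng.normal(0.0, sd0)) if sd0 else 0.0,
            spec.random_slopes[0]: float(rng.normal(0.0, sd1)) if sd1 else 0.0,
            spec.random_slopes[1]: float(rng.normal(0.0, sd2)) if sd2 else 0.0,
        }

    means = np.zeros((len(years), cfg.n_commodities))
    for ti, t in enumerate(years):
        re = random[t]
        for i in range(cfg.n_commodities):
            mean = cfg.beta["intercept"] + re["intercept"]
            for v in spec.quadratic:
                mean += cfg.beta[f"{v}_sq"] * scaled[v][i] ** 2
            for v in spec.linear:
                mean += cfg.beta[v] * scaled[v][i]
            for v in spec.random_slopes:
                mean += re[v] * scaled[v][i]
            means[ti, i] = mean
    resid_sd = (
        cfg.resid_sd
        if cfg.resid_sd is not None
        else 0.05 * float(np.mean(np.abs(means)))
    )

    rows = []
    for ti, t in enumerate(years):
        for i in range(cfg.n_commodities):
            mean = means[ti, i]
            price = mean + (rng.normal(0.0, resid_sd) if resid_sd else 0.0)
            rows.append(
                {
                    "commodity": f"{cfg.model}_{i + 1:02d}",
                    "year": t,
                    "price": price,
                    **{v: comp[v][i] for v in spec.variables},
                }
            )
    panel = pd.DataFrame(rows)
    if (panel["price"] < _PRICE_FLOOR).any():
        warnings.warn(
            f"simulated prices below {_PRICE_FLOOR} USD/t clipped", stacklevel=2
        )
        panel["price"] = panel["price"].clip(lower=_PRICE_FLOOR)

    truth = HedonicFit(
        model=cfg.model,
        beta=dict(cfg.beta),
        beta_se={k: 0.0 for k in cfg.beta},
        random=random,
        sigma_resid=resid_sd,
        loglik=float("nan"),
        scaling=scaling,
    )
    return panel, truth


@dataclass
class TitrationSimConfig:
    """pH-stat titration generator settings (triplicate by default)."""

    true_dh_stomach: float = 2.0  # %
    true_dh_intestine: float = 4.29  # %
    protein_mass: float = 0.08  # g, 80 mg substrate protein
    normality: float = 0.1  # meqv/mL for both titrants
    dose_noise_sd: float = 0.02  # mL on the total consumed volume
    replicates: int = 3
    P: float = 8.0
    F_pH: float = 1.08
    inv_a: float = 1.50
    H_tot: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_dh_stomach < 0 or self.true_dh_intestine < 0:
            raise InvalidInputError("true DH must be >= 0")
        if self.replicates < 1:
            raise InvalidInputError("need >= 1 replicate")
        if self.protein_mass <= 0 or self.normality <= 0:
            raise InvalidInputError("protein mass and normality must be positive")


def simulate_titration(
    cfg: TitrationSimConfig,
) -> list[tuple[StomachTitration, IntestineTitration]]:
    """Generate replicate titration records by inverting the DH formulas.

    The exact titrant volume yielding the configured true DH is computed
    for each phase, Gaussian dosing noise added, and a (stomach,
    intestine) record pair emitted per replicate.
    """
    rng = np.random.default_rng(cfg.seed)
    # invert DH_stomach = (V*N/E)*(1/P)*F_pH*100  for V
    v_true = (
        cfg.true_dh_stomach / 100.0 * cfg.protein_mass * cfg.P
    ) / (cfg.normality * cfg.F_pH)
    # invert DH_intestine = B*Nb*inv_a*(1/MP)*(1/H_tot)*100  for B
    b_true = (
        cfg.true_dh_intestine / 100.0 * cfg.protein_mass * cfg.H_tot
    ) / (cfg.normality * cfg.inv_a)
    out = []
    for _ in range(cfg.replicates):
        v = v_true + (rng.normal(0.0, cfg.dose_noise_sd) if cfg.dose_noise_sd else 0.0)
        b = b_true + (rng.normal(0.0, cfg.dose_noise_sd) if cfg.dose_noise_sd else 0.0)
        out.append(
            (
                StomachTitration(
                    V=max(v, 0.0),
                    N=cfg.normality,
                    E=cfg.protein_mass,
                    P=cfg.P,
                    F_pH=cfg.F_pH,
                ),
                IntestineTitration(
                    B=max(b, 0.0),
                    Nb=cfg.normality,
                    MP=cfg.protein_mass,
                    inv_a=cfg.inv_a,
                    H_tot=cfg.H_tot,
                ),
            )
        )
    return out
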