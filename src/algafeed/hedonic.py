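"""Hedonic pricing of novel aquafeed ingredients.

A hedonic regression explains a commodity's market price by its intrinsic
attributes.  Fitted to a decade-long panel of feed commodities, it lets us
impute a market price for an ingredient that is not yet traded — here a
defatted microalgal meal (priced by crude protein, ether extract,
methionine and lysine) and a microalgal oil (priced by its EPA, 14:0,
16:1n-7 and 16:0 fatty-acid fractions, then converted to a whole-cell
price via the cell's lipid fraction).

Prices are modelled with year-grouped linear mixed effects, estimated by
maximum likelihood.  For the meal model the mean structure is

    price = b0 + b1*CP^2 + b2*Met^2 + b3*Lys^2 + b4*EE
            + u0(year) + u1(year)*CP + u2(year)*EE + eps

and the oil model analogously uses {EPA^2, 14:0^2, 16:1n-7^2, 14:0, 16:0}
fixed terms with year-level intercept and slopes on 14:0 and 16:0.  All
composition variables are standardized ((x - center)/scale) before
fitting; by default center/scale are the panel mean/SD, and externally
supplied scaling parameters can be injected.

The estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) so they compose
with sklearn tooling; module-level ``fit_hedonic_meal`` /
``fit_hedonic_oil`` / ``predict_price`` are thin functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InvalidInputError

__all__ = [
    "MealNutrients",
    "OilFattyAcids",
    "FreightSpec",
    "ScalingParams",
    "HedonicMealRegressor",
    "HedonicOilRegressor",
    "scale_variables",
    "fit_hedonic_meal",
    "fit_hedonic_oil",
    "predict_price",
    "freight_adjust",
    "oil_to_whole_cell",
]

# per-variable (center, scale) used to standardize compositions
ScalingParams = dict[str, tuple[float, float]]


def _check_pct(name: str, value: float) -> None:
    if not 0.0 <= value <= 100.0:
        raise InvalidInputError(f"{name}={value} outside [0, 100] %")


@dataclass(frozen=True)
class MealNutrients:
    """Meal composition vector (% mass): crude protein, ether extract,
    methionine, lysine."""

    cp: float
    ee: float
    met: float
    lys: float

    def __post_init__(self) -> None:
        for k, v in self.__dict__.items():
            _check_pct(k, v)

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class OilFattyAcids:
    """Oil fatty-acid vector (% of total fatty acids): EPA (20:5n-3),
    myristic (14:0), palmitoleic (16:1n-7), palmitic (16:0)."""

    epa: float
    fa14_0: float
    fa16_1n7: float
    fa16_0: float

    def __post_init__(self) -> None:
        for k, v in self.__dict__.items():
            _check_pct(k, v)

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class FreightSpec:
    """Multi-modal freight cost specification.

    ``modal_shares`` apportion the domestic leg across transport modes
    (must sum to 1); ``rates`` are USD per tonne-km per mode;
    ``distances`` give the domestic km per mode plus an optional
    ``"ocean"`` leg (also keyed in ``rates``).
    """

    modal_shares: dict[str, float]
    distances: dict[str, float]
    rates: dict[str, float]
    destination: str = "Port of Shanghai"

    def __post_init__(self) -> None:
        total = sum(self.modal_shares.values())
        if abs(total - 1.0) > 1e-6:
            raise InvalidInputError(f"modal shares sum to {total}, expected 1")
        if any(v < 0 for v in self.modal_shares.values()):
            raise InvalidInputError("modal shares must be >= 0")
        if any(v < 0 for v in self.distances.values()) or any(
            v < 0 for v in self.rates.values()
        ):
            raise InvalidInputError("distances and rates must be >= 0")


def freight_adjust(price: float, spec: FreightSpec) -> float:
    """Landed price (USD/tonne): source price plus modal domestic freight
    and the ocean leg."""
    domestic = sum(
        share * spec.rates.get(mode, 0.0) * spec.distances.get(mode, 0.0)
        for mode, share in spec.modal_shares.items()
    )
    ocean = spec.rates.get("ocean", 0.0) * spec.distances.get("ocean", 0.0)
    return price + domestic + ocean


def oil_to_whole_cell(oil_price: float, lipid_fraction: float) -> float:
    """Convert an extracted-oil price to a whole-cell biomass price by the
    cell's lipid mass fraction (0.54 for Schizochytrium sp.)."""
    if not 0.0 < lipid_fraction <= 1.0:
        raise InvalidInputError(f"lipid fraction {lipid_fraction} outside (0, 1]")
    return oil_price * lipid_fraction


def scale_variables(panel: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Standardize composition columns: x -> (x - center)/scale.

    Price and identifier columns are untouched.  Every variable named in a
    panel composition column must have scaling parameters.
    """
    out = panel.copy()
    for col in params:
        if col not in out.columns:
            raise InvalidInputError(f"scaling parameter for unknown column {col!r}")
    for col, (center, scale) in params.items():
        if scale <= 0:
            raise InvalidInputError(f"scale for {col!r} must be > 0")
        out[col] = (out[col] - center) / scale
    return out


@dataclass(frozen=True)
class _ModelSpec:
    name: str
    variables: tuple[str, ...]  # composition columns, model order
    quadratic: tuple[str, ...]  # fixed-effect squared terms
    linear: tuple[str, ...]  # fixed-effect linear terms
    random_slopes: tuple[str, ...]  # year-level random slope variables


MEAL_SPEC = _ModelSpec(
    name="meal",
    variables=("cp", "ee", "met", "lys"),
    quadratic=("cp", "met", "lys"),
    linear=("ee",),
    random_slopes=("cp", "ee"),
)
OIL_SPEC = _ModelSpec(
    name="oil",
    variables=("epa", "fa14_0", "fa16_1n7", "fa16_0"),
    quadratic=("epa", "fa14_0", "fa16_1n7"),
    linear=("fa14_0", "fa16_0"),
    random_slopes=("fa14_0", "fa16_0"),
)


@dataclass(frozen=True)
class HedonicFit:
    """Serializable snapshot of a fitted hedonic model."""

    model: str
    beta: dict[str, float]
    beta_se: dict[str, float]
    random: dict[int, dict[str, float]]
    sigma_resid: float
    loglik: float
    scaling: ScalingParams = dc_field(repr=False, default_factory=dict)


class _BaseHedonicRegressor(RegressorMixin, BaseEstimator):
    """Year-grouped mixed-effects hedonic price regression.

    Parameters
    ----------
    scaling : dict or None
        Per-variable ``(center, scale)``; ``None`` uses panel mean/SD.
    reml : bool
        Restricted maximum likelihood instead of ML (default False, ML).
    cov_structure : {"diagonal", "free"}
        Independent variance components (default; identifiable with few
        grouping levels) or a fully free random-effects covariance.  A
        singular free covariance triggers a diagonal refit with a warning.
    """

    _spec: _ModelSpec  # set by subclass

    def __init__(
        self,
        scaling: ScalingParams | None = None,
        reml: bool = False,
        cov_structure: str = "diagonal",
    ):
        self.scaling = scaling
        self.reml = reml
        self.cov_structure = cov_structure

    # ------------------------------------------------------------------
    def _term_names(self) -> list[str]:
        spec = self._spec
        return (
            ["intercept"]
            + [f"{v}_sq" for v in spec.quadratic]
            + list(spec.linear)
        )

    def _design(self, scaled: pd.DataFrame) -> pd.DataFrame:
        spec = self._spec
        d = pd.DataFrame(index=scaled.index)
        d["intercept"] = 1.0
        for v in spec.quadratic:
            d[f"{v}_sq"] = scaled[v] ** 2
        for v in spec.linear:
            d[v] = scaled[v]
        return d

    def _validate_panel(self, X: pd.DataFrame) -> pd.DataFrame:
        spec = self._spec
        missing = [c for c in (*spec.variables, "year") if c not in X.columns]
        if missing:
            raise InvalidInputError(f"panel missing columns: {missing}")
        X = X.reset_index(drop=True)
        for v in spec.variables:
            if np.ptp(X[v].to_numpy(float)) == 0 and len(X) > 1:
                raise InvalidInputError(
                    f"composition variable {v!r} is constant across the panel: "
                    "design is singular"
                )
        return X

    def fit(self, X: pd.DataFrame, y: np.ndarray | pd.Series):
        """Fit to a commodity price panel.

        ``X`` needs the model's composition columns plus ``year``; ``y``
        is the price (USD/tonne, freight-adjusted).
        """
        spec = self._spec
        X = self._validate_panel(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise InvalidInputError("X and y length mismatch")
        if np.any(y <= 0):
            warnings.warn("panel contains non-positive prices", stacklevel=2)

        if self.scaling is not None:
            scaling = dict(self.scaling)
            missing = [v for v in spec.variables if v not in scaling]
            if missing:
                raise InvalidInputError(f"scaling params missing for: {missing}")
        else:
            scaling = {}
            for v in spec.variables:
                col = X[v].to_numpy(float)
                # population SD: invariant to repeating each commodity
                # across years, so it matches commodity-level scaling
                sd = float(np.std(col))
                if sd == 0:
                    raise InvalidInputError(f"cannot auto-scale constant {v!r}")
                scaling[v] = (float(np.mean(col)), sd)

        scaled = scale_variables(X[list(spec.variables)], scaling)
        scaled["year"] = X["year"].to_numpy()
        design = self._design(scaled)

        self.scaling_ = scaling
        self.n_obs_ = len(y)
        self.years_ = sorted(int(t) for t in scaled["year"].unique())
        self.scaled_range_ = {
            v: (float(scaled[v].min()), float(scaled[v].max()))
            for v in spec.variables
        }

        # noise-free or single-year panels: mixed-model variance components
        # are degenerate; the GLS fixed-effect solution reduces to OLS.
        ols = sm.OLS(y, design.to_numpy()).fit()
        resid_sd = float(np.sqrt(ols.scale))
        degenerate = len(self.years_) < 2 or resid_sd <= 1e-8 * (
            1.0 + float(np.mean(np.abs(y)))
        )
        if degenerate:
            if len(self.years_) < 2:
                warnings.warn(
                    "single-year panel: random effects unidentifiable, "
                    "falling back to fixed-effects-only fit",
                    stacklevel=2,
                )
            self._store_ols(ols, design.columns)
            return self

        df = scaled.copy()
        df["price"] = y
        for name, col in design.items():
            if name != "intercept":
                df[name] = col
        fixed_terms = [c for c in design.columns if c != "intercept"]
        formula = "price ~ " + " + ".join(fixed_terms)
        try:
            result = self._fit_mixed(df, formula, self.cov_structure)
        except (np.linalg.LinAlgError, ValueError) as exc:
            if self.cov_structure == "free":
                warnings.warn(
                    f"free random-effects covariance failed ({exc}); "
                    "refitting with diagonal covariance",
                    stacklevel=2,
                )
                result = self._fit_mixed(df, formula, "diagonal")
            else:
                raise InvalidInputError(
                    f"hedonic {spec.name} model did not converge: {exc}"
                ) from exc
        self._store_mixed(result, design.columns)
        return self

    def _fit_mixed(self, df: pd.DataFrame, formula: str, cov_structure: str):
        spec = self._spec
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if cov_structure == "diagonal":
                vc = {"year_intercept": "1"}
                for v in spec.random_slopes:
                    vc[f"slope_{v}"] = f"0 + {v}"
                model = smf.mixedlm(
                    formula, df, groups="year", re_formula="0", vc_formula=vc
                )
            elif cov_structure == "free":
                re_formula = "1 + " + " + ".join(spec.random_slopes)
                model = smf.mixedlm(formula, df, groups="year", re_formula=re_formula)
            else:
                raise InvalidInputError(
                    f"unknown cov_structure {cov_structure!r}"
                )
            # MixedLM convergence is optimizer-sensitive with few
            # grouping levels; walk a chain before giving up
            result = None
            for method in ("lbfgs", "bfgs", "powell", "cg"):
                result = model.fit(reml=self.reml, method=method, maxiter=2000)
                if result.converged:
                    break
            return result

    def _store_ols(self, ols, columns) -> None:
        names = self._term_names()
        self.coef_ = dict(zip(names, map(float, ols.params)))
        self.coef_se_ = dict(zip(names, map(float, ols.bse)))
        self.random_effects_ = {
            t: {"intercept": 0.0, **{v: 0.0 for v in self._spec.random_slopes}}
            for t in self.years_
        }
        self.sigma_resid_ = float(np.sqrt(ols.scale))
        self.loglik_ = float(ols.llf)
        self.converged_ = True
        self.method_ = "ols"
        return None

    def _store_mixed(self, result, columns) -> None:
        spec = self._spec
        if not result.converged:
            raise InvalidInputError(
                f"hedonic {spec.name} model did not converge after trying "
                "lbfgs/bfgs/powell/cg; check the panel for a singular or "
                "near-degenerate design"
            )
        fe = result.fe_params
        # statsmodels names the patsy intercept 'Intercept'
        rename = {"Intercept": "intercept"}
        self.coef_ = {
            rename.get(k, k): float(v) for k, v in fe.items()
        }
        self.coef_se_ = {
            rename.get(k, k): float(v) for k, v in result.bse_fe.items()
        }
        random_effects: dict[int, dict[str, float]] = {}
        for year, re in result.random_effects.items():
            d = {"intercept": 0.0, **{v: 0.0 for v in spec.random_slopes}}
            for key, val in re.items():
                if key.startswith("year_intercept"):
                    d["intercept"] = float(val)
                else:
                    for v in spec.random_slopes:
                        if key.startswith(f"slope_{v}") or key == v:
                            d[v] = float(val)
            random_effects[int(year)] = d
        self.random_effects_ = random_effects
        self.sigma_resid_ = float(np.sqrt(result.scale))
        self.loglik_ = float(result.llf)
        self.converged_ = True
        self.method_ = "reml" if self.reml else "ml"
        return None

    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise InvalidInputError("estimator is not fitted")

    def _scale_point(self, x: dict[str, float]) -> dict[str, float]:
        spec = self._spec
        missing = [v for v in spec.variables if v not in x]
        if missing:
            raise InvalidInputError(f"composition missing variables: {missing}")
        scaled = {}
        for v in spec.variables:
            center, scale = self.scaling_[v]
            scaled[v] = (x[v] - center) / scale
        return scaled

    def _warn_extrapolation(self, scaled: dict[str, float]) -> None:
        for v, z in scaled.items():
            lo, hi = self.scaled_range_[v]
            span = hi - lo
            margin = 0.25 * span
            if z < lo - margin or z > hi + margin:
                warnings.warn(
                    f"extrapolation: scaled {v}={z:.3f} outside panel range "
                    f"[{lo:.3f}, {hi:.3f}] by more than 25%",
                    stacklevel=3,
                )

    def _predict_point(
        self, x: dict[str, float], year_effects: str | int = "marginal"
    ) -> float:
        spec = self._spec
        scaled = self._scale_point(x)
        self._warn_extrapolation(scaled)
        yhat = self.coef_["intercept"]
        for v in spec.quadratic:
            yhat += self.coef_[f"{v}_sq"] * scaled[v] ** 2
        for v in spec.linear:
            yhat += self.coef_[v] * scaled[v]
        if year_effects != "marginal":
            year = int(year_effects)
            if year not in self.random_effects_:
                raise InvalidInputError(f"no random effects for year {year}")
            re = self.random_effects_[year]
            yhat += re["intercept"]
            for v in spec.random_slopes:
                yhat += re[v] * scaled[v]
        return float(yhat)

    def predict(
        self, X: pd.DataFrame, year_effects: str | int = "marginal"
    ) -> np.ndarray:
        """Predicted price (USD/tonne) at each composition row.

        ``year_effects="marginal"`` sets random effects to zero; an
        integer year adds that year's realized random coefficients.
        """
        self._check_fitted()
        rows = X.to_dict("records") if isinstance(X, pd.DataFrame) else list(X)
        return np.array(
            [self._predict_point(r, year_effects) for r in rows], dtype=float
        )

    def predict_per_year(self, x: dict[str, float]) -> pd.Series:
        """Price distribution over panel years (one prediction per year's
        realized random effects)."""
        self._check_fitted()
        return pd.Series(
            {t: self._predict_point(x, t) for t in self.years_}, name="price"
        )

    @property
    def result_(self) -> HedonicFit:
        self._check_fitted()
        return HedonicFit(
            model=self._spec.name,
            beta=dict(self.coef_),
            beta_se=dict(self.coef_se_),
            random={t: dict(d) for t, d in self.random_effects_.items()},
            sigma_resid=self.sigma_resid_,
            loglik=self.loglik_,
            scaling=dict(self.scaling_),
        )

    def to_dict(self) -> dict:
        """JSON-serializable snapshot (inverse of :meth:`from_dict`)."""
        self._check_fitted()
        return {
            "model": self._spec.name,
            "beta": self.coef_,
            "beta_se": self.coef_se_,
            "random_effects": {str(t): d for t, d in self.random_effects_.items()},
            "sigma_resid": self.sigma_resid_,
            "loglik": self.loglik_,
            "scaling": {v: list(cs) for v, cs in self.scaling_.items()},
            "scaled_range": {v: list(r) for v, r in self.scaled_range_.items()},
            "years": self.years_,
            "n_obs": self.n_obs_,
            "method": self.method_,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "_BaseHedonicRegressor":
        est = _REGRESSORS[payload["model"]]()
        est.coef_ = dict(payload["beta"])
        est.coef_se_ = dict(payload["beta_se"])
        est.random_effects_ = {
            int(t): dict(d) for t, d in payload["random_effects"].items()
        }
        est.sigma_resid_ = float(payload["sigma_resid"])
        est.loglik_ = float(payload["loglik"])
        est.scaling_ = {v: tuple(cs) for v, cs in payload["scaling"].items()}
        est.scaled_range_ = {
            v: tuple(r) for v, r in payload["scaled_range"].items()
        }
        est.years_ = [int(t) for t in payload["years"]]
        est.n_obs_ = int(payload["n_obs"])
        est.method_ = payload["method"]
        est.converged_ = True
        return est


class HedonicMealRegressor(_BaseHedonicRegressor):
    """Hedonic model for protein meals: price on {CP^2, Met^2, Lys^2, EE}
    with year-level random intercept and CP/EE slopes."""

    _spec = MEAL_SPEC


class HedonicOilRegressor(_BaseHedonicRegressor):
    """Hedonic model for feed oils: price on {EPA^2, 14:0^2, 16:1n-7^2,
    14:0, 16:0} with year-level random intercept and 14:0/16:0 slopes."""

    _spec = OIL_SPEC


_REGRESSORS = {"meal": HedonicMealRegressor, "oil": HedonicOilRegressor}


def _panel_xy(panel: pd.DataFrame, spec: _ModelSpec):
    if "price" not in panel.columns:
        raise InvalidInputError("panel needs a 'price' column (USD/tonne)")
    if "commodity" in panel.columns and panel["commodity"].nunique() < 2:
        raise InvalidInputError("panel needs >= 2 commodities")
    return panel.drop(columns=["price"]), panel["price"].to_numpy(float)


def fit_hedonic_meal(panel: pd.DataFrame, **kwargs) -> HedonicMealRegressor:
    """Fit the meal hedonic model to a long panel with columns
    commodity, year, price, cp, ee, met, lys."""
    X, y = _panel_xy(panel, MEAL_SPEC)
    return HedonicMealRegressor(**kwargs).fit(X, y)


def fit_hedonic_oil(panel: pd.DataFrame, **kwargs) -> HedonicOilRegressor:
    """Fit the oil hedonic model to a long panel with columns
    commodity, year, price, epa, fa14_0, fa16_1n7, fa16_0."""
    X, y = _panel_xy(panel, OIL_SPEC)
    return HedonicOilRegressor(**kwargs).fit(X, y)


def predict_price(
    fit: _BaseHedonicRegressor,
    x: MealNutrients | OilFattyAcids | dict[str, float],
    year_effects: str | int = "marginal",
) -> float:
    """Predicted price (USD/tonne) for one composition vector."""
    if hasattr(x, "as_dict"):
        x = x.as_dict()
    fit._check_fitted()
    return fit._predict_point(dict(x), year_effects)
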