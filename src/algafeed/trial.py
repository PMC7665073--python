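"""Growth-performance metrics for tank-replicated feeding trials.

The tank is the experimental unit: every metric (weight gain, FCR, SGR,
PER, survival) is computed per tank first and only then averaged within a
diet, so the reported mean +/- SE describes between-tank variability of
the metric itself, not a ratio of group means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedMetricError

__all__ = [
    "TankRecord",
    "GrowthSummary",
    "weight_gain",
    "weight_gain_pct",
    "fcr",
    "sgr",
    "per",
    "survival",
    "summarize_tank",
    "summarize_diet",
]


@dataclass(frozen=True)
class TankRecord:
    """One tank's trajectory through a feeding trial.

    Weights are mean wet weights per fish (g); ``feed_intake`` and
    ``protein_fed`` are cumulative amounts per fish (g) over the trial.
    """

    tank_id: str
    diet: str
    n_initial: int
    n_final: int
    w_initial: float
    w_final: float
    feed_intake: float
    protein_fed: float
    duration_days: float

    def __post_init__(self) -> None:
        if self.w_initial <= 0 or self.w_final <= 0:
            raise InvalidInputError(
                f"tank {self.tank_id}: weights must be positive "
                f"(w_initial={self.w_initial}, w_final={self.w_final})"
            )
        if self.n_initial < 0 or self.n_final < 0:
            raise InvalidInputError(f"tank {self.tank_id}: fish counts must be >= 0")
        if self.n_final > self.n_initial:
            raise InvalidInputError(
                f"tank {self.tank_id}: n_final ({self.n_final}) exceeds "
                f"n_initial ({self.n_initial})"
            )
        if self.duration_days <= 0:
            raise InvalidInputError(f"tank {self.tank_id}: duration_days must be > 0")
        if self.feed_intake < 0 or self.protein_fed < 0:
            raise InvalidInputError(f"tank {self.tank_id}: feed amounts must be >= 0")


@dataclass(frozen=True)
class GrowthSummary:
    """Per-tank growth metrics: WG (g and %), FCR, SGR (%/day), PER, survival (%)."""

    weight_gain_g: float
    weight_gain_pct: float
    fcr: float
    sgr: float
    per: float
    survival_pct: float


def weight_gain(w_final: float, w_initial: float) -> float:
    """Absolute weight gain (g): ``w_final - w_initial``."""
    if w_final <= 0 or w_initial <= 0:
        raise InvalidInputError("weights must be positive")
    return w_final - w_initial


def weight_gain_pct(w_final: float, w_initial: float) -> float:
    """Relative weight gain (%): ``100 * (w_final - w_initial) / w_initial``."""
    if w_initial <= 0:
        raise InvalidInputError("initial weight must be positive")
    return 100.0 * (w_final - w_initial) / w_initial


def fcr(feed_intake: float, gain: float) -> float:
    """Feed conversion ratio: feed intake / weight gain (same units).

    Undefined for non-positive gain; such tanks are reported via
    :class:`UndefinedMetricError` rather than silently dropped.
    """
    if gain <= 0:
        raise UndefinedMetricError(f"FCR undefined for weight gain {gain} <= 0")
    return feed_intake / gain


def sgr(w_final: float, w_initial: float, days: float) -> float:
    """Specific growth rate (%/day): ``100 * (ln w_final - ln w_initial) / days``."""
    if w_final <= 0 or w_initial <= 0 or days <= 0:
        raise InvalidInputError("weights and duration must be positive")
    return 100.0 * (math.log(w_final) - math.log(w_initial)) / days


def per(gain: float, protein_fed: float) -> float:
    """Protein efficiency ratio: weight gain (g) / protein fed (g)."""
    if protein_fed <= 0:
        raise InvalidInputError("protein fed must be positive")
    return gain / protein_fed


def survival(n_final: int, n_initial: int) -> float:
    """Survival rate (%): ``100 * n_final / n_initial``."""
    if n_initial <= 0:
        raise InvalidInputError("initial fish count must be positive")
    return 100.0 * n_final / n_initial


def summarize_tank(rec: TankRecord) -> GrowthSummary:
    """All growth metrics for a single tank."""
    gain = weight_gain(rec.w_final, rec.w_initial)
    return GrowthSummary(
        weight_gain_g=gain,
        weight_gain_pct=weight_gain_pct(rec.w_final, rec.w_initial),
        fcr=fcr(rec.feed_intake, gain),
        sgr=sgr(rec.w_final, rec.w_initial, rec.duration_days),
        per=per(gain, rec.protein_fed),
        survival_pct=survival(rec.n_final, rec.n_initial),
    )


_METRICS = [f.name for f in fields(GrowthSummary)]


def tank_metrics_frame(tanks: list[TankRecord]) -> pd.DataFrame:
    """Per-tank metric table (one row per tank, one column per metric)."""
    if not tanks:
        raise InvalidInputError("no tank records supplied")
    rows = []
    for t in tanks:
        s = summarize_tank(t)
        rows.append({"tank_id": t.tank_id, "diet": t.diet, **s.__dict__})
    return pd.DataFrame(rows)


def summarize_diet(tanks: list[TankRecord]) -> pd.DataFrame:
    """Per-diet mean and standard error of every growth metric.

    Metrics are computed per tank, then averaged; SE = sd / sqrt(n) over
    tank-level values.  A diet with a single tank gets its mean with SE
    reported as NaN (flagged by warning).

    Returns a frame indexed by diet with ``<metric>_mean``, ``<metric>_se``
    and ``n_tanks`` columns.
    """
    frame = tank_metrics_frame(tanks)
    out = {}
    for diet, grp in frame.groupby("diet", sort=False):
        n = len(grp)
        if n < 2:
            warnings.warn(
                f"diet {diet!r} has a single tank: SE unavailable", stacklevel=2
            )
        row: dict[str, float] = {"n_tanks": n}
        for m in _METRICS:
            vals = grp[m].to_numpy(float)
            row[f"{m}_mean"] = float(np.mean(vals))
            row[f"{m}_se"] = (
                float(np.std(vals, ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
            )
        out[diet] = row
    res = pd.DataFrame.from_dict(out, orient="index")
    res.index.name = "diet"
    return res
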