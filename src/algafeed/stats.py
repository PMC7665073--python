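"""One-way ANOVA with Tukey HSD letters, from raw replicates or from
published group summaries (mean, SE, n).

The summary route reconstructs each group's variance as ``n * se**2``
(since SE = sd/sqrt(n)), pools it into MS_within, and runs the classical
fixed-effects F test plus Tukey pairwise comparisons off the pooled
variance — which is exactly what the raw-data route produces for balanced
designs, so the two agree to numerical tolerance and printed mean +/- SE
tables can be re-analysed without the underlying replicates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import InvalidInputError

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "anova_oneway",
    "anova_from_summaries",
    "compact_letter_display",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Published per-group statistics: mean +/- SE over n replicates."""

    group: str
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise InvalidInputError(f"group {self.group}: SE must be >= 0")
        if self.n < 2:
            raise InvalidInputError(f"group {self.group}: need n >= 2 replicates")


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA outcome with Tukey HSD compact letter display.

    ``tukey_letters`` maps each group to a letter string; two groups
    sharing no letter differ significantly at ``alpha``.  ``pairwise_p``
    holds the Tukey-adjusted p-value for every unordered pair.
    """

    f_value: float
    p_value: float
    df_between: int
    df_within: int
    tukey_letters: dict[str, str]
    pairwise_p: dict[tuple[str, str], float] = field(repr=False)
    alpha: float = DEFAULT_ALPHA


def compact_letter_display(
    groups: list[str],
    means: dict[str, float],
    significant: dict[tuple[str, str], bool],
) -> dict[str, str]:
    """Assign letters so that significantly different groups share none.

    Insert-and-absorb: start from one column holding every group; for each
    significant pair split every column containing both; drop columns that
    became subsets of others.  Letters are ordered by descending column-max
    mean, matching the convention of annotating the best group 'a'.
    """
    columns: list[set[str]] = [set(groups)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend([col - {a}, col - {b}])
            else:
                new_cols.append(col)
        # absorb: keep only maximal columns
        columns = [
            c
            for i, c in enumerate(new_cols)
            if c and not any(c < d or (c == d and i > j) for j, d in enumerate(new_cols))
        ]
    columns.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in groups}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in groups}


def _assemble(
    names: list[str],
    means: np.ndarray,
    ns: np.ndarray,
    ms_within: float,
    df_within: int,
    alpha: float,
) -> AnovaResult:
    k = len(names)
    grand = float(np.sum(ns * means) / np.sum(ns))
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    df_between = k - 1
    ms_between = ss_between / df_between

    if ms_within <= 0:
        if ms_between == 0:
            f_val, p_val = 0.0, 1.0
        else:
            warnings.warn(
                "zero within-group variance: F reported as infinite", stacklevel=3
            )
            f_val, p_val = float("inf"), 0.0
    else:
        f_val = ms_between / ms_within
        p_val = float(sps.f.sf(f_val, df_between, df_within))

    pairwise: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        diff = abs(means[i] - means[j])
        if ms_within <= 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            # Tukey-Kramer: q statistic with pooled variance
            se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = diff / se
            p = float(sps.studentized_range.sf(q, k, df_within))
        pairwise[(names[i], names[j])] = p

    mean_map = dict(zip(names, means.tolist()))
    letters = compact_letter_display(
        names, mean_map, {pair: p < alpha for pair, p in pairwise.items()}
    )
    return AnovaResult(
        f_value=float(f_val),
        p_value=p_val,
        df_between=df_between,
        df_within=df_within,
        tukey_letters=letters,
        pairwise_p=pairwise,
        alpha=alpha,
    )


def anova_oneway(
    values: dict[str, list[float]], alpha: float = DEFAULT_ALPHA
) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA with Tukey HSD letters.

    ``values`` maps group label to its replicate observations (>= 2 each).
    """
    if len(values) < 2:
        raise InvalidInputError("need at least two groups")
    names = list(values)
    arrays = []
    for g in names:
        arr = np.asarray(values[g], dtype=float)
        if arr.size < 2:
            raise InvalidInputError(f"group {g!r} needs >= 2 replicates")
        arrays.append(arr)
    means = np.array([a.mean() for a in arrays])
    ns = np.array([a.size for a in arrays])
    df_within = int(np.sum(ns - 1))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    ms_within = ss_within / df_within
    return _assemble(names, means, ns, ms_within, df_within, alpha)


def anova_from_summaries(
    groups: list[GroupSummary], alpha: float = DEFAULT_ALPHA
) -> AnovaResult:
    """ANOVA/Tukey reconstructed from per-group (mean, SE, n) summaries."""
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    names = [g.group for g in groups]
    means = np.array([g.mean for g in groups], dtype=float)
    ns = np.array([g.n for g in groups])
    # sd^2 = n * se^2; pool with df weights
    variances = ns * np.array([g.se for g in groups], dtype=float) ** 2
    df_within = int(np.sum(ns - 1))
    ms_within = float(np.sum((ns - 1) * variances) / df_within)
    return _assemble(names, means, ns, ms_within, df_within, alpha)
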