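"""CSV/YAML readers with schema validation, and the full-pipeline driver.

All tables are comma-separated UTF-8 with a mandatory header and ``.``
decimals.  ``read_table`` validates a declared schema (required columns,
numeric coercion with cell coordinates on failure) and preserves unknown
columns, so outputs round-trip through the same reader.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .digestibility import (
    IntestineTitration,
    StomachTitration,
    dh_intestine,
    dh_stomach,
    predict_ipd,
)
from .economics import Formulation, ecr_table
from .errors import InvalidInputError, SchemaError
from .trial import TankRecord, summarize_diet, tank_metrics_frame

logger = logging.getLogger("algafeed")

__all__ = [
    "TableSchema",
    "read_table",
    "tanks_from_frame",
    "read_tanks",
    "read_formulations",
    "read_ingredient_prices",
    "read_titration",
    "digestibility_table",
    "PipelineConfig",
    "run_pipeline",
]


@dataclass(frozen=True)
class TableSchema:
    """Declared shape of a CSV input: required columns and their types
    (``"float"``, ``"int"`` or ``"str"``)."""

    name: str
    columns: dict[str, str]


TANKS_SCHEMA = TableSchema(
    "tanks",
    {
        "tank_id": "str",
        "diet": "str",
        "n_initial": "int",
        "n_final": "int",
        "w_initial_g": "float",
        "w_final_g": "float",
        "feed_intake_g": "float",
        "protein_fed_g": "float",
        "duration_days": "float",
    },
)
FORMULATION_SCHEMA = TableSchema(
    "formulation", {"diet": "str", "ingredient": "str", "g_per_100g": "float"}
)
PRICES_SCHEMA = TableSchema(
    "ingredient_prices", {"ingredient": "str", "usd_per_kg": "float"}
)
TITRATION_SCHEMA = TableSchema(
    "titration",
    {
        "diet": "str",
        "replicate": "int",
        "phase": "str",
        "volume_ml": "float",
        "normality": "float",
        "protein_mass_g": "float",
    },
)
PANEL_SCHEMA = TableSchema(
    "panel", {"commodity": "str", "year": "int", "price": "float"}
)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV against ``schema``.

    Missing required columns raise :class:`SchemaError` naming them;
    malformed numeric cells raise with row/column coordinates; unknown
    columns pass through untouched.  An empty file with only a header
    returns an empty frame with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{schema.name}: file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema.name}: missing required column(s) {missing} in {path}"
        )
    if df.empty:
        warnings.warn(f"{schema.name}: {path} has a header but no rows", stacklevel=2)
    for col, kind in schema.columns.items():
        if kind == "str":
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col].str.strip() != "")
        empty = df[col].str.strip() == ""
        if bad.any() or empty.any():
            row = int((bad | empty).idxmax())
            raise SchemaError(
                f"{schema.name}: malformed numeric cell at row {row + 2} "
                f"(1-based, incl. header), column {col!r}: {df[col][row]!r}"
            )
        df[col] = converted.astype(float if kind == "float" else int)
    return df


def tanks_from_frame(df: pd.DataFrame) -> list[TankRecord]:
    """Build validated :class:`TankRecord` objects from a tanks frame."""
    return [
        TankRecord(
            tank_id=str(r.tank_id),
            diet=str(r.diet),
            n_initial=int(r.n_initial),
            n_final=int(r.n_final),
            w_initial=float(r.w_initial_g),
            w_final=float(r.w_final_g),
            feed_intake=float(r.feed_intake_g),
            protein_fed=float(r.protein_fed_g),
            duration_days=float(r.duration_days),
        )
        for r in df.itertuples()
    ]


def read_tanks(path: str | Path) -> list[TankRecord]:
    return tanks_from_frame(read_table(path, TANKS_SCHEMA))


def read_formulations(path: str | Path) -> list[Formulation]:
    df = read_table(path, FORMULATION_SCHEMA)
    out = []
    for diet, grp in df.groupby("diet", sort=False):
        out.append(
            Formulation(
                diet=str(diet),
                inclusion=dict(zip(grp["ingredient"], grp["g_per_100g"])),
            )
        )
    return out


def read_ingredient_prices(path: str | Path) -> dict[str, float]:
    df = read_table(path, PRICES_SCHEMA)
    return dict(zip(df["ingredient"], df["usd_per_kg"]))


def read_titration(path: str | Path) -> pd.DataFrame:
    df = read_table(path, TITRATION_SCHEMA)
    bad = set(df["phase"]) - {"stomach", "intestine"}
    if bad:
        raise SchemaError(f"titration: unknown phase value(s) {sorted(bad)}")
    return df


def digestibility_table(
    titration: pd.DataFrame, reported: str = "intestine"
) -> pd.DataFrame:
    """Per-diet DH (mean +/- SE over replicates) and predicted IPD.

    Replicates are matched by (diet, replicate); each needs one stomach
    and one intestine row.  Optional constant columns (``P``, ``F_pH``,
    ``inv_a``, ``H_tot``) override the defaults row-wise.
    """
    rows = []
    for (diet, rep), grp in titration.groupby(["diet", "replicate"], sort=False):
        by_phase = {p: g.iloc[0] for p, g in grp.groupby("phase")}
        if set(by_phase) != {"stomach", "intestine"}:
            raise InvalidInputError(
                f"diet {diet} replicate {rep}: need one stomach and one "
                "intestine row"
            )
        s_row, i_row = by_phase["stomach"], by_phase["intestine"]
        s = StomachTitration(
            V=float(s_row["volume_ml"]),
            N=float(s_row["normality"]),
            E=float(s_row["protein_mass_g"]),
            P=float(s_row.get("P", 8.0) or 8.0),
            F_pH=float(s_row.get("F_pH", 1.08) or 1.08),
        )
        i = IntestineTitration(
            B=float(i_row["volume_ml"]),
            Nb=float(i_row["normality"]),
            MP=float(i_row["protein_mass_g"]),
            inv_a=float(i_row.get("inv_a", 1.50) or 1.50),
            H_tot=float(i_row.get("H_tot", 8.0) or 8.0),
        )
        ds, di = dh_stomach(s), dh_intestine(i)
        dr = {"stomach": ds, "intestine": di, "sum": ds + di}[reported]
        rows.append({"diet": diet, "replicate": rep, "dh": dr})
    per_rep = pd.DataFrame(rows)
    out = []
    for diet, grp in per_rep.groupby("diet", sort=False):
        vals = grp["dh"].to_numpy(float)
        n = len(vals)
        mean_dh = float(vals.mean())
        out.append(
            {
                "diet": diet,
                "n": n,
                "dh_mean": mean_dh,
                "dh_se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "ipd": predict_ipd(mean_dh),
            }
        )
    return pd.DataFrame(out)


@dataclass
class PipelineConfig:
    """Paths and parameters for the end-to-end pipeline run."""

    tanks: str
    out_dir: str
    titration: str | None = None
    formulation: str | None = None
    ingredient_prices: str | None = None
    bootstrap_reps: int = 10_000
    seed: int = 20201112
    alpha: float = 0.05
    dh_reported: str = "intestine"
    verbosity: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 1000:
            raise InvalidInputError("bootstrap_reps must be >= 1000")
        if not 0.0 < self.alpha < 0.5:
            raise InvalidInputError("alpha must be in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw.pop(k) for k in list(raw) if k in cls.__dataclass_fields__}
        return cls(**known, extra=raw)

    def config_hash(self) -> str:
        """SHA-256 over the config parameters and every input file's
        bytes; changes iff any input byte or parameter changes."""
        h = hashlib.sha256()
        payload = {
            k: v for k, v in self.__dict__.items() if k not in ("extra", "out_dir")
        }
        h.update(json.dumps(payload, sort_keys=True).encode())
        for p in (self.tanks, self.titration, self.formulation, self.ingredient_prices):
            if p is not None and Path(p).exists():
                h.update(Path(p).read_bytes())
        return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Always: per-diet growth summary + weight-gain ANOVA.  With titration
    input: digestibility table.  With formulation + prices: feed cost /
    ECR table and per-ingredient ECR disaggregation.  A manifest records
    seed, package version and the config hash; re-running an unchanged
    config reproduces the JSON byte-for-byte.
    """
    from .stats import anova_oneway

    logging.basicConfig(level=cfg.verbosity)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    tanks = read_tanks(cfg.tanks)
    growth = summarize_diet(tanks)
    growth.to_csv(out_dir / "growth_summary.csv")
    per_tank = tank_metrics_frame(tanks)
    anova = anova_oneway(
        {d: g["weight_gain_g"].tolist() for d, g in per_tank.groupby("diet", sort=False)},
        alpha=cfg.alpha,
    )
    report["growth"] = {
        "anova_f": anova.f_value,
        "anova_p": anova.p_value,
        "tukey_letters": anova.tukey_letters,
    }
    logger.info("growth summary written (%d tanks)", len(tanks))

    if cfg.titration:
        dig = digestibility_table(read_titration(cfg.titration), cfg.dh_reported)
        dig.to_csv(out_dir / "digestibility.csv", index=False)
        report["digestibility"] = dig.set_index("diet")["ipd"].round(6).to_dict()
    else:
        logger.info("no titration input: digestibility stage skipped")

    if cfg.formulation and cfg.ingredient_prices:
        formulations = read_formulations(cfg.formulation)
        prices = read_ingredient_prices(cfg.ingredient_prices)
        logger.info("ECR bootstrap: seed=%d reps=%d", cfg.seed, cfg.bootstrap_reps)
        estimates, ecr_anova = ecr_table(
            formulations,
            prices,
            tanks,
            seed=cfg.seed,
            n_reps=cfg.bootstrap_reps,
            alpha=cfg.alpha,
        )
        ecr_rows = []
        dis_rows = []
        for e in estimates:
            ecr_rows.append(
                {
                    "diet": e.diet,
                    "feed_cost_median": round(e.feed_cost_median, 4),
                    "feed_cost_lo": round(e.feed_cost_ci[0], 4),
                    "feed_cost_hi": round(e.feed_cost_ci[1], 4),
                    "fcr_mean": round(e.fcr_mean, 4),
                    "fcr_se": round(e.fcr_se, 4),
                    "ecr_median": round(e.ecr_median, 4),
                    "ecr_lo": round(e.ecr_ci[0], 4),
                    "ecr_hi": round(e.ecr_ci[1], 4),
                    "tukey": ecr_anova.tukey_letters[e.diet],
                }
            )
            for ing, c in e.contributions.items():
                dis_rows.append(
                    {"diet": e.diet, "ingredient": ing, "ecr_contribution": c}
                )
        pd.DataFrame(ecr_rows).to_csv(out_dir / "ecr_table.csv", index=False)
        pd.DataFrame(dis_rows).to_csv(
            out_dir / "ecr_disaggregation.csv", index=False
        )
        report["ecr"] = {
            r["diet"]: {"feed_cost": r["feed_cost_median"], "ecr": r["ecr_median"]}
            for r in ecr_rows
        }
        report["ecr_anova"] = {"f": ecr_anova.f_value, "p": ecr_anova.p_value}
    else:
        logger.info("price/formulation inputs missing: economics stage skipped")

    manifest = {
        "algafeed_version": __version__,
        "seed": cfg.seed,
        "bootstrap_reps": cfg.bootstrap_reps,
        "alpha": cfg.alpha,
        "config_hash": cfg.config_hash(),
        "stages": sorted(report),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
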