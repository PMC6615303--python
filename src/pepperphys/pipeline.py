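"""End-to-end run: simulate (or load) -> fit -> derive -> analyze -> report.

A run is driven by a :class:`RunConfig` (usually loaded from YAML) and
produces a bundle of CSV report tables plus a JSON manifest recording
the seed, a hash of the configuration and library versions, so a bundle
can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import (
    gas_exchange_metrics as gem,
    photosynthesis_models as pm,
    synthetic_data as sd,
    treatment_stats as ts,
    water_balance as wb,
)

log = logging.getLogger("pepperphys")

GAS_EXCHANGE_COLUMNS = ["pot_id", "ec_iw", "target_lf", "day", "pn", "gs", "ci", "ca"]
CURVE_COLUMNS = ["pot_id", "ec_iw", "target_lf", "setpoint", "pn"]
ISOTOPE_COLUMNS = [
    "pot_id", "ec_iw", "target_lf", "delta13c_permil", "delta15n_permil",
    "c_content_pct", "n_content_pct", "leaf_dry_biomass_g",
]
LEDGER_COLUMNS = [
    "pot_id", "event_index", "w_before_g", "w_next_g", "applied_L", "drainage_L",
]


class SchemaError(ValueError):
    """An input table is missing a required column."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``inputs`` (paths to existing CSVs) or ``simulate``
    (design/model overrides for the synthetic generator) may be given;
    an empty ``simulate`` block means "simulate with defaults".
    """

    outdir: str = "pepperphys_run"
    seed: int = 20150428
    inputs: dict | None = None
    simulate: dict | None = field(default_factory=dict)
    alpha: float = 0.05
    wue_mode: str = "mean_of_ratios"  # or "ratio_of_means"
    lf_mode: str = "exact"  # or "paper_multiplier"
    anova_mode: str = "average_then_test"  # or "pool_days"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.inputs is not None and self.simulate is not None:
            raise ValueError("config must provide either 'inputs' or 'simulate', not both")
        if self.inputs is None and self.simulate is None:
            raise ValueError("config must provide one of 'inputs' or 'simulate'")
        if self.wue_mode not in ("mean_of_ratios", "ratio_of_means"):
            raise ValueError(f"unknown wue_mode {self.wue_mode!r}")
        if self.anova_mode not in ("average_then_test", "pool_days"):
            raise ValueError(f"unknown anova_mode {self.anova_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "inputs" in raw and "simulate" in raw:
            raise ValueError("config must provide either 'inputs' or 'simulate', not both")
        if "inputs" in raw:
            raw.setdefault("simulate", None)
        return cls(**raw)


def _require(df: pd.DataFrame, cols, table: str) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")
    return df


def _load_tables(config: RunConfig) -> dict[str, pd.DataFrame]:
    if config.simulate is not None:
        block = dict(config.simulate)
        design_kwargs = block.get("design", {})
        design_kwargs.setdefault("rng_seed", config.seed)
        design = sd.ExperimentDesign(**design_kwargs)
        model = sd.GenerationModel.default(
            design,
            noise_sd=block.get("noise_sd"),
            interaction=_parse_interaction(block.get("interaction")),
        )
        if block.get("noise_free"):
            model = model.noise_free()
        tables = sd.simulate(design, model)
    else:
        tables = {name: pd.read_csv(path) for name, path in config.inputs.items()}
    _require(tables["gas_exchange"], GAS_EXCHANGE_COLUMNS, "gas_exchange")
    _require(tables["light_curves"], CURVE_COLUMNS, "light_curves")
    _require(tables["co2_curves"], CURVE_COLUMNS, "co2_curves")
    _require(tables["isotopes"], ISOTOPE_COLUMNS, "isotopes")
    _require(tables["irrigation"], LEDGER_COLUMNS, "irrigation")
    return tables


def _parse_interaction(raw):
    # YAML keys are "ec,lf" strings; convert to tuple keys
    if not raw:
        return None
    out = {}
    for key, deltas in raw.items():
        if isinstance(key, str):
            ec, lf = (float(x) for x in key.split(","))
        else:
            ec, lf = key
        out[(ec, lf)] = deltas
    return out


def _stars_row(anova: ts.AnovaResult) -> dict:
    return {term: ts.significance_stars(anova.table.loc[term, "p"]) for term in anova.table.index}


def _factorial_summary(
    df: pd.DataFrame, responses: list[str], alpha: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marginal means with Duncan letters plus an ANOVA star table.

    One row per factor level per response for the means table; ANOVA is
    run per response with terms LF, EC_iw and LF x EC_iw.
    """
    mean_rows, anova_rows = [], []
    for resp in responses:
        anova = ts.two_way_anova(
            df[resp], df["target_lf"], df["ec_iw"], names=("LF", "EC_iw")
        )
        n_cells = df.groupby(["ec_iw", "target_lf"]).ngroups
        for factor in ("ec_iw", "target_lf"):
            marg = df.groupby(factor)[resp].mean()
            n_per = len(df) // df[factor].nunique()
            letters = ts.duncan_mrt(
                marg.to_dict(), anova.residual_ms, anova.residual_df, n_per, alpha
            )
            for lvl, mean, letter in zip(letters.levels, letters.means, letters.letters):
                mean_rows.append(
                    {"response": resp, "factor": factor, "level": lvl,
                     "mean": mean, "letter": letter}
                )
        stars = _stars_row(anova)
        anova_rows.append(
            {"response": resp, **{f"{k} stars": v for k, v in stars.items()},
             **{f"{term} p": anova.table.loc[term, "p"] for term in anova.table.index}}
        )
    return pd.DataFrame(mean_rows), pd.DataFrame(anova_rows)


def _fit_curves(curves: pd.DataFrame, kind: str) -> pd.DataFrame:
    rows = []
    for pot, sub in curves.groupby("pot_id", sort=True):
        fit = (
            pm.fit_light_response(sub["setpoint"], sub["pn"])
            if kind == "light"
            else pm.fit_co2_response(sub["setpoint"], sub["pn"])
        )
        p = fit.params
        base = {
            "pot_id": pot,
            "ec_iw": sub["ec_iw"].iloc[0],
            "target_lf": sub["target_lf"].iloc[0],
            "rss": fit.rss,
            "r_squared": fit.r_squared,
            "converged": fit.converged,
            "n_points": fit.n_points,
        }
        if kind == "light":
            base.update(alpha=p.alpha, pn_max=p.pn_max, kappa=p.kappa, rd=p.rd)
        else:
            base.update(epsilon=p.epsilon, pn_sat=p.pn_sat, rp=p.rp)
        rows.append(base)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and write the report bundle to ``outdir``.

    Returns the report tables keyed by output name (also written as CSV,
    with a ``manifest.json`` alongside).
    """
    logging.basicConfig(level=config.log_level)
    t0 = time.time()
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tables = _load_tables(config)
    log.info("stage=load tables=%s rows=%s", list(tables), {k: len(v) for k, v in tables.items()})

    # --- gas exchange summary (table 1 analogue)
    gx = tables["gas_exchange"].copy()
    gx["ci_ca"] = gem.ci_ca_ratio(gx["ci"], gx["ca"])
    gx["wue"] = gem.intrinsic_wue(gx["pn"], gx["gs"])
    n_flagged = int((gx["ci_ca"] > 1.0).sum())
    if n_flagged:
        log.warning("%d observations with C_i/C_a > 1", n_flagged)
    if config.anova_mode == "average_then_test":
        per_pot = gx.groupby(["pot_id", "ec_iw", "target_lf"], as_index=False)[
            ["pn", "gs", "ci_ca", "wue"]
        ].mean()
        if config.wue_mode == "ratio_of_means":
            per_pot["wue"] = per_pot["pn"] / per_pot["gs"]
    else:
        per_pot = gx[["pot_id", "ec_iw", "target_lf", "pn", "gs", "ci_ca", "wue"]].copy()
    table1_means, table1_anova = _factorial_summary(
        per_pot, ["pn", "gs", "ci_ca", "wue"], config.alpha
    )
    log.info("stage=gas_exchange rows=%d elapsed=%.2fs", len(per_pot), time.time() - t0)

    # --- curve fits (table 2 analogue)
    light_fits = _fit_curves(tables["light_curves"], "light")
    co2_fits = _fit_curves(tables["co2_curves"], "co2")
    curve_params = light_fits.merge(
        co2_fits,
        on=["pot_id", "ec_iw", "target_lf"],
        suffixes=("_light", "_co2"),
    )
    table2_means, table2_anova = _factorial_summary(
        curve_params, ["alpha", "pn_max", "kappa", "rd", "epsilon", "pn_sat", "rp"], config.alpha
    )
    log.info("stage=curve_fits pots=%d elapsed=%.2fs", len(curve_params), time.time() - t0)

    # --- isotopes and biomass (tables 3-4 analogues)
    iso = tables["isotopes"].copy()
    from . import isotope_metrics as im

    iso["big_delta13c_permil"] = im.big_delta13c(iso["delta13c_permil"])
    iso["total_c_g"] = im.total_accumulation(iso["c_content_pct"], iso["leaf_dry_biomass_g"])
    iso["total_n_g"] = im.total_accumulation(iso["n_content_pct"], iso["leaf_dry_biomass_g"])
    table3_means, table3_anova = _factorial_summary(
        iso, ["big_delta13c_permil", "c_content_pct", "total_c_g", "delta15n_permil", "total_n_g"],
        config.alpha,
    )
    biomass_cols = [c for c in ("leaf_dry_biomass_g", "root_dry_biomass_g", "na_content_mg_g")
                    if c in iso.columns]
    table4_means, table4_anova = _factorial_summary(iso, biomass_cols, config.alpha)
    log.info("stage=isotopes rows=%d elapsed=%.2fs", len(iso), time.time() - t0)

    # --- water balance
    water_report = wb.season_summary(tables["irrigation"], tables["units"])
    neg_et = int((water_report["total_et_g"] < 0).sum())
    if neg_et:
        log.warning("%d pots with negative seasonal ET", neg_et)

    # --- regressions and ANCOVA
    regressions = _regression_report(gx, iso, config.alpha)

    bundle = {
        "table1_gas_exchange": table1_means,
        "table1_anova": table1_anova,
        "table2_curve_params": table2_means,
        "table2_anova": table2_anova,
        "table2_pot_fits": curve_params,
        "table3_isotopes": table3_means,
        "table3_anova": table3_anova,
        "table4_biomass": table4_means,
        "table4_anova": table4_anova,
        "water_balance_report": water_report,
        "regressions": regressions,
    }
    for name, df in bundle.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    _write_manifest(config, outdir, bundle)
    log.info("stage=report outputs=%d elapsed=%.2fs", len(bundle), time.time() - t0)
    return bundle


def _regression_report(gx: pd.DataFrame, iso: pd.DataFrame, alpha: float) -> pd.DataFrame:
    rows = []
    a, b, r2, n = gem.fit_pn_gs_log(gx["pn"], gx["gs"])
    rows.append({"name": "pn_vs_ln_gs_pooled", "intercept": a, "slope": b,
                 "r_squared": r2, "p": np.nan, "n": n})
    for factor in ("ec_iw", "target_lf"):
        anc = ts.ancova_slope_test(gx["pn"], gx["gs"], gx[factor], alpha)
        rows.append({
            "name": f"ancova_slope_homogeneity_{factor}",
            "intercept": np.nan, "slope": anc.common_slope,
            "r_squared": np.nan, "p": anc.interaction_p, "n": len(gx),
        })
    cell = iso.groupby(["ec_iw", "target_lf"]).mean(numeric_only=True)
    if len(cell) >= 3:
        reg = ts.linear_regression_r2(cell["total_n_g"], cell["leaf_dry_biomass_g"])
        rows.append({"name": "leaf_biomass_vs_total_n_cells", "intercept": reg.intercept,
                     "slope": reg.slope, "r_squared": reg.r_squared, "p": reg.p_value,
                     "n": reg.n})
    return pd.DataFrame(rows)


def _write_manifest(config: RunConfig, outdir: pathlib.Path, bundle: dict) -> None:
    import scipy
    import statsmodels

    cfg = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "config": cfg,
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "outputs": {name: len(df) for name, df in bundle.items()},
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
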