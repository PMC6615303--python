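"""Synthetic pot-experiment generator.

Emulates a greenhouse pot study of hot pepper (*Capsicum annuum* L.)
irrigated with saline water: three irrigation-water salinities
(EC_iw = 0.9, 4.7, 7.0 dS m^-1) crossed with two target leaching
fractions (0.17, 0.29), four replicate pots per cell (24 pots in a
randomized block layout), spot gas exchange on three days after
transplanting (23, 39, 76 DAT), light- and CO2-response curves at the
standard instrument setpoints, end-of-season leaf isotope and biomass
assays, and a 24-event irrigation/weighing/drainage ledger per pot.

Default treatment means are anchored to published responses of hot
pepper to irrigation-water salinity under these conditions; only the
factor marginal means are published, so default cell means are an
additive reconstruction (EC-level mean plus the leaching-fraction
deviation from its own mean), with an ``interaction`` hook to inject
non-additive cell effects.  Spot P_n is tied to stomatal conductance
through the logarithmic link P_n = a + b*ln(g_s) that partial stomatal
closure produces, with the intercept chosen per cell so that noise-free
generation reproduces the configured cell means exactly.

All randomness flows from one master seed through
:class:`numpy.random.SeedSequence` children, so identical configuration
gives bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import isotope_metrics, photosynthesis_models as pm


class ConfigError(ValueError):
    """Invalid experiment-design or generation-model configuration."""


# ---------------------------------------------------------------------------
# design

DEFAULT_PPFD_SETPOINTS = (2000, 1500, 1000, 700, 400, 200, 100, 50, 20, 0)
DEFAULT_CO2_SETPOINTS = (400, 250, 150, 100, 50, 500, 700, 1000, 1500)
SPOT_PPFD = 1200.0  # umol m^-2 s^-1, light-saturating spot-measurement level
CHAMBER_CA = 400.0  # umol mol^-1 ambient CO2 in the cuvette


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout and measurement schedule of the emulated study."""

    ec_levels: tuple = (0.9, 4.7, 7.0)  # irrigation-water salinity, dS m^-1
    lf_levels: tuple = (0.17, 0.29)  # target leaching fractions
    n_replicates: int = 4
    measurement_days: tuple = (23, 39, 76)  # days after transplanting
    ppfd_setpoints: tuple = DEFAULT_PPFD_SETPOINTS
    co2_setpoints: tuple = DEFAULT_CO2_SETPOINTS
    rng_seed: int = 20150428
    leaves_per_day: int = 1  # spot leaves per pot per day (instrument takes 3-6 per treatment)

    def __post_init__(self) -> None:
        if not self.ec_levels or not self.lf_levels:
            raise ConfigError("ec_levels and lf_levels must be non-empty")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if any(not (0.0 <= lf < 1.0) for lf in self.lf_levels):
            raise ConfigError("leaching fractions must lie in [0, 1)")
        if any(q < 0 for q in self.ppfd_setpoints) or any(c < 0 for c in self.co2_setpoints):
            raise ConfigError("setpoints must be >= 0")
        if self.leaves_per_day < 1:
            raise ConfigError("leaves_per_day must be >= 1")

    @property
    def n_units(self) -> int:
        return len(self.ec_levels) * len(self.lf_levels) * self.n_replicates


# ---------------------------------------------------------------------------
# default calibration: factor marginal means of the emulated experiment

# per EC_iw level (dS m^-1)
_EC_MARGINALS = pd.DataFrame(
    {
        "pn": [21.2, 16.0, 13.2],  # umol m^-2 s^-1
        "gs": [0.81, 0.41, 0.32],  # mol m^-2 s^-1
        "ci_ca": [0.80, 0.74, 0.70],
        "alpha": [0.052, 0.047, 0.030],
        "pn_max": [19.9, 15.7, 8.6],
        "kappa": [0.53, 0.78, 0.83],
        "rd": [2.07, 1.78, 1.43],
        "epsilon": [0.224, 0.188, 0.109],
        "pn_sat": [61.0, 55.7, 42.8],
        "rp": [12.7, 11.2, 7.5],
        "big_delta13c": [23.61, 23.04, 22.17],  # per mil
        "c_content": [40.14, 38.54, 35.43],  # % DW
        "delta15n": [2.44, 2.68, 2.82],  # per mil
        "n_content": [4.24, 3.87, 3.40],  # % DW, consistent with N accumulation / biomass
        "leaf_biomass": [14.3, 9.8, 7.0],  # g plant^-1
        "root_biomass": [5.5, 3.4, 2.5],  # g plant^-1
        "na_content": [2.73, 8.53, 12.60],  # mg g^-1 DW in roots
    },
    index=pd.Index([0.9, 4.7, 7.0], name="ec_iw"),
)

# per leaching-fraction level
_LF_MARGINALS = pd.DataFrame(
    {
        "pn": [16.9, 17.5],
        "gs": [0.51, 0.56],
        "ci_ca": [0.75, 0.75],
        "alpha": [0.045, 0.042],
        "pn_max": [16.4, 14.2],
        "kappa": [0.64, 0.75],
        "rd": [1.68, 1.96],
        "epsilon": [0.179, 0.168],
        "pn_sat": [52.1, 54.2],
        "rp": [10.5, 10.4],
        "big_delta13c": [22.87, 23.09],
        "c_content": [36.71, 39.72],
        "delta15n": [2.69, 2.58],
        "n_content": [3.98, 3.92],
        "leaf_biomass": [9.6, 11.1],
        "root_biomass": [3.6, 4.1],
        "na_content": [8.51, 7.39],
    },
    index=pd.Index([0.17, 0.29], name="target_lf"),
)

#: default per-variable Gaussian noise standard deviations; values were
#: chosen once as plausible within-treatment leaf-to-leaf / pot-to-pot
#: spreads for this species and instrument.
DEFAULT_NOISE_SD = {
    "pn": 1.5,
    "gs": 0.06,
    "ci_ca": 0.03,
    "curve_pn": 0.5,  # additive noise on curve points, umol m^-2 s^-1
    "big_delta13c": 0.25,
    "c_content": 1.2,
    "n_content": 0.25,
    "delta15n": 0.20,
    "leaf_biomass": 1.0,
    "root_biomass": 0.5,
    "na_content": 0.8,
}

#: slope of the P_n = a + b*ln(g_s) link (umol m^-2 s^-1 per ln unit),
#: the between-salinity-level slope of the default calibration.
DEFAULT_PN_GS_SLOPE = 8.6


@dataclass(frozen=True)
class GenerationModel:
    """Cell means, noise levels and the P_n-g_s link used for generation.

    ``cell_means`` is indexed by (ec_iw, target_lf) with one column per
    generated variable; ``interaction`` entries (ec, lf) -> {var: delta}
    are added on top of the additive reconstruction.
    """

    cell_means: pd.DataFrame
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    pn_gs_slope: float = DEFAULT_PN_GS_SLOPE

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ConfigError("noise standard deviations must be >= 0")
        if (self.cell_means["gs"] <= 0).any() or (self.cell_means["pn"] <= 0).any():
            raise ConfigError("cell means for pn and gs must be positive")
        bad = (self.cell_means["kappa"] < 0) | (self.cell_means["kappa"] > 1)
        if bad.any():
            raise ConfigError("kappa cell means must lie in [0, 1]")

    @classmethod
    def default(
        cls,
        design: ExperimentDesign | None = None,
        noise_sd: dict | None = None,
        interaction: dict | None = None,
    ) -> "GenerationModel":
        """Additive reconstruction of cell means from the factor marginals.

        cell(ec, lf) = marginal(ec) + [marginal(lf) - mean over LF levels];
        this preserves the EC marginal means exactly and the LF contrasts
        exactly (the published marginal tables are not perfectly mutually
        consistent, so both cannot be preserved at once).  Clipped where a
        hard domain applies (kappa to [0, 1], positive rates).
        """
        design = design or ExperimentDesign()
        try:
            ec_marg = _EC_MARGINALS.loc[list(design.ec_levels)]
            lf_marg = _LF_MARGINALS.loc[list(design.lf_levels)]
        except KeyError as exc:
            raise ConfigError(
                "no default calibration for factor level "
                f"{exc.args[0]!r}; supply cell_means explicitly"
            ) from exc
        lf_dev = lf_marg - lf_marg.mean(axis=0)
        rows = {}
        for ec in design.ec_levels:
            for lf in design.lf_levels:
                cell = ec_marg.loc[ec] + lf_dev.loc[lf]
                if interaction and (ec, lf) in interaction:
                    for var, delta in interaction[(ec, lf)].items():
                        cell[var] = cell[var] + delta
                rows[(ec, lf)] = cell
        cm = pd.DataFrame(rows).T
        cm.index = pd.MultiIndex.from_tuples(cm.index, names=["ec_iw", "target_lf"])
        cm["kappa"] = cm["kappa"].clip(0.0, 1.0)
        for col in ("alpha", "pn_max", "rd", "epsilon", "pn_sat", "rp", "gs",
                    "leaf_biomass", "root_biomass", "na_content"):
            cm[col] = cm[col].clip(lower=1e-6)
        sd = dict(DEFAULT_NOISE_SD)
        if noise_sd:
            sd.update(noise_sd)
        return cls(cell_means=cm, noise_sd=sd)

    def noise_free(self) -> "GenerationModel":
        """Copy of the model with every noise SD set to zero."""
        return replace(self, noise_sd={k: 0.0 for k in self.noise_sd})


# ---------------------------------------------------------------------------
# seeding

def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _rng_for(design: ExperimentDesign, stream: int) -> np.random.Generator:
    # fixed stream layout: 0 design, 1 gas exchange, 2 light curves,
    # 3 co2 curves, 4 isotopes, 5 irrigation
    return _child_rngs(design.rng_seed, 6)[stream]


def _truncated_normal(rng, mean, sd, low, high=np.inf, size=None):
    """Gaussian draw truncated by rejection (vectorised resampling)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), np.shape(mean) if size is None else size)
    out = rng.normal(mean, sd)
    for _ in range(1000):
        bad = (out < low) | (out > high)
        if not bad.any():
            break
        out = np.where(bad, rng.normal(mean, sd), out)
    return np.clip(out, low, high)


# ---------------------------------------------------------------------------
# generators

def generate_design(config: ExperimentDesign | None = None) -> pd.DataFrame:
    """Unit table: one row per pot with treatment and block labels.

    Replicate r of every treatment combination sits in block r, the usual
    randomized-complete-block layout; pot order within a block is shuffled
    deterministically from the design seed.
    """
    config = config or ExperimentDesign()
    rng = _rng_for(config, 0)
    rows = []
    for block in range(1, config.n_replicates + 1):
        cells = [(ec, lf) for ec in config.ec_levels for lf in config.lf_levels]
        order = rng.permutation(len(cells))
        for ec, lf in (cells[i] for i in order):
            rows.append({"ec_iw": ec, "target_lf": lf, "block": block})
    units = pd.DataFrame(rows)
    units.insert(0, "pot_id", [f"P{i + 1:02d}" for i in range(len(units))])
    return units


def _cell_lookup(model: GenerationModel, units: pd.DataFrame) -> pd.DataFrame:
    try:
        return model.cell_means.loc[
            pd.MultiIndex.from_frame(units[["ec_iw", "target_lf"]])
        ].set_index(units.index)
    except KeyError as exc:
        raise ConfigError(f"no cell means for treatment {exc.args[0]!r}") from exc


def generate_spot_gas_exchange(
    units: pd.DataFrame,
    model: GenerationModel,
    days=(23, 39, 76),
    leaves_per_day: int = 1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Spot gas-exchange table: one row per pot x day x leaf.

    g_s is drawn from a positivity-truncated Gaussian around the cell
    mean; P_n follows the logarithmic link
    P_n = pn_cell + b*(ln g_s - ln gs_cell) + noise, so pooled data show
    the saturating P_n-g_s relationship.  C_i is (C_i/C_a) * C_a with
    C_a held at the 400 umol mol^-1 chamber setpoint.  With all noise
    SDs zero every row equals its cell means exactly.
    """
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(0 if seed is None else seed))
    cells = _cell_lookup(model, units)
    sd = model.noise_sd
    rows = []
    for day in days:
        for leaf in range(1, leaves_per_day + 1):
            gs_mean = cells["gs"].to_numpy()
            if sd.get("gs", 0) > 0:
                gs = _truncated_normal(rng, gs_mean, sd["gs"], low=1e-4)
            else:
                gs = gs_mean.copy()
            pn = (
                cells["pn"].to_numpy()
                + model.pn_gs_slope * (np.log(gs) - np.log(gs_mean))
                + (rng.normal(0.0, sd["pn"], len(units)) if sd.get("pn", 0) > 0 else 0.0)
            )
            ci_ca = cells["ci_ca"].to_numpy() + (
                rng.normal(0.0, sd["ci_ca"], len(units)) if sd.get("ci_ca", 0) > 0 else 0.0
            )
            ci_ca = np.clip(ci_ca, 0.0, 1.2)
            rows.append(
                pd.DataFrame(
                    {
                        "pot_id": units["pot_id"],
                        "ec_iw": units["ec_iw"],
                        "target_lf": units["target_lf"],
                        "day": day,
                        "leaf": leaf,
                        "ppfd": SPOT_PPFD,
                        "ca": CHAMBER_CA,
                        "ci": ci_ca * CHAMBER_CA,
                        "gs": gs,
                        "pn": pn,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def generate_curve_data(
    units: pd.DataFrame,
    model: GenerationModel,
    kind: str,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    setpoints=None,
) -> pd.DataFrame:
    """Response-curve table: one P_n per pot and setpoint.

    ``kind`` is ``'light'`` (P_n vs PPFD, non-rectangular hyperbola) or
    ``'co2'`` (P_n vs C_i).  Each pot's generating parameters are its
    cell means; points are forward model evaluations plus Gaussian noise
    of SD ``noise_sd['curve_pn']`` (zero gives exact model curves).
    """
    if kind not in ("light", "co2"):
        raise ValueError(f"unknown curve kind {kind!r}; expected 'light' or 'co2'")
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(0 if seed is None else seed))
    if setpoints is None:
        setpoints = DEFAULT_PPFD_SETPOINTS if kind == "light" else DEFAULT_CO2_SETPOINTS
    setpoints = np.asarray(setpoints, dtype=float)
    cells = _cell_lookup(model, units)
    sd = model.noise_sd.get("curve_pn", 0.0)
    rows = []
    for idx, unit in units.iterrows():
        cell = cells.loc[idx]
        if kind == "light":
            params = pm.LightResponseParams(
                alpha=cell["alpha"], pn_max=cell["pn_max"], kappa=cell["kappa"], rd=cell["rd"]
            )
            pn = pm.eval_light_response(params, setpoints)
        else:
            params = pm.CO2ResponseParams(
                epsilon=cell["epsilon"], pn_sat=cell["pn_sat"], rp=cell["rp"]
            )
            pn = pm.eval_co2_response(params, setpoints)
        if sd > 0:
            pn = pn + rng.normal(0.0, sd, len(setpoints))
        rows.append(
            pd.DataFrame(
                {
                    "pot_id": unit["pot_id"],
                    "ec_iw": unit["ec_iw"],
                    "target_lf": unit["target_lf"],
                    "setpoint": setpoints,
                    "pn": pn,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_isotope_table(
    units: pd.DataFrame,
    model: GenerationModel,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """End-of-season leaf assay table: one row per pot.

    delta13C is generated by inverting the discrimination relation from
    the cell-mean Delta13C (source air at -8 per mil), so recomputing
    Delta13C downstream recovers the configured mean in noise-free mode.
    Total C and N accumulations are enforced as content x biomass for
    every row.
    """
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(0 if seed is None else seed))
    cells = _cell_lookup(model, units)
    sd = model.noise_sd
    n = len(units)

    def draw(col, low=None, high=None):
        mean = cells[col].to_numpy()
        s = sd.get(col, 0.0)
        if s == 0:
            out = mean.copy()
        elif low is None:
            out = rng.normal(mean, s)
        else:
            out = _truncated_normal(rng, mean, s, low=low, high=np.inf if high is None else high)
        return out

    big_delta = draw("big_delta13c")
    c_content = draw("c_content", low=1e-6, high=100.0 - 1e-6)
    n_content = draw("n_content", low=1e-6, high=100.0 - 1e-6)
    if np.any((c_content <= 0) | (c_content >= 100) | (n_content <= 0) | (n_content >= 100)):
        raise ConfigError("element contents must lie strictly inside (0, 100) % DW")
    leaf_biomass = draw("leaf_biomass", low=0.0)
    root_biomass = draw("root_biomass", low=0.0)
    return pd.DataFrame(
        {
            "pot_id": units["pot_id"],
            "ec_iw": units["ec_iw"],
            "target_lf": units["target_lf"],
            "delta13c_permil": isotope_metrics.invert_big_delta13c(big_delta),
            "delta15n_permil": draw("delta15n"),
            "c_content_pct": c_content,
            "n_content_pct": n_content,
            "leaf_dry_biomass_g": leaf_biomass,
            "root_dry_biomass_g": root_biomass,
            "na_content_mg_g": draw("na_content", low=0.0),
            "total_c_g": c_content / 100.0 * leaf_biomass,
            "total_n_g": n_content / 100.0 * leaf_biomass,
        }
    )


def default_et_trajectory(n_events: int = 24, start: float = 300.0, end: float = 1500.0):
    """Per-event ET (g) ramping linearly with canopy growth over the season."""
    if n_events < 1:
        raise ConfigError("need at least one irrigation event")
    if start <= 0 or end <= 0:
        raise ConfigError("ET must be positive")
    return np.linspace(start, end, n_events)


def generate_irrigation_ledger(
    units: pd.DataFrame,
    season_events: int = 24,
    et_trajectory=None,
    rho: float = 1000.0,
    initial_weight_g: float = 12000.0,
) -> pd.DataFrame:
    """Irrigation/weighing/drainage ledger: ``season_events`` rows per pot.

    Events are constructed to be exactly self-consistent under the water
    balance: applied water follows the leaching scheduler
    AW = ET / (rho * (1 - LF)) for the pot's target LF, drainage is
    LF * AW, and successive weights satisfy
    W_{n+1} = W_n + (AW - D) * rho - ET (which keeps weight constant when
    the scheduler exactly replaces ET plus leaching).  Recomputing ET from
    the ledger therefore returns the input trajectory exactly, and the
    seasonal drainage/applied ratio equals the target LF.
    """
    if et_trajectory is None:
        et_trajectory = default_et_trajectory(season_events)
    et = np.asarray(et_trajectory, dtype=float)
    if et.size != season_events:
        raise ConfigError("et_trajectory length must equal season_events")
    if np.any(et <= 0):
        raise ConfigError("ET trajectory must be positive")
    frames = []
    for _, unit in units.iterrows():
        lf = float(unit["target_lf"])
        if not 0.0 <= lf < 1.0:
            raise ConfigError(f"target LF {lf} outside [0, 1)")
        aw = et / rho / (1.0 - lf)
        drainage = lf * aw
        w = np.empty(season_events + 1)
        w[0] = initial_weight_g
        for n in range(season_events):
            w[n + 1] = w[n] + (aw[n] - drainage[n]) * rho - et[n]
        frames.append(
            pd.DataFrame(
                {
                    "pot_id": unit["pot_id"],
                    "ec_iw": unit["ec_iw"],
                    "target_lf": lf,
                    "event_index": np.arange(1, season_events + 1),
                    "w_before_g": w[:-1],
                    "w_next_g": w[1:],
                    "applied_L": aw,
                    "drainage_L": drainage,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate(
    design: ExperimentDesign | None = None,
    model: GenerationModel | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate the full synthetic experiment as a dict of tidy tables.

    Keys: units, gas_exchange, light_curves, co2_curves, isotopes,
    irrigation.  Per-table RNG streams are spawned from the design seed,
    so the bundle is reproducible bit-for-bit.
    """
    design = design or ExperimentDesign()
    model = model or GenerationModel.default(design)
    rngs = _child_rngs(design.rng_seed, 6)
    units = generate_design(design)
    return {
        "units": units,
        "gas_exchange": generate_spot_gas_exchange(
            units, model, days=design.measurement_days,
            leaves_per_day=design.leaves_per_day, rng=rngs[1],
        ),
        "light_curves": generate_curve_data(
            units, model, "light", rng=rngs[2], setpoints=design.ppfd_setpoints
        ),
        "co2_curves": generate_curve_data(
            units, model, "co2", rng=rngs[3], setpoints=design.co2_setpoints
        ),
        "isotopes": generate_isotope_table(units, model, rng=rngs[4]),
        "irrigation": generate_irrigation_ledger(units),
    }


def write_tables(tables: dict[str, pd.DataFrame], outdir) -> list[str]:
    """Write each table of :func:`simulate` to ``<outdir>/<name>.csv``."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(str(path))
    return written
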