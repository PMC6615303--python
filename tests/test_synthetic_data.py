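"""Synthetic experiment generator: design, determinism and closure."""

import numpy as np
import pandas as pd
import pytest

from pepperphys import (
    isotope_metrics as im,
    photosynthesis_models as pm,
    synthetic_data as sd,
    water_balance as wb,
)


class TestDesign:
    def test_default_is_24_pots(self, default_units):
        assert len(default_units) == 24

    def test_every_cell_has_four_replicates(self, default_units):
        counts = default_units.groupby(["ec_iw", "target_lf"]).size()
        assert (counts == 4).all() and len(counts) == 6

    def test_blocks_are_complete(self, default_units):
        per_block = default_units.groupby("block").size()
        assert (per_block == 6).all()

    @pytest.mark.parametrize(
        "ec, lf, rep, expected",
        [((0.9,), (0.17,), 1, 1), ((0.9, 4.7), (0.17, 0.2, 0.29), 5, 30)],
    )
    def test_product_rule(self, ec, lf, rep, expected):
        # non-default levels have no calibrated means; the design layer
        # only needs the factor lists
        cfg = sd.ExperimentDesign(ec_levels=ec, lf_levels=lf, n_replicates=rep)
        assert len(sd.generate_design(cfg)) == expected

    def test_empty_factor_list_rejected(self):
        with pytest.raises(sd.ConfigError):
            sd.ExperimentDesign(ec_levels=())

    def test_lf_at_or_above_one_rejected(self):
        with pytest.raises(sd.ConfigError):
            sd.ExperimentDesign(lf_levels=(0.17, 1.0))

    def test_deterministic_for_fixed_seed(self):
        a = sd.generate_design(sd.ExperimentDesign(rng_seed=5))
        b = sd.generate_design(sd.ExperimentDesign(rng_seed=5))
        pd.testing.assert_frame_equal(a, b)


class TestGenerationModel:
    def test_cell_means_preserve_ec_marginals(self, noise_free_model):
        cm = noise_free_model.cell_means
        ec_marg = cm.groupby(level="ec_iw")[["pn", "gs", "pn_max"]].mean()
        assert ec_marg.loc[0.9, "pn"] == pytest.approx(21.2)
        assert ec_marg.loc[7.0, "gs"] == pytest.approx(0.32)
        assert ec_marg.loc[4.7, "pn_max"] == pytest.approx(15.7)

    def test_cell_means_preserve_lf_contrasts(self, noise_free_model):
        cm = noise_free_model.cell_means
        lf_marg = cm.groupby(level="target_lf")["leaf_biomass"].mean()
        assert lf_marg[0.29] - lf_marg[0.17] == pytest.approx(11.1 - 9.6)

    def test_interaction_hook_shifts_one_cell(self, default_design):
        model = sd.GenerationModel.default(
            default_design, interaction={(0.9, 0.17): {"pn": 2.0}}
        )
        base = sd.GenerationModel.default(default_design)
        diff = model.cell_means["pn"] - base.cell_means["pn"]
        assert diff.loc[(0.9, 0.17)] == pytest.approx(2.0)
        assert (diff.drop(index=(0.9, 0.17)) == 0).all()

    def test_negative_noise_sd_rejected(self, default_design):
        with pytest.raises(sd.ConfigError):
            sd.GenerationModel.default(default_design, noise_sd={"pn": -1.0})

    def test_kappa_clipped_into_unit_interval(self, default_design):
        model = sd.GenerationModel.default(
            default_design, interaction={(7.0, 0.29): {"kappa": 5.0}}
        )
        assert model.cell_means["kappa"].between(0, 1).all()


class TestSpotGasExchange:
    def test_noise_free_rows_equal_cell_means(self, default_units, noise_free_model):
        obs = sd.generate_spot_gas_exchange(default_units, noise_free_model, seed=1)
        merged = obs.merge(
            noise_free_model.cell_means.reset_index(), on=["ec_iw", "target_lf"],
            suffixes=("", "_cell"),
        )
        np.testing.assert_allclose(merged["pn"], merged["pn_cell"], atol=1e-12)
        np.testing.assert_allclose(merged["gs"], merged["gs_cell"], atol=1e-12)
        np.testing.assert_allclose(merged["ci"] / merged["ca"], merged["ci_ca"], atol=1e-12)

    def test_one_row_per_pot_day_leaf(self, default_units, noise_free_model):
        obs = sd.generate_spot_gas_exchange(
            default_units, noise_free_model, days=(23, 39, 76), leaves_per_day=3, seed=1
        )
        assert len(obs) == 24 * 3 * 3

    def test_determinism_bit_for_bit(self, default_design):
        t1 = sd.simulate(default_design)
        t2 = sd.simulate(default_design)
        for name in t1:
            pd.testing.assert_frame_equal(t1[name], t2[name])

    def test_sample_mean_approaches_cell_mean(self, default_design):
        # CLT check: sd(pn)=1, n=200 per cell -> cell sample mean within 0.2
        units = sd.generate_design(
            sd.ExperimentDesign(n_replicates=200, rng_seed=default_design.rng_seed)
        )
        model = sd.GenerationModel.default(default_design, noise_sd={
            **{k: 0.0 for k in sd.DEFAULT_NOISE_SD}, "pn": 1.0,
        })
        obs = sd.generate_spot_gas_exchange(units, model, days=(23,), seed=2)
        got = obs.groupby(["ec_iw", "target_lf"])["pn"].mean()
        expected = model.cell_means["pn"]
        assert np.all(np.abs(got - expected.loc[got.index]) < 0.2)

    def test_generated_conductance_positive(self, default_units, default_design):
        model = sd.GenerationModel.default(default_design, noise_sd={"gs": 0.5})
        obs = sd.generate_spot_gas_exchange(default_units, model, seed=3)
        assert (obs["gs"] > 0).all()


class TestCurveData:
    def test_light_curve_dark_point(self, default_units, noise_free_model):
        pot = default_units[default_units.ec_iw == 0.9].iloc[[0]]
        curve = sd.generate_curve_data(pot, noise_free_model, "light", seed=1)
        lf = pot["target_lf"].iloc[0]
        rd_cell = noise_free_model.cell_means.loc[(0.9, lf), "rd"]
        dark = curve.loc[curve["setpoint"] == 0.0, "pn"].iloc[0]
        assert dark == pytest.approx(-rd_cell, abs=1e-12)

    def test_co2_curve_would_emit_minus_rp_at_zero(self, default_units, noise_free_model):
        pot = default_units[default_units.ec_iw == 0.9].iloc[[0]]
        curve = sd.generate_curve_data(
            pot, noise_free_model, "co2", seed=1, setpoints=(0.0, 100.0, 400.0, 1500.0)
        )
        lf = pot["target_lf"].iloc[0]
        rp_cell = noise_free_model.cell_means.loc[(0.9, lf), "rp"]
        assert curve.loc[curve["setpoint"] == 0.0, "pn"].iloc[0] == pytest.approx(-rp_cell)

    def test_unknown_kind_rejected(self, default_units, noise_free_model):
        with pytest.raises(ValueError, match="unknown curve kind"):
            sd.generate_curve_data(default_units, noise_free_model, "aci")

    def test_noise_free_round_trip_recovers_generators(self, default_units, noise_free_model):
        curves = sd.generate_curve_data(default_units, noise_free_model, "light", seed=1)
        cells = noise_free_model.cell_means
        for (ec, lf), sub in curves.groupby(["ec_iw", "target_lf"]):
            one_pot = sub[sub.pot_id == sub.pot_id.iloc[0]]
            fit = pm.fit_light_response(one_pot["setpoint"], one_pot["pn"])
            truth = cells.loc[(ec, lf), ["alpha", "pn_max", "kappa", "rd"]].to_numpy(float)
            np.testing.assert_allclose(fit.params.as_array(), truth, rtol=1e-6)


class TestIsotopeTable:
    def test_noise_free_delta13c_matches_configured_discrimination(
        self, default_units, noise_free_model
    ):
        iso = sd.generate_isotope_table(default_units, noise_free_model, seed=1)
        back = im.big_delta13c(iso["delta13c_permil"])
        cells = noise_free_model.cell_means
        expected = cells.loc[
            pd.MultiIndex.from_frame(iso[["ec_iw", "target_lf"]]), "big_delta13c"
        ].to_numpy()
        np.testing.assert_allclose(back, expected, atol=1e-9)

    def test_accumulations_are_content_times_biomass(self, default_units, default_design):
        model = sd.GenerationModel.default(default_design)
        iso = sd.generate_isotope_table(default_units, model, seed=4)
        np.testing.assert_allclose(
            iso["total_c_g"], iso["c_content_pct"] / 100 * iso["leaf_dry_biomass_g"],
            atol=1e-12,
        )

    def test_zero_biomass_gives_zero_accumulation(self, default_design, default_units):
        model = sd.GenerationModel.default(default_design, interaction={
            (ec, lfv): {"leaf_biomass": -100.0}
            for ec in default_design.ec_levels for lfv in default_design.lf_levels
        })
        iso = sd.generate_isotope_table(default_units, model.noise_free(), seed=1)
        assert (iso["leaf_dry_biomass_g"] <= 1e-6).all()
        assert np.allclose(iso["total_c_g"], 0.0, atol=1e-6)


class TestIrrigationLedger:
    def test_default_event_count(self, default_units):
        ledger = sd.generate_irrigation_ledger(default_units)
        assert (ledger.groupby("pot_id").size() == 24).all()

    def test_zero_target_lf_means_no_drainage(self, default_units):
        units = default_units.assign(target_lf=0.0)
        ledger = sd.generate_irrigation_ledger(units)
        assert (ledger["drainage_L"] == 0.0).all()

    def test_recomputed_et_equals_input_trajectory(self, default_units):
        traj = sd.default_et_trajectory(24)
        ledger = sd.generate_irrigation_ledger(default_units, et_trajectory=traj)
        for _, sub in ledger.groupby("pot_id"):
            et = wb.compute_et(
                sub["w_before_g"], sub["w_next_g"], sub["applied_L"], sub["drainage_L"]
            )
            np.testing.assert_allclose(et, traj, atol=1e-9)

    def test_lf_of_one_rejected(self, default_units):
        units = default_units.assign(target_lf=1.0)
        with pytest.raises(sd.ConfigError):
            sd.generate_irrigation_ledger(units)


class TestClosure:
    def test_full_noise_free_pipeline_reproduces_cell_means(self, noise_free_tables,
                                                            noise_free_model):
        # downstream treatment means equal the configured generator means
        gx = noise_free_tables["gas_exchange"]
        got = gx.groupby(["ec_iw", "target_lf"])[["pn", "gs"]].mean()
        cells = noise_free_model.cell_means
        np.testing.assert_allclose(got["pn"], cells.loc[got.index, "pn"], atol=1e-9)
        np.testing.assert_allclose(got["gs"], cells.loc[got.index, "gs"], atol=1e-9)

    def test_tables_are_balanced(self, noise_free_tables):
        for name in ("gas_exchange", "light_curves", "co2_curves", "isotopes"):
            counts = noise_free_tables[name].groupby(["ec_iw", "target_lf"]).size()
            assert counts.nunique() == 1, name
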