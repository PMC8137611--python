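import numpy as np
import pytest

from qstox.crypt import (
    ARREST,
    DIFF,
    EMPTY,
    PROLIF,
    STEM,
    AbmTimeSeries,
    CryptConfig,
    InjurySpec,
    apply_injury,
    init_crypt,
    recovery_time,
    run_scenario,
    step,
)


class TestConfig:
    def test_defaults(self):
        cfg = CryptConfig()
        assert cfg.n_columns == 16 and cfg.n_rows == 30
        assert cfg.stem_band == (0, 4) and cfg.ta_band == (5, 20)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"stem_band": (0, 5), "ta_band": (5, 20)},  # overlapping bands
            {"ta_band": (5, 30)},  # beyond lattice
            {"cycle_time_mean": 0.0},
            {"cycle_time_jitter": 1.0},
            {"dt": 5.0},  # > min cycle / 10
            {"villus_init": -1.0},
            {"burn_in": -1.0},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            CryptConfig(**kwargs)

    def test_dict_round_trip(self):
        cfg = CryptConfig(seed=7, villus_shed_rate=11.0)
        assert CryptConfig.from_dict(cfg.to_dict()) == cfg
        with pytest.raises(ValueError, match="unknown"):
            CryptConfig.from_dict({"bogus": 1})


class TestInjurySpec:
    def test_json_round_trip(self, tmp_path):
        inj = InjurySpec(0.85, (5, 12), 0.0, method="exact")
        path = tmp_path / "inj.json"
        inj.to_json(path)
        assert InjurySpec.from_json(path) == inj

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"arrest_fraction": 1.5},
            {"target_band": (12, 5)},
            {"time": -1.0},
            {"method": "magic"},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            InjurySpec(**kwargs)


class TestInit:
    def test_band_layout_without_burn_in(self, fixed_rate_config):
        cs = init_crypt(fixed_rate_config, burn_in=False)
        assert (cs.cell_state[0:5] == STEM).all()
        assert (cs.cell_state[5:21] == PROLIF).all()
        assert (cs.cell_state[21:] == DIFF).all()
        assert cs.crypt_count == 16 * 30
        assert cs.villus == pytest.approx(770.0)
        assert cs.time == 0.0

    def test_burn_in_requires_shed_rate(self):
        with pytest.raises(ValueError, match="shed_rate"):
            init_crypt(CryptConfig(), burn_in=False)

    def test_residual_clocks_within_cycle(self, fixed_rate_config):
        cs = init_crypt(fixed_rate_config, burn_in=False)
        prolif = cs.cell_state == PROLIF
        assert (cs.clock[prolif] >= 0).all()
        assert (cs.clock[prolif] <= fixed_rate_config.cycle_time_mean).all()


class TestDivision:
    def test_full_column_push_transfers_top_cell_to_villus(self, bare_crypt):
        cs = bare_crypt
        before = cs.villus
        cs.clock[10, 0] = 0.1
        step(cs, 0.5)
        assert cs.last_influx == 1
        assert cs.villus == pytest.approx(before + 1 - cs.shed_rate * 0.5)
        assert cs.crypt_count == 16 * 30  # column stays full
        assert cs.cell_state[10, 0] == PROLIF and cs.clock[10, 0] > 0

    def test_push_stops_at_first_vacancy(self, bare_crypt):
        cs = bare_crypt
        cs.cell_state[25, 1] = EMPTY
        before = cs.villus
        cs.clock[10, 1] = 0.1
        step(cs, 0.5)
        assert cs.last_influx == 0  # vacancy absorbed the push
        assert cs.villus == pytest.approx(before - cs.shed_rate * 0.5)
        assert cs.cell_state[25, 1] != EMPTY
        assert (cs.cell_state[:, 1] != EMPTY).all()

    def test_stem_promoted_when_pushed_out_of_niche(self, bare_crypt):
        cs = bare_crypt
        cs.clock[4, 2] = 0.1  # top stem row divides
        step(cs, 0.5)
        assert cs.cell_state[4, 2] == STEM  # daughter keeps the niche identity
        assert cs.cell_state[5, 2] == PROLIF  # pushed mother differentiates a step

    def test_prolif_pushed_past_ta_top_differentiates(self, bare_crypt):
        cs = bare_crypt
        cs.clock[20, 3] = 0.1  # top TA row divides
        step(cs, 0.5)
        assert cs.cell_state[20, 3] == PROLIF
        assert cs.cell_state[21, 3] == DIFF and cs.clock[21, 3] == 0.0

    def test_arrested_cells_are_pushed_passively(self, bare_crypt):
        cs = bare_crypt
        cs.cell_state[10, 4] = ARREST
        cs.arrest_age[10, 4] = 5.0
        cs.clock[5, 4] = 0.1
        step(cs, 0.5)
        assert cs.cell_state[11, 4] == ARREST
        assert cs.arrest_age[11, 4] == pytest.approx(5.5)  # age advanced by dt


class TestSenescence:
    def test_removal_collapses_column_downward(self, bare_crypt):
        cs = bare_crypt
        marker_above = cs.cell_state[11, 5]
        cs.cell_state[10, 5] = ARREST
        cs.arrest_age[10, 5] = cs.config.arrested_lifetime - 0.25
        step(cs, 0.5)
        assert cs.senescence_removals == 1
        assert cs.cell_state[10, 5] == marker_above  # collapsed down by one
        assert cs.cell_state[-1, 5] == EMPTY  # transient vacancy at the top
        assert cs.crypt_count == 16 * 30 - 1

    def test_young_arrested_cells_survive(self, bare_crypt):
        cs = bare_crypt
        cs.cell_state[10, 6] = ARREST
        step(cs, 0.5)
        assert cs.cell_state[10, 6] == ARREST
        assert cs.senescence_removals == 0


class TestStep:
    def test_villus_decays_without_divisions(self, bare_crypt):
        cs = bare_crypt  # all clocks frozen: no divisions possible
        v0 = cs.villus
        for _ in range(10):
            step(cs, 0.5)
            assert cs.last_influx == 0
        assert cs.villus == pytest.approx(v0 - cs.shed_rate * 5.0)

    def test_flux_bookkeeping_exact(self, fixed_rate_config):
        cs = init_crypt(fixed_rate_config, burn_in=False)
        for _ in range(200):
            v_before = cs.villus
            step(cs)
            assert cs.villus == pytest.approx(v_before + cs.last_influx - cs.last_shed)

    def test_dt_too_large_rejected(self, bare_crypt):
        with pytest.raises(ValueError, match="dt"):
            step(bare_crypt, 5.0)

    def test_copy_is_independent_and_deterministic(self, fixed_rate_config):
        a = init_crypt(fixed_rate_config, burn_in=False)
        b = a.copy()
        for _ in range(50):
            step(a)
            step(b)
        assert np.array_equal(a.cell_state, b.cell_state)
        assert a.villus == b.villus


class TestInjury:
    def test_zero_fraction_is_noop(self, bare_crypt):
        before = bare_crypt.cell_state.copy()
        apply_injury(bare_crypt, InjurySpec(0.0, (5, 12)))
        assert np.array_equal(bare_crypt.cell_state, before)

    def test_exact_full_fraction_arrests_whole_band(self, bare_crypt):
        apply_injury(bare_crypt, InjurySpec(1.0, (5, 12), method="exact"))
        assert (bare_crypt.cell_state[5:13] == ARREST).all()
        assert (bare_crypt.cell_state[0:5] == STEM).all()  # stem cells untouched
        assert (bare_crypt.cell_state[13:21] == PROLIF).all()  # outside band untouched
        assert (bare_crypt.arrest_age[5:13] == 0.0).all()
        assert (bare_crypt.clock[5:13] == 0.0).all()

    def test_bernoulli_fraction_plausible(self, bare_crypt):
        apply_injury(bare_crypt, InjurySpec(0.85, (5, 12)))
        n_band = 8 * 16
        hits = int((bare_crypt.cell_state[5:13] == ARREST).sum())
        # binomial(128, 0.85): mean 108.8, sd ~4; allow +/- 6 sd
        assert 85 <= hits <= 128

    def test_band_outside_ta_rejected(self, bare_crypt):
        with pytest.raises(ValueError, match="TA band"):
            apply_injury(bare_crypt, InjurySpec(0.85, (3, 12)))


class TestScenario:
    def test_seed_determinism(self, fixed_rate_config):
        inj = InjurySpec(0.85, (5, 12))
        a = run_scenario(fixed_rate_config, inj, horizon=60.0)
        b = run_scenario(fixed_rate_config, inj, horizon=60.0)
        assert np.array_equal(a.ta_proliferative_count, b.ta_proliferative_count)
        assert np.array_equal(a.villus_count, b.villus_count)

    def test_different_seeds_differ(self, fixed_rate_config):
        import dataclasses

        inj = InjurySpec(0.85, (5, 12))
        a = run_scenario(fixed_rate_config, inj, horizon=60.0)
        b = run_scenario(dataclasses.replace(fixed_rate_config, seed=43), inj, horizon=60.0)
        assert not np.array_equal(a.ta_proliferative_count, b.ta_proliferative_count)

    def test_injury_depletes_ta_band(self, fixed_rate_config):
        series = run_scenario(fixed_rate_config, InjurySpec(0.85, (5, 12)), horizon=60.0)
        pre = series.pre_injury_mean()
        just_after = series.ta_proliferative_count[series.times >= series.injury_time][1]
        assert just_after < 0.6 * pre

    def test_homeostasis_default_calibrated_config(self):
        # full calibrated config: villus stays within 10% of its initial size
        # and the crypt stays full over a 240 h uninjured run
        series = run_scenario(CryptConfig(seed=7), None, horizon=240.0)
        v0 = series.villus_count[0]
        assert np.abs(series.villus_count / v0 - 1.0).max() < 0.10
        assert (series.crypt_count == 16 * 30).all()
        lo, hi = (5, 20)
        assert series.ta_proliferative_count.min() > 0.8 * 16 * (hi - lo + 1)

    def test_csv_outputs(self, fixed_rate_config, tmp_path):
        import pandas as pd

        series = run_scenario(fixed_rate_config, InjurySpec(0.85, (5, 12)), horizon=30.0)
        p1, p2 = tmp_path / "ts.csv", tmp_path / "profile.csv"
        series.to_csv(p1)
        series.profile_to_csv(p2)
        df = pd.read_csv(p1)
        assert list(df.columns) == ["time_h", "crypt_cells", "villus_cells", "ta_proliferative_cells"]
        prof = pd.read_csv(p2)
        assert prof.shape[1] == 1 + fixed_rate_config.n_rows

    def test_horizon_must_exceed_injury_time(self, fixed_rate_config):
        with pytest.raises(ValueError, match="horizon"):
            run_scenario(fixed_rate_config, InjurySpec(0.85, (5, 12), time=100.0), horizon=50.0)


class TestRecoveryTime:
    def _series(self, counts, injury_time=10.0):
        t = np.arange(len(counts), dtype=float)
        return AbmTimeSeries(
            times=t,
            crypt_count=np.full(len(counts), 480),
            villus_count=np.full(len(counts), 700.0),
            ta_proliferative_count=np.asarray(counts, dtype=float),
            per_row_proliferative_fraction=np.zeros((len(counts), 30)),
            injury_time=injury_time,
        )

    def test_simple_recovery(self):
        counts = [100.0] * 10 + [40.0] * 20 + [100.0] * 70
        series = self._series(counts)
        # drops at t=10, returns at t=30 and holds: recovery 20 h after injury
        assert recovery_time(series) == pytest.approx(20.0)

    def test_transient_touch_does_not_count(self):
        counts = [100.0] * 10 + [40.0] * 10 + [100.0] + [40.0] * 20 + [100.0] * 59
        series = self._series(counts)
        assert recovery_time(series) == pytest.approx(31.0)

    def test_never_recovered_is_none(self):
        counts = [100.0] * 10 + [40.0] * 90
        assert recovery_time(self._series(counts)) is None

    def test_requires_injury(self):
        series = self._series([100.0] * 20)
        object.__setattr__(series, "injury_time", None)
        with pytest.raises(ValueError):
            recovery_time(series)
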