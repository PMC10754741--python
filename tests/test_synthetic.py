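"""Synthetic campaign generator: moment recovery, censoring, trajectory
geometry and the daily risk driver."""

import numpy as np
import pandas as pd
import pytest

from riskpm import (
    GeneratorSpec,
    TrajectorySpec,
    gen_concentrations,
    gen_risk_days,
    gen_trajectories,
    lognormal_params,
    plant_episodes,
    summarize_zone,
)
from riskpm.datatypes import ValidationError


class TestConcentrations:
    def test_sd_zero_constant_series_uncensored(self):
        spec = GeneratorSpec(targets={("North", "Zn"): (50.0, 0.0)},
                             lod={"Zn": 10.0}, n_days=20, seed=1)
        df = gen_concentrations(spec)
        assert (df["value_ng_m3"] == 50.0).all()
        assert not df["censored"].any()

    def test_moment_matched_mean_recovered_within_3_se(self):
        mean, sd, n = 104.16, 66.28, 10_000
        spec = GeneratorSpec(targets={("North", "Cr(VI)"): (mean, sd)},
                             n_days=n, seed=2)
        df = gen_concentrations(spec)
        se = sd / np.sqrt(n)
        assert abs(df["value_ng_m3"].mean() - mean) < 3 * se
        assert abs(df["value_ng_m3"].std(ddof=1) - sd) < 5 * se

    def test_summarize_recovers_generator_targets(self):
        mean, sd, n = 104.16, 66.28, 10_000
        spec = GeneratorSpec(targets={("North", "Cr(VI)"): (mean, sd)},
                             n_days=n, seed=3)
        out = summarize_zone(gen_concentrations(spec), "zero")
        assert abs(out.loc[0, "mean"] - mean) < 3 * sd / np.sqrt(n)

    def test_lod_above_all_draws_fully_censored(self):
        spec = GeneratorSpec(targets={("North", "As"): (10.0, 2.0)},
                             lod={"As": 1e6}, n_days=30, seed=4)
        assert gen_concentrations(spec)["censored"].all()

    def test_moment_matching_formula(self):
        mu, sigma = lognormal_params(104.16, 66.28)
        assert np.exp(mu + sigma ** 2 / 2) == pytest.approx(104.16)
        var = (np.exp(sigma ** 2) - 1) * np.exp(2 * mu + sigma ** 2)
        assert np.sqrt(var) == pytest.approx(66.28)

    def test_mean_zero_with_sd_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorSpec(targets={("North", "Zn"): (0.0, 1.0)})

    def test_seeded_determinism_byte_identical(self, tmp_path):
        from riskpm import io
        spec = GeneratorSpec(targets={("North", "Zn"): (50.0, 10.0)},
                             n_days=30, seed=5)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        io.write_measurements(gen_concentrations(spec), p1)
        io.write_measurements(gen_concentrations(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_correlation_knob_produces_correlated_species(self):
        from riskpm import correlation_matrix
        spec = GeneratorSpec(targets={("North", "Cu"): (30.0, 10.0),
                                      ("North", "Zn"): (55.0, 15.0)},
                             n_days=300, seed=6)
        r_indep, _ = correlation_matrix(gen_concentrations(spec))
        r_coupled, _ = correlation_matrix(
            gen_concentrations(spec, correlation=0.8))
        assert abs(r_indep.loc["Cu", "Zn"]) < 0.25
        assert r_coupled.loc["Cu", "Zn"] > 0.5


def _bearing_deg(lat0, lon0, lat1, lon1):
    dy = (lat1 - lat0) * 110.574
    dx = (lon1 - lon0) * 111.320 * np.cos(np.deg2rad(lat0))
    return np.degrees(np.arctan2(dx, dy)) % 360.0


class TestTrajectories:
    def test_zero_spread_straight_lines(self):
        spec = GeneratorSpec(targets={("North", "Zn"): (50, 10)}, n_days=3,
                             seed=7,
                             trajectory=TrajectorySpec(prevailing_deg=90,
                                                       spread_deg=0.0))
        for t in gen_trajectories(spec, directions=("backward",)):
            ll = t.latlon()
            bearings = [_bearing_deg(*ll[k], *ll[k + 1])
                        for k in range(len(ll) - 1)]
            assert np.allclose(bearings, 90.0, atol=0.5)

    def test_easterly_regime_mean_endpoint_bearing(self):
        spec = GeneratorSpec(targets={("North", "Zn"): (50, 10)}, n_days=500,
                             seed=8,
                             trajectory=TrajectorySpec(prevailing_deg=90,
                                                       spread_deg=15))
        trajs = gen_trajectories(spec, directions=("backward",))
        ends = np.array([t.latlon()[-1] for t in trajs])
        t0 = trajs[0]
        b = _bearing_deg(t0.points[0][1], t0.points[0][2],
                         ends[:, 0].mean(), ends[:, 1].mean())
        assert abs(b - 90.0) < 15.0

    def test_forward_opposes_backward(self):
        spec = GeneratorSpec(targets={("North", "Zn"): (50, 10)}, n_days=50,
                             seed=9)
        trajs = gen_trajectories(spec)
        back = [t for t in trajs if t.direction == "backward"]
        fwd = [t for t in trajs if t.direction == "forward"]
        b_end = np.array([t.latlon()[-1] for t in back]).mean(axis=0)
        f_end = np.array([t.latlon()[-1] for t in fwd]).mean(axis=0)
        rec = np.array([back[0].points[0][1], back[0].points[0][2]])
        assert b_end[1] > rec[1]   # backward tracks extend east
        assert f_end[1] < rec[1]   # forward tracks extend west

    def test_same_seed_identical(self):
        spec = GeneratorSpec(targets={("North", "Zn"): (50, 10)}, n_days=5,
                             seed=10)
        a = gen_trajectories(spec)
        b = gen_trajectories(spec)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.latlon(), tb.latlon())

    def test_negative_spread_rejected(self):
        with pytest.raises(ValidationError):
            TrajectorySpec(spread_deg=-1.0)


class TestRiskDays:
    def _measurements(self, n_days=12, seed=11):
        spec = GeneratorSpec(
            targets={("North", "Cr(VI)"): (104.16, 30.0),
                     ("North", "As"): (44.92, 20.0)},
            n_days=n_days, seed=seed)
        return gen_concentrations(spec)

    def test_doubling_concentrations_doubles_daily_cr(self, params, toxicity):
        df = self._measurements()
        doubled = df.copy()
        doubled["value_ng_m3"] *= 2.0
        a = gen_risk_days(df, params, toxicity, metric="CR")
        b = gen_risk_days(doubled, params, toxicity, metric="CR")
        for day in a.values:
            assert b.values[day] == pytest.approx(2 * a.values[day])

    def test_constant_concentrations_constant_series(self, params, toxicity):
        spec = GeneratorSpec(targets={("North", "Cr(VI)"): (104.16, 0.0)},
                             n_days=8, seed=12)
        series = gen_risk_days(gen_concentrations(spec), params, toxicity,
                               metric="HI")
        vals = list(series.values.values())
        assert np.allclose(vals, vals[0])

    def test_planted_episodes_are_the_threshold_exceedances(self, params,
                                                            toxicity):
        """10 episode days in 40 (exactly the top quartile) are precisely
        the days at or above the 75th-percentile threshold."""
        df = self._measurements(n_days=40, seed=13)
        dates = sorted(df["date"].unique())
        episodes = [dates[k] for k in (2, 5, 9, 14, 18, 22, 27, 31, 35, 38)]
        planted = plant_episodes(df, episodes, factor=5.0)
        series = gen_risk_days(planted, params, toxicity, metric="CR")
        values = series.values
        thr = np.percentile(list(values.values()), 75.0)
        high = {d for d, v in values.items() if v >= thr}
        assert high == {pd.Timestamp(d).normalize() for d in episodes}

    def test_ilcr_metric_uses_pah_congeners(self, params, toxicity):
        spec = GeneratorSpec(targets={("North", "BaP"): (0.49, 0.1),
                                      ("North", "IDP"): (2.0, 0.4)},
                             n_days=6, seed=14)
        series = gen_risk_days(gen_concentrations(spec), params, toxicity,
                               metric="ILCR")
        assert all(v > 0 for v in series.values.values())
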