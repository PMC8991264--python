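"""Structured growth models: rate laws, simulation, integrated-form
oracles, parameter recovery, model comparison, and fed-batch balances."""

import numpy as np
import pytest

import epferm as ep
from epferm.errors import (
    CollinearityError,
    InsufficientDataError,
    KineticsDomainError,
    ScheduleError,
    SingularityError,
)


def _random_params(rng):
    return ep.KineticParams(
        mu_max=rng.uniform(0.03, 0.2),
        ks=rng.uniform(2, 25),
        yb=rng.uniform(0.3, 0.7),
        yp=rng.uniform(5, 30),
        c0=rng.uniform(20, 40),
        x0=rng.uniform(0.0, 2.0),
        ki=rng.uniform(20, 80),
        kp=rng.uniform(80, 400),
    )


class TestRateLaws:
    def test_half_saturation(self):
        p = ep.KineticParams(mu_max=0.2, ks=10.0, yb=0.5, yp=10.0, c0=30.0)
        assert ep.specific_growth_rate("monod", p, cs=10.0) == pytest.approx(0.1)

    def test_product_inhibition_vanishes_without_product(self):
        p = ep.KineticParams(mu_max=0.2, ks=10.0, kp=100.0, yb=0.5, yp=10.0, c0=30.0)
        cs = np.linspace(0.0, 40.0, 50)
        aibe = ep.specific_growth_rate("aibe", p, cs, cp=0.0)
        monod = ep.specific_growth_rate("monod", p, cs)
        assert np.allclose(aibe, monod)

    def test_substrate_inhibition_peaks_at_sqrt_ks_ki(self):
        p = ep.KineticParams(mu_max=0.2, ks=5.0, ki=45.0, yb=0.5, yp=10.0, c0=30.0)
        cs = np.linspace(0.01, 200.0, 20001)
        mu = ep.specific_growth_rate("andrews", p, cs)
        assert cs[np.argmax(mu)] == pytest.approx(np.sqrt(p.ks * p.ki), rel=1e-3)

    def test_domain_errors(self):
        p = ep.KineticParams(mu_max=0.2, ks=10.0, yb=0.5, yp=10.0, c0=30.0)
        with pytest.raises(KineticsDomainError):
            ep.specific_growth_rate("monod", p, cs=-1.0)
        with pytest.raises(SingularityError):
            ep.specific_growth_rate("contois", p, cs=5.0, x=0.0)

    def test_bounded_by_mu_max(self):
        rng = np.random.default_rng(5)
        for kind in ep.MODEL_KINDS:
            p = _random_params(rng)
            cs = rng.uniform(0, 50, 100)
            mu = ep.specific_growth_rate(kind, p, cs, x=1.0, cp=10.0)
            assert np.all(mu >= 0) and np.all(mu <= p.mu_max + 1e-12)


class TestSimulation:
    def test_yield_coupling_identity(self, batch_grid):
        rng = np.random.default_rng(1)
        for kind in ep.MODEL_KINDS:
            p = _random_params(rng)
            s = ep.simulate_batch(kind, p, batch_grid)
            lhs = s.biomass - p.x0
            rhs = p.yb * (p.c0 - s.substrate)
            assert np.allclose(lhs, rhs, rtol=1e-6)
            assert np.allclose(s.product, p.yp * (p.c0 - s.substrate), rtol=1e-6)

    def test_substrate_monotone_nonincreasing(self, batch_grid):
        rng = np.random.default_rng(2)
        for kind in ep.MODEL_KINDS:
            s = ep.simulate_batch(kind, _random_params(rng), batch_grid)
            assert np.all(np.diff(s.substrate) <= 1e-12)

    def test_integrated_form_is_the_ode_solution(self, batch_grid):
        """Closed-form time evaluated on simulated (t, Cs) pairs must
        reproduce the grid to < 1e-3 h for all kinds and 20 seeded random
        parameter sets each (points at the depletion floor excluded)."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for kind in ep.MODEL_KINDS:
            for _ in range(20):
                p = _random_params(rng)
                sim = ep.simulate_batch(kind, p, batch_grid)
                keep = sim.substrate > 1e-6 * p.c0
                keep[0] = False
                t_ref = batch_grid[keep]
                t_pred = ep.integrated_form_time(kind, p, sim.substrate[keep])
                t_pred += t_ref[0] - t_pred[0]
                worst = max(worst, float(np.max(np.abs(t_pred - t_ref))))
        assert worst < 1e-3

    def test_faster_growth_halves_substrate_sooner(self):
        grid = np.linspace(0.0, 200.0, 2001)
        base = dict(ks=15.0, yb=0.5, yp=10.0, c0=30.0, x0=0.5)
        t_half = []
        for mu in (0.05, 0.08):
            s = ep.simulate_batch("monod", ep.KineticParams(mu_max=mu, **base), grid)
            t_half.append(grid[np.argmax(s.substrate <= base["c0"] / 2)])
        assert t_half[1] < t_half[0]

    def test_limit_reductions_to_monod(self, batch_grid):
        base = dict(mu_max=0.08, ks=10.0, yb=0.5, yp=10.0, c0=30.0, x0=0.5)
        monod = ep.simulate_batch("monod", ep.KineticParams(**base), batch_grid)
        andrews = ep.simulate_batch(
            "andrews", ep.KineticParams(**base, ki=1e9), batch_grid
        )
        aibe = ep.simulate_batch("aibe", ep.KineticParams(**base, kp=1e9), batch_grid)
        assert np.allclose(andrews.substrate, monod.substrate, rtol=1e-5, atol=1e-5)
        assert np.allclose(aibe.substrate, monod.substrate, rtol=1e-5, atol=1e-5)
        # contois at pinned unit biomass reduces to monod in the rate itself
        p = ep.KineticParams(**base)
        cs = np.linspace(0.1, 30, 50)
        assert np.allclose(
            ep.specific_growth_rate("contois", p, cs, x=1.0),
            ep.specific_growth_rate("monod", p, cs),
        )


class TestTransform:
    def test_midpoint_regressors(self):
        c0 = 30.0
        series = ep.BatchTimeSeries(
            times=np.linspace(0, 5, 6),
            substrate=np.array([c0, 25.0, 20.0, c0 / 2, 10.0, 5.0]),
        )
        table, dropped = ep.transform_regressors("monod", series, c0)
        assert dropped == 1  # the t = 0 point sits at the log singularity
        mid = table.iloc[2]
        assert mid["ln_cs_over_remaining"] == pytest.approx(0.0)
        assert mid["ln_remaining"] == pytest.approx(np.log(c0 / 2))

    def test_product_inhibition_table_has_four_regressors(self, batch_grid):
        p = ep.KineticParams(
            mu_max=0.1, ks=5.0, kp=150.0, yb=0.5, yp=19.6, c0=34.34, x0=0.5
        )
        s = ep.simulate_batch("aibe", p, batch_grid)
        table, _ = ep.transform_regressors("aibe", s, p.c0_eff)
        assert list(table.columns) == [
            "time_h",
            "ln_cs_over_remaining",
            "ln_remaining",
            "ln_cs",
            "cs",
        ]

    def test_substrate_above_c0_eff_is_a_domain_error(self):
        series = ep.BatchTimeSeries(
            times=np.arange(8.0), substrate=np.linspace(35, 20, 8)
        )
        with pytest.raises(KineticsDomainError):
            ep.transform_regressors("monod", series, 30.0)

    def test_too_few_points(self):
        series = ep.BatchTimeSeries(
            times=np.arange(3.0), substrate=np.array([30.0, 25.0, 20.0])
        )
        with pytest.raises(InsufficientDataError):
            ep.transform_regressors("monod", series, 30.0)


class TestIntegratedFit:
    def test_noiseless_round_trip_all_models(self, batch_grid):
        """Simulate-then-fit must recover the generating parameters to
        better than 1% without noise."""
        cases = {
            "monod": ep.KineticParams(
                mu_max=0.05, ks=15.0, yb=0.5, yp=19.6, c0=34.34, x0=0.5
            ),
            "contois": ep.KineticParams(
                mu_max=0.08, ks=2.0, yb=0.5, yp=19.6, c0=34.34, x0=0.5
            ),
            "andrews": ep.KineticParams(
                mu_max=0.12, ks=8.0, ki=40.0, yb=0.5, yp=19.6, c0=34.34, x0=0.5
            ),
            "aibe": ep.KineticParams(
                mu_max=0.1, ks=5.0, kp=150.0, yb=0.5, yp=19.6, c0=34.34, x0=0.5
            ),
        }
        for kind, p in cases.items():
            s = ep.simulate_batch(kind, p, batch_grid)
            fit = ep.fit_integrated(kind, s, p.c0_eff, yb=p.yb, yp=p.yp, x0=p.x0)
            rec = fit.params_recovered
            assert rec["mu_max"] == pytest.approx(p.mu_max, rel=0.01), kind
            assert rec["ks"] == pytest.approx(p.ks, rel=0.01), kind
            if kind == "andrews":
                assert rec["ki"] == pytest.approx(p.ki, rel=0.01)
            if kind == "aibe":
                assert rec["kp"] == pytest.approx(p.kp, rel=0.01)

    def test_noisy_recovery_median_error(self):
        """At 2% multiplicative noise on 20 samples spanning near-complete
        substrate consumption, the median relative error of mu_max and ks
        over 100 seeds stays below 15%.

        Saturation parameters are identifiable only when the trajectory
        covers both the saturated and the substrate-limited regime, so the
        recovery run samples to 160 h (substrate essentially exhausted);
        points with consumption inside one noise SD are excluded.
        """
        p = ep.KineticParams(mu_max=0.05, ks=15.0, yb=0.5, yp=19.6, c0=34.34, x0=0.5)
        times = tuple(np.linspace(0.0, 160.0, 20))
        errs_mu, errs_ks = [], []
        for seed in range(100):
            spec = ep.TrajectoryNoiseSpec(
                kind="monod", params=p, times=times, cv_substrate=0.02, seed=seed
            )
            noisy = ep.generate_batch_series(spec)
            fit = ep.fit_integrated(
                "monod", noisy, p.c0_eff, yb=p.yb, min_consumed=1.0
            )
            rec = fit.params_recovered
            errs_mu.append(abs(rec["mu_max"] - p.mu_max) / p.mu_max)
            errs_ks.append(abs(rec["ks"] - p.ks) / p.ks)
        assert np.median(errs_mu) < 0.15
        assert np.median(errs_ks) < 0.15

    def test_fit_quality_on_calibrated_noisy_data(self, default_kinetics):
        """All four linearized fits reach R^2 > 0.98 on the calibrated
        noisy synthetic trajectory."""
        kind, p = default_kinetics
        spec = ep.default_trajectory_spec(seed=0)
        noisy = ep.generate_batch_series(spec)
        ranked = ep.compare_models(
            noisy, p.c0_eff, yb=p.yb, yp=p.yp, x0=p.x0, min_consumed=1.0
        )
        for r in ranked:
            assert not r.failed
            assert r.r_squared > 0.98

    def test_constant_substrate_fails_cleanly(self):
        series = ep.BatchTimeSeries(
            times=np.arange(8.0), substrate=np.full(8, 20.0)
        )
        with pytest.raises((CollinearityError, InsufficientDataError)):
            ep.fit_integrated("monod", series, 30.0)


class TestCompareModels:
    def test_generator_model_wins_or_ties(self, batch_grid):
        p = ep.KineticParams(mu_max=0.05, ks=15.0, yb=0.5, yp=19.6, c0=34.34, x0=0.5)
        s = ep.simulate_batch("monod", p, batch_grid)
        ranked = ep.compare_models(s, p.c0_eff, yb=p.yb, yp=p.yp, x0=p.x0)
        assert len(ranked) == 4
        top_adj = ranked[0].adj_r_squared
        tied = [r.kind for r in ranked if abs(r.adj_r_squared - top_adj) < 1e-9]
        assert "monod" in tied

    def test_deterministic_and_complete(self, batch_grid, default_kinetics):
        kind, p = default_kinetics
        s = ep.simulate_batch(kind, p, batch_grid)
        r1 = ep.compare_models(s, p.c0_eff, yb=p.yb)
        r2 = ep.compare_models(s, p.c0_eff, yb=p.yb)
        assert [r.kind for r in r1] == [r.kind for r in r2]
        assert {r.kind for r in r1} == set(ep.MODEL_KINDS)

    def test_failed_fits_are_flagged_not_raised(self):
        series = ep.BatchTimeSeries(
            times=np.arange(8.0), substrate=np.full(8, 20.0)
        )
        ranked = ep.compare_models(series, 30.0)
        assert len(ranked) == 4
        assert all(r.failed for r in ranked)


class TestFedBatch:
    def test_water_only_dilution_halves_concentrations(self):
        p = ep.KineticParams(mu_max=0.05, ks=15.0, yb=0.5, yp=19.6, c0=34.34, x0=0.5)
        sched = ep.FeedSchedule(events=((10.0, 15.0, 0.0),), initial_volume=15.0)
        s = ep.simulate_fed_batch("monod", p, sched, np.linspace(0, 20, 21))
        i = np.flatnonzero(s.times == 10.0)
        assert len(i) == 2  # pre- and post-event state
        pre, post = i
        assert s.substrate[post] == pytest.approx(s.substrate[pre] / 2, rel=1e-12)
        assert s.biomass[post] == pytest.approx(s.biomass[pre] / 2, rel=1e-12)
        # total biomass mass unchanged
        assert s.biomass[post] * s.volume[post] == pytest.approx(
            s.biomass[pre] * s.volume[pre], rel=1e-12
        )

    def test_substrate_feed_mass_balance_arithmetic(self):
        """15 L at 10 g/L plus 1 L carrying 300 g must land at 28.125 g/L."""
        p = ep.KineticParams(mu_max=1e-9, ks=15.0, yb=0.5, yp=19.6, c0=10.0, x0=0.1)
        sched = ep.FeedSchedule(events=((5.0, 1.0, 300.0),), initial_volume=15.0)
        s = ep.simulate_fed_batch("monod", p, sched, np.linspace(0, 10, 11))
        post = np.flatnonzero(s.times == 5.0)[-1]
        assert s.substrate[post] == pytest.approx((10.0 * 15 + 300) / 16, rel=1e-9)

    def test_event_conservation_to_1e10(self):
        schedules, spec = ep.make_group_fixtures()
        s = ep.simulate_fed_batch(
            spec.kind, spec.params, schedules[2], np.asarray(spec.times)
        )
        for te, dv, m in schedules[2].events:
            pre, post = np.flatnonzero(s.times == te)
            v_pre, v_post = s.volume[pre], s.volume[post]
            assert v_post == v_pre + dv
            assert s.biomass[post] * v_post == pytest.approx(
                s.biomass[pre] * v_pre, rel=1e-10
            )
            assert s.product[post] * v_post == pytest.approx(
                s.product[pre] * v_pre, rel=1e-10
            )
            assert s.substrate[post] * v_post == pytest.approx(
                s.substrate[pre] * v_pre + m, rel=1e-10
            )

    def test_group_ordering_of_final_product_mass(self):
        """Substrate feeding beats water addition beats no addition in final
        product mass under the default product-inhibition kinetics."""
        schedules, spec = ep.make_group_fixtures()
        masses = []
        for sched in schedules:
            s = ep.simulate_fed_batch(
                spec.kind, spec.params, sched, np.asarray(spec.times)
            )
            masses.append(s.product[-1] * s.volume[-1])
        assert masses[2] >= masses[1] >= masses[0]

    def test_event_outside_span_rejected(self):
        p = ep.KineticParams(mu_max=0.05, ks=15.0, yb=0.5, yp=19.6, c0=34.34)
        sched = ep.FeedSchedule(events=((90.0, 1.0, 0.0),), initial_volume=15.0)
        with pytest.raises(ScheduleError):
            ep.simulate_fed_batch("monod", p, sched, np.linspace(0, 80, 9))
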