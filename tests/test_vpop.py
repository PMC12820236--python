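"""Virtual-patient sampling, population threshold optimization, Kaplan–Meier."""

import numpy as np
import pytest
from scipy import stats

from adaptox import (
    LognormalSpec,
    ModelParams,
    Protocol,
    ProtocolSpec,
    VPopSpec,
    km_curve,
    mean_ttp_threshold_sweep,
    optimize_thresholds,
    sample_vpop,
    sweep_thresholds,
    vpop_ttp,
)


@pytest.fixture(scope="module")
def small_pop():
    return sample_vpop(VPopSpec(n_patients=12, seed=99))


class TestLognormalSpec:
    def test_mode_and_interval_construction(self):
        ln = LognormalSpec.from_mode_and_range(2.4, 0.5, 3.5)
        assert ln.mode == pytest.approx(2.4)
        # central 95% interval of the lognormal spans the requested ratio
        lo = np.exp(ln.mu_log - 1.96 * ln.sigma_log)
        hi = np.exp(ln.mu_log + 1.96 * ln.sigma_log)
        assert hi / lo == pytest.approx(3.5 / 0.5, rel=1e-3)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            LognormalSpec(mu_log=0.0, sigma_log=0.0)
        with pytest.raises(ValueError):
            LognormalSpec.from_mode_and_range(1.0, 2.0, 1.0)


class TestSampling:
    def test_reproducible_under_seed(self):
        spec = VPopSpec(n_patients=20, seed=5)
        a = sample_vpop(spec)
        b = sample_vpop(spec)
        assert a.patients == b.patients
        c = sample_vpop(VPopSpec(n_patients=20, seed=6))
        assert a.patients != c.patients

    def test_parameters_positive_and_epsilon_truncated(self):
        pop = sample_vpop(VPopSpec(n_patients=2000, seed=1))
        eps = np.array([p.epsilon for p in pop.patients])
        assert np.all(eps > 0) and np.all(eps <= 1.0)
        for name in ("alpha_S", "delta", "beta", "gamma"):
            vals = np.array([getattr(p, name) for p in pop.patients])
            assert np.all(vals > 0)

    def test_fixed_parameters_stay_at_baseline(self, small_pop):
        base = ModelParams()
        for p in small_pop.patients:
            assert (p.K, p.lam, p.mu) == (base.K, base.lam, base.mu)

    def test_sample_mode_sits_near_baseline(self):
        # kernel-density peak of each marginal ~ baseline value at n = 10,000
        pop = sample_vpop(VPopSpec(n_patients=10_000, seed=2))
        base = ModelParams()
        for name in ("alpha_S", "delta", "beta", "gamma"):
            vals = np.array([getattr(p, name) for p in pop.patients])
            kde = stats.gaussian_kde(vals)
            grid = np.linspace(vals.min(), vals.max(), 400)
            peak = grid[np.argmax(kde(grid))]
            expected = getattr(base, name)
            assert peak == pytest.approx(expected, rel=0.25)

    def test_alpha_r_derived_per_patient(self, small_pop):
        for p in small_pop.patients:
            assert p.alpha_R == pytest.approx(p.epsilon * p.alpha_S)


class TestVpopTtp:
    def test_single_baseline_patient_reproduces_published_ttp(self):
        pop = [ModelParams()]
        ttps = vpop_ttp(pop, ProtocolSpec(protocol=Protocol.ADAPTIVE_TOX))
        assert ttps[0] == pytest.approx(79.1, abs=1.0)

    def test_empty_population_gives_empty_list(self):
        assert vpop_ttp([], ProtocolSpec()).size == 0

    def test_sentinel_arithmetic(self, baseline):
        # a population that never progresses averages to the sentinel
        controlled = [baseline.replace(beta=3.4)] * 3
        ttps = vpop_ttp(controlled, ProtocolSpec(protocol=Protocol.ADAPTIVE))
        assert np.all(ttps == 150.0)
        assert np.mean(ttps) == 150.0


class TestMeanSweep:
    AXES = (("tox_on", np.array([0.75, 1.25])), ("tox_off", np.array([1.0, 2.0])))

    def test_single_patient_reduces_to_plain_threshold_sweep(self, baseline):
        mean = mean_ttp_threshold_sweep([baseline], Protocol.DAILY_TOX, *self.AXES, engine="grid")
        plain = sweep_thresholds(baseline, Protocol.DAILY_TOX, *self.AXES, engine="grid")
        np.testing.assert_array_equal(
            mean.ttp[Protocol.DAILY_TOX], plain.ttp[Protocol.DAILY_TOX]
        )
        np.testing.assert_array_equal(mean.feasible, plain.feasible)

    def test_vectorized_path_matches_per_patient_average(self, small_pop):
        pats = list(small_pop.patients[:3])
        fast = mean_ttp_threshold_sweep(pats, Protocol.DAILY_TOX, *self.AXES, engine="grid")
        per = [
            sweep_thresholds(p, Protocol.DAILY_TOX, *self.AXES, engine="grid") for p in pats
        ]
        expected = np.mean([r.ttp[Protocol.DAILY_TOX] for r in per], axis=0)
        np.testing.assert_allclose(
            fast.ttp[Protocol.DAILY_TOX], expected, atol=1e-12, equal_nan=True
        )

    def test_masking_is_population_independent(self, small_pop):
        res = mean_ttp_threshold_sweep(
            small_pop, Protocol.DAILY_TOX, *self.AXES, engine="grid"
        )
        # tox_on=1.25 vs tox_off=1.0 violates the band
        assert not res.feasible[1, 0]
        assert np.isnan(res.ttp[Protocol.DAILY_TOX][1, 0])


class TestOptimizeThresholds:
    def test_one_cell_grid_returns_that_cell(self, small_pop):
        out = optimize_thresholds(
            small_pop, Protocol.ADAPTIVE, {"rx_on": [55.0], "rx_off": [30.0]}
        )
        assert out["thresholds"] == {"rx_on": 55.0, "rx_off": 30.0}
        assert out["n_feasible"] == 1

    def test_optimum_dominates_baseline_thresholds(self, small_pop):
        grids = {"rx_on": np.array([40.0, 50.0, 60.0]), "rx_off": np.array([10.0, 20.0, 30.0])}
        out = optimize_thresholds(small_pop, Protocol.ADAPTIVE, grids)
        base_mean = np.mean(vpop_ttp(small_pop, ProtocolSpec(protocol=Protocol.ADAPTIVE)))
        assert out["mean_ttp"] >= base_mean - 1e-9  # baseline (50, 20) is in the grid

    def test_reported_optimum_survives_independent_reevaluation(self, small_pop):
        grids = {"tox_on": np.array([0.75, 1.25]), "tox_off": np.array([1.5, 2.0])}
        out = optimize_thresholds(small_pop, Protocol.DAILY_TOX, grids)
        spec = ProtocolSpec(protocol=Protocol.DAILY_TOX, **out["thresholds"])
        re_ttps = vpop_ttp(small_pop, spec, engine="grid")
        assert np.mean(re_ttps) == pytest.approx(out["mean_ttp"], abs=1e-12)

    def test_inactive_axes_rejected(self, small_pop):
        with pytest.raises(ValueError, match="inactive"):
            optimize_thresholds(small_pop, Protocol.ADAPTIVE, {"tox_on": [1.0]})

    def test_no_feasible_cell_is_an_error(self, small_pop):
        with pytest.raises(ValueError, match="feasible"):
            optimize_thresholds(
                small_pop, Protocol.ADAPTIVE, {"rx_on": [10.0], "rx_off": [20.0]}
            )


class TestKMCurve:
    def test_direct_enumeration_two_events(self):
        km = km_curve([10.0, 20.0], horizon=100.0)
        assert km.survival_at(5.0) == 1.0
        assert km.survival_at(10.0) == 0.5
        assert km.survival_at(15.0) == 0.5
        assert km.survival_at(20.0) == 0.0
        assert km.survival_at(100.0) == 0.0

    def test_sentinels_never_become_events(self):
        km = km_curve([150.0, 150.0, 150.0], horizon=100.0)
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_survival_at_horizon_equals_sentinel_fraction(self):
        ttps = [10.0, 50.0, 150.0, 150.0, 99.0]
        km = km_curve(ttps, horizon=100.0)
        assert km.survival_at(100.0) == pytest.approx(2 / 5)

    def test_starts_at_one_and_never_increases(self, small_pop):
        ttps = vpop_ttp(small_pop, ProtocolSpec(protocol=Protocol.DAILY_TOX))
        km = km_curve(ttps, horizon=100.0)
        assert km.survival_at(0.0) <= 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_negative_ttp_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1.0, 10.0])
        with pytest.raises(ValueError):
            km_curve([])

    def test_matches_lifelines_estimator(self, small_pop):
        # independent cross-check against the survival-analysis standard
        lifelines = pytest.importorskip("lifelines")
        ttps = vpop_ttp(small_pop, ProtocolSpec(protocol=Protocol.ADAPTIVE))
        km = km_curve(ttps, horizon=100.0)
        durations = np.minimum(ttps, 100.0)
        observed = ttps <= 100.0
        kmf = lifelines.KaplanMeierFitter().fit(durations, observed)
        for t in list(km.event_times) + [100.0]:
            assert km.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-12
            )
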