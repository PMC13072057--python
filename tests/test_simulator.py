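import numpy as np
import pytest

from hemodose import (BeamSchedule, CumulativeDVH, SimulationConfig,
                      blood_dvh_from_doses, build_reference_model,
                      initialize_particles, mean_dose, sample_organ_dose,
                      simulate_course, simulate_fraction, step, v_at_dose)
from hemodose.errors import ConfigurationError, DomainError

from conftest import toy_table


def model_from(volumes, flows, **kw):
    return build_reference_model("male", toy_table(volumes, flows, **kw),
                                 required_compartments=[])


SCHED_1F = BeamSchedule("IMRT", n_fields=1, field_beam_on=60.0, n_fractions=1)


class TestInitialization:
    def test_single_compartment_all_particles(self):
        m = model_from([1.0], [1.0])
        e = initialize_particles(m, SimulationConfig(n_particles=500, seed=0))
        assert np.all(e.compartment_index == 0)
        assert np.all(e.cumulative_dose == 0)

    def test_occupancy_within_binomial_bound(self, two_compartment_model):
        n = 10**5
        e = initialize_particles(two_compartment_model,
                                 SimulationConfig(n_particles=n, seed=7))
        frac0 = np.mean(e.compartment_index == 0)
        bound = 3 * np.sqrt(0.2 * 0.8 / n)
        assert abs(frac0 - 0.2) < bound

    def test_same_seed_identical(self, two_compartment_model):
        cfg = SimulationConfig(n_particles=1000, seed=3)
        e1 = initialize_particles(two_compartment_model, cfg)
        e2 = initialize_particles(two_compartment_model, cfg)
        np.testing.assert_array_equal(e1.compartment_index, e2.compartment_index)
        np.testing.assert_array_equal(e1.residence_remaining,
                                      e2.residence_remaining)

    def test_zero_particles_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_particles=0)


class TestStep:
    def test_single_compartment_assignment_never_changes(self):
        m = model_from([1.0], [1.0])
        e = initialize_particles(m, SimulationConfig(n_particles=200, seed=1))
        for _ in range(20):
            e = step(e, m, 5.0)
        assert np.all(e.compartment_index == 0)

    def test_small_dt_only_decrements(self, two_compartment_model):
        e = initialize_particles(two_compartment_model,
                                 SimulationConfig(n_particles=100, seed=2))
        e.residence_remaining[:] = 10.0
        before = e.compartment_index.copy()
        e2 = step(e, two_compartment_model, 0.05)
        np.testing.assert_array_equal(e2.compartment_index, before)
        np.testing.assert_allclose(e2.residence_remaining, 10.0 - 0.05)

    def test_long_run_time_average_occupancy(self):
        # incommensurate fixed transits; time-averaged occupancy ~ V-weights
        m = model_from([0.3, 0.7], [0.55, 0.45])
        n = 20_000
        e = initialize_particles(m, SimulationConfig(n_particles=n, seed=4))
        counts = np.zeros(2)
        steps = 400
        for _ in range(steps):
            e = step(e, m, 0.5)
            counts[0] += np.mean(e.compartment_index == 0)
            counts[1] += np.mean(e.compartment_index == 1)
        avg = counts / steps
        assert avg[0] == pytest.approx(0.3, abs=0.01)
        assert avg[1] == pytest.approx(0.7, abs=0.01)

    def test_particle_count_conserved(self, two_compartment_model):
        e = initialize_particles(two_compartment_model,
                                 SimulationConfig(n_particles=333, seed=5))
        e2 = step(e, two_compartment_model, 100.0)  # force many expiries
        assert e2.n_particles == 333


class TestOrganDoseSampling:
    def test_delta_always_d(self, rng):
        d = CumulativeDVH.delta(4.0)
        draws = sample_organ_dose(d, rng, size=200)
        assert np.all(np.abs(draws - 4.0) <= d.bin_width)

    def test_two_step_dvh_frequencies(self, rng):
        # half the volume at 10 Gy, half at ~0
        grid = np.arange(0, 10.02, 0.01)
        frac = np.where(grid <= 0.005, 1.0, np.where(grid <= 10.0, 0.5, 0.0))
        d = CumulativeDVH(grid, frac)
        draws = sample_organ_dose(d, rng, size=40_000)
        p_high = np.mean(draws > 5.0)
        assert abs(p_high - 0.5) < 3 * np.sqrt(0.25 / 40_000)

    def test_sample_mean_matches_dvh_mean(self, linear_dvh, rng):
        draws = sample_organ_dose(linear_dvh, rng, size=10**6)
        se = draws.std() / 1e3
        assert draws.mean() == pytest.approx(mean_dose(linear_dvh), abs=3 * se)


class TestFraction:
    def test_uniform_limit_single_compartment(self):
        m = model_from([1.0], [1.0])
        e = initialize_particles(m, SimulationConfig(n_particles=300, seed=6))
        dvh = CumulativeDVH.delta(5.0)
        e2 = simulate_fraction(m, {"c0": dvh}, SCHED_1F, e)
        assert np.all(np.abs(e2.cumulative_dose - 5.0) <= dvh.bin_width)

    def test_routing_independence_of_identical_deltas(self, two_compartment_model):
        e = initialize_particles(two_compartment_model,
                                 SimulationConfig(n_particles=300, seed=7))
        dvhs = {"c0": CumulativeDVH.delta(3.0), "c1": CumulativeDVH.delta(3.0)}
        e2 = simulate_fraction(two_compartment_model, dvhs, SCHED_1F, e)
        assert np.all(np.abs(e2.cumulative_dose - 3.0) <= 0.01)

    def test_ensemble_mean_closed_form(self, two_compartment_model):
        n = 50_000
        e = initialize_particles(two_compartment_model,
                                 SimulationConfig(n_particles=n, seed=8))
        dvhs = {"c0": CumulativeDVH.delta(10.0), "c1": CumulativeDVH.delta(0.0)}
        e2 = simulate_fraction(two_compartment_model, dvhs, SCHED_1F, e)
        expected = 0.2 * 10.0 + 0.8 * 0.0
        se = e2.cumulative_dose.std() / np.sqrt(n)
        assert e2.cumulative_dose.mean() == pytest.approx(expected, abs=3 * se + 0.01)

    def test_missing_in_field_dvh_named(self, two_compartment_model):
        e = initialize_particles(two_compartment_model,
                                 SimulationConfig(n_particles=10, seed=9))
        with pytest.raises(ConfigurationError, match="c1"):
            simulate_fraction(two_compartment_model,
                              {"c0": CumulativeDVH.delta(1.0)}, SCHED_1F, e)

    def test_doses_non_decreasing(self, two_compartment_model):
        e = initialize_particles(two_compartment_model,
                                 SimulationConfig(n_particles=500, seed=10))
        dvhs = {"c0": CumulativeDVH.delta(2.0), "c1": CumulativeDVH.delta(1.0)}
        e2 = simulate_fraction(two_compartment_model, dvhs, SCHED_1F, e)
        assert np.all(e2.cumulative_dose >= 0)
        e3 = simulate_fraction(two_compartment_model, dvhs, SCHED_1F, e2)
        assert np.all(e3.cumulative_dose >= e2.cumulative_dose - 1e-12)


class TestCourse:
    def test_uniform_delta_additivity(self, two_compartment_model):
        sched = BeamSchedule("IMRT", n_fields=2, field_beam_on=30.0,
                             n_fractions=33)
        dvhs = {"c0": CumulativeDVH.delta(33.0), "c1": CumulativeDVH.delta(33.0)}
        res = simulate_course(two_compartment_model, dvhs, sched,
                              SimulationConfig(n_particles=400, seed=11))
        # course DVH delta at 33 Gy delivered over 33 fractions
        assert res.metrics["Dmean"] == pytest.approx(33.0, abs=0.05)
        assert res.per_particle_dose.std() < 0.05

    def test_fraction_modes_same_mean_narrower_spread(self):
        m = model_from([0.5, 0.5], [0.5, 0.5])
        dvhs = {"c0": CumulativeDVH.delta(20.0), "c1": CumulativeDVH.delta(0.0)}
        sched = BeamSchedule("IMRT", n_fields=1, field_beam_on=40.0,
                             n_fractions=10)
        res_r = simulate_course(m, dvhs, sched,
                                SimulationConfig(n_particles=20_000, seed=12,
                                                 fraction_mode="resample_each_fraction"))
        res_s = simulate_course(m, dvhs, sched,
                                SimulationConfig(n_particles=20_000, seed=12,
                                                 fraction_mode="scale_single_fraction"))
        se = (res_r.per_particle_dose.std() + res_s.per_particle_dose.std()) / np.sqrt(20_000)
        assert res_r.per_particle_dose.mean() == pytest.approx(
            res_s.per_particle_dose.mean(), abs=3 * se)
        # independent per-fraction draws average out: ~sqrt(n_fx) narrower
        assert res_r.per_particle_dose.std() < 0.6 * res_s.per_particle_dose.std()

    def test_determinism_bit_identical(self, two_compartment_model):
        dvhs = {"c0": CumulativeDVH.delta(2.0), "c1": CumulativeDVH.delta(1.0)}
        sched = BeamSchedule("IMPT", n_fields=4, field_beam_on=30.0,
                             n_fractions=3)
        cfg = SimulationConfig(n_particles=2_000, seed=13)
        r1 = simulate_course(two_compartment_model, dvhs, sched, cfg)
        r2 = simulate_course(two_compartment_model, dvhs, sched, cfg)
        np.testing.assert_array_equal(r1.per_particle_dose, r2.per_particle_dose)

    def test_monotone_under_stochastic_dominance(self, two_compartment_model):
        # lowering one organ's DVH cannot raise blood Dmean (common randoms)
        sched = BeamSchedule("IMRT", n_fields=1, field_beam_on=60.0,
                             n_fractions=2)
        cfg = SimulationConfig(n_particles=5_000, seed=14)
        hi = {"c0": CumulativeDVH.delta(8.0), "c1": CumulativeDVH.delta(1.0)}
        lo = {"c0": CumulativeDVH.delta(8.0).scale_dose(0.5),
              "c1": CumulativeDVH.delta(1.0)}
        r_hi = simulate_course(two_compartment_model, hi, sched, cfg)
        r_lo = simulate_course(two_compartment_model, lo, sched, cfg)
        assert r_lo.metrics["Dmean"] <= r_hi.metrics["Dmean"] + 1e-9
        assert np.all(r_lo.per_particle_dose <= r_hi.per_particle_dose + 1e-9)

    def test_exponential_residence_mode_runs(self, two_compartment_model):
        dvhs = {"c0": CumulativeDVH.delta(4.0), "c1": CumulativeDVH.delta(0.0)}
        res = simulate_course(two_compartment_model, dvhs, SCHED_1F,
                              SimulationConfig(n_particles=20_000, seed=15,
                                               residence_mode="exponential"))
        se = res.per_particle_dose.std() / np.sqrt(20_000)
        assert res.metrics["Dmean"] == pytest.approx(0.8, abs=3 * se + 0.01)


class TestBloodDvhReduction:
    def test_all_equal_step(self):
        d = blood_dvh_from_doses(np.full(100, 2.0))
        assert v_at_dose(d, 1.9) == 1.0
        assert v_at_dose(d, 2.05) == pytest.approx(0.0, abs=1e-9)

    def test_counting(self):
        d = blood_dvh_from_doses(np.array([0.0, 1.0, 2.0, 3.0]))
        assert v_at_dose(d, 0.5) == pytest.approx(0.75)
        assert v_at_dose(d, 2.5) == pytest.approx(0.25)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            blood_dvh_from_doses(np.array([]))

    def test_dkw_band_against_known_mixture(self, rng):
        # 30% at ~1 Gy, 70% at ~4 Gy
        doses = np.where(rng.random(50_000) < 0.3, 1.0, 4.0)
        d = blood_dvh_from_doses(doses)
        eps = np.sqrt(np.log(2 / 0.001) / (2 * 50_000))  # DKW, alpha=0.1%
        for x, s_true in [(0.5, 1.0), (2.0, 0.7), (5.0, 0.0)]:
            assert abs(v_at_dose(d, x) - s_true) <= eps + 1e-9
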