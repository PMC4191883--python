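"""Boost-potential and steering-force contracts plus toy-run behavior."""

import numpy as np
import pytest

from statemap.sampling import (KB, AmdParams, amd_boost, amd_force_factor,
                               amd_reweight, TmdParams, tmd_target_rmsd,
                               tmd_force_magnitude, tmd_restraint_energy,
                               tmd_forces, IntegratorSettings, run_toy_tmd,
                               DihedralPotential, run_toy_amd,
                               count_well_crossings,
                               boltzmann_well_population,
                               weighted_population, block_bootstrap_se)
from statemap.geometry import kabsch_rmsd
from statemap.synthgen import make_ideal_helix

STUDY_AMD = AmdParams(E=18600.0, alpha=210.0)


class TestAmdBoost:
    def test_zero_at_threshold(self):
        assert amd_boost(18600.0, STUDY_AMD) == 0.0

    def test_alpha_below_threshold_gives_half_alpha(self):
        # ΔV(E − α) = α²/(2α) = α/2
        assert amd_boost(18600.0 - 210.0, STUDY_AMD) == pytest.approx(105.0)

    def test_study_parameter_evaluation(self):
        assert amd_boost(18390.0, STUDY_AMD) == pytest.approx(105.0)

    def test_zero_above_threshold(self):
        assert amd_boost(20000.0, STUDY_AMD) == 0.0

    def test_boosted_surface_bounded_and_monotone(self):
        v = np.linspace(17000.0, 19000.0, 2001)
        vstar = v + amd_boost(v, STUDY_AMD)
        below = v < 18600.0
        assert np.all(vstar[below] <= 18600.0 + 1e-9)
        assert np.all(np.diff(vstar) > 0)
        assert np.all(amd_boost(v, STUDY_AMD) >= 0)

    def test_c1_continuity_at_threshold(self):
        """dV*/dV approaches 0⁺ below E and is 1... the boosted force
        factor is continuous: (α/(α+E−V))² -> 1 as V -> E⁻."""
        eps = 1e-6
        below = amd_force_factor(18600.0 - eps, STUDY_AMD)
        above = amd_force_factor(18600.0 + eps, STUDY_AMD)
        assert below == pytest.approx(above, abs=1e-4)
        # finite-difference slope of V* is continuous at V = E
        p = STUDY_AMD
        h = 1e-3
        def vstar(v):
            return v + amd_boost(v, p)
        slope_below = (vstar(p.E - h) - vstar(p.E - 2 * h)) / h
        slope_above = (vstar(p.E + 2 * h) - vstar(p.E + h)) / h
        assert slope_below == pytest.approx(slope_above, abs=1e-4)


class TestAmdReweight:
    def test_uniform_for_zero_boost(self):
        w = amd_reweight(np.zeros(5), 310.0)
        assert np.allclose(w, 0.2)

    def test_ln2_ratio(self):
        w = amd_reweight(np.array([0.0, KB * 310.0 * np.log(2.0)]), 310.0)
        assert np.allclose(w, [1 / 3, 2 / 3])

    def test_overflow_guarded(self):
        w = amd_reweight(np.array([0.0, 5000.0]), 310.0)
        assert np.isfinite(w).all() and w.sum() == pytest.approx(1.0)


class TestTmdForce:
    P = TmdParams(k=200.0, n_atoms=100, rmsd0=4.0, duration=10.0)

    def test_zero_on_schedule(self):
        assert tmd_force_magnitude(2.0, 5.0, self.P) == pytest.approx(0.0)

    def test_unit_deviation_value(self):
        # ½ (200/100) · 1 Å = 1 kcal/(mol·Å)
        assert tmd_force_magnitude(1.0, 10.0, self.P) == pytest.approx(1.0)

    def test_linear_schedule_midpoint(self):
        assert tmd_target_rmsd(5.0, self.P) == pytest.approx(2.0)
        assert tmd_target_rmsd(0.0, self.P) == pytest.approx(4.0)
        assert tmd_target_rmsd(10.0, self.P) == pytest.approx(0.0)

    def test_time_outside_schedule_errors(self):
        with pytest.raises(ValueError):
            tmd_target_rmsd(11.0, self.P)

    def test_force_is_negative_energy_gradient(self):
        """Finite-difference check of the per-atom restraint forces."""
        rng = np.random.default_rng(2)
        coords = make_ideal_helix(8)
        target = coords + 0.5 * rng.standard_normal(coords.shape)
        params = TmdParams(k=50.0, n_atoms=8, rmsd0=2.0, duration=10.0)
        t = 3.0
        forces, _ = tmd_forces(coords, target, t, params)

        def energy(x):
            r, _, _ = kabsch_rmsd(x, target)
            return tmd_restraint_energy(r, t, params)

        h = 1e-6
        for idx in [(0, 0), (3, 1), (7, 2)]:
            xp = coords.copy(); xp[idx] += h
            xm = coords.copy(); xm[idx] -= h
            fd = -(energy(xp) - energy(xm)) / (2 * h)
            assert forces[idx] == pytest.approx(fd, abs=1e-5)


class TestToyTmd:
    START = make_ideal_helix(10)
    TARGET = make_ideal_helix(10, rise=2.6, radius=1.0)

    def test_steering_reaches_target(self):
        settings = IntegratorSettings(n_steps=4000, temperature=30.0)
        _, _, rmsds = run_toy_tmd(self.START, self.TARGET,
                                  settings=settings, seed=1)
        assert rmsds[-1] <= 0.5

    def test_zero_schedule_stays_near_target(self):
        settings = IntegratorSettings(n_steps=1000, temperature=30.0)
        params = TmdParams(k=200.0, n_atoms=10, rmsd0=0.0, duration=10.0)
        _, _, rmsds = run_toy_tmd(self.START, self.START, params=params,
                                  settings=settings, seed=2)
        assert np.max(rmsds) < 0.5

    def test_unbiased_rmsd_does_not_decay(self):
        settings = IntegratorSettings(n_steps=3000, temperature=30.0)
        r0, _, _ = kabsch_rmsd(self.START, self.TARGET)
        params0 = TmdParams(k=0.0, n_atoms=10, rmsd0=r0, duration=30.0)
        _, _, free = run_toy_tmd(self.START, self.TARGET, params=params0,
                                 settings=settings, seed=3)
        _, _, steered = run_toy_tmd(self.START, self.TARGET,
                                    settings=settings, seed=3)
        assert steered[-1] < 0.5
        assert free[-1] > 0.6 * r0       # stays near the start basin

    def test_deterministic_given_seed(self):
        settings = IntegratorSettings(n_steps=200, temperature=30.0)
        t1, _, r1 = run_toy_tmd(self.START, self.TARGET,
                                settings=settings, seed=7)
        t2, _, r2 = run_toy_tmd(self.START, self.TARGET,
                                settings=settings, seed=7)
        assert np.array_equal(r1, r2)
        assert all(np.array_equal(a, b)
                   for a, b in zip(t1.frames, t2.frames))


DOUBLE_WELL = DihedralPotential(terms=((5.0, 2, 0.0),))


class TestToyAmd:
    def test_boost_increases_crossings(self):
        boosted = run_toy_amd(DOUBLE_WELL, AmdParams(E=11.0, alpha=2.0),
                              n_steps=50_000, seed=4)
        unbiased = run_toy_amd(DOUBLE_WELL,
                               AmdParams(E=-1.0, alpha=2.0),
                               n_steps=50_000, seed=4)
        assert count_well_crossings(boosted.phi) > \
            count_well_crossings(unbiased.phi)

    def test_threshold_below_minimum_is_unbiased(self):
        with pytest.warns(UserWarning):
            res = run_toy_amd(DOUBLE_WELL, AmdParams(E=-5.0, alpha=2.0),
                              n_steps=2_000, seed=5)
        assert np.all(res.boost == 0.0)
        assert np.allclose(res.weights, 1.0 / len(res.weights))

    def test_reweighted_population_matches_quadrature(self):
        """Asymmetric double well: reweighted well occupancy vs
        Boltzmann quadrature within 3 standard errors."""
        pot = DihedralPotential(terms=((2.0, 2, 0.0), (0.6, 1, 0.0)))
        params = AmdParams(E=6.0, alpha=1.5)
        res = run_toy_amd(pot, params, n_steps=100_000, seed=6)
        pop = weighted_population(res.phi, res.weights)
        ref = boltzmann_well_population(pot)
        se = block_bootstrap_se(res.phi, res.boost, params.temperature,
                                seed=1)
        assert count_well_crossings(res.phi) > 20
        assert abs(pop - ref) <= 3.0 * max(se, 1e-3)
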