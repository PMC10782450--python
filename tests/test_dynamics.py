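"""Geometry optimization, Langevin MD, snapshot selection and rigid scans."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import h2_structure
from bdekit.bdecore import kabsch_rmsd
from bdekit.chemio import Structure
from bdekit.dynamics import (
    MDSettings,
    OptimizationError,
    OptSettings,
    langevin_md,
    max_force_norm,
    optimize,
    sample_snapshot,
    stretch_scan,
)
from bdekit.fixtures import FixtureSpec, QuadraticWell, make_fixture


class TestOptimize:
    @pytest.mark.parametrize("algorithm", ["fire", "bfgs"])
    def test_h2_converges_to_morse_minimum(self, toy_params, toy_calc, algorithm):
        _, _, r0 = toy_params.morse[("H", "H")]
        s = h2_structure(1.3 * r0)
        out = optimize(s, toy_calc, OptSettings(fmax=1e-5, algorithm=algorithm))
        assert out.distance(0, 1) == pytest.approx(r0, abs=1e-4)
        # input untouched, energy attached
        assert s.distance(0, 1) == pytest.approx(1.3 * r0)
        assert out.energy is not None

    def test_noop_when_already_converged(self, toy_calc, toy_params):
        _, _, r0 = toy_params.morse[("H", "H")]
        s = h2_structure(r0)
        out = optimize(s, toy_calc, OptSettings(fmax=0.05))
        assert np.array_equal(out.positions, s.positions)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_quadratic_well_reaches_center(self, seed):
        rng = np.random.default_rng(seed)
        centers = rng.standard_normal((4, 3)) * 2
        calc = QuadraticWell(centers, k=30.0)
        start = Structure(["C", "H", "H", "H"],
                          centers + rng.standard_normal((4, 3)))
        out = optimize(start, calc, OptSettings(fmax=1e-6))
        assert np.allclose(out.positions, centers, atol=1e-5)

    def test_monotone_descent_over_accepted_steps(self, toy_calc):
        s = make_fixture(FixtureSpec(name="butane", perturbation=0.08, seed=6))
        hist = []
        optimize(s, toy_calc, OptSettings(), history=hist)
        energies = [e for e, _ in hist]
        tol = 1e-8 * (1.0 + abs(energies[0]))
        assert all(b <= a + tol for a, b in zip(energies, energies[1:]))

    def test_nonconvergence_carries_best_structure(self, toy_calc):
        s = make_fixture(FixtureSpec(name="butane", perturbation=0.1, seed=2))
        with pytest.raises(OptimizationError) as err:
            optimize(s, toy_calc, OptSettings(fmax=1e-9, max_steps=5))
        assert err.value.structure.energy is not None
        assert err.value.residual_force > 1e-9

    def test_rotation_invariant_up_to_rigid_motion(self, toy_calc):
        s = make_fixture(FixtureSpec(name="propane", perturbation=0.05, seed=8))
        opt = OptSettings(fmax=1e-4, algorithm="bfgs")
        a = optimize(s, toy_calc, opt)
        rng = np.random.default_rng(1)
        rot = s.copy()
        rot.positions = Rotation.random(rng=rng).apply(s.positions)
        b = optimize(rot, toy_calc, opt)
        assert kabsch_rmsd(a, b) < 1e-3

    def test_deterministic(self, toy_calc):
        s = make_fixture(FixtureSpec(name="ethanol", perturbation=0.05, seed=3))
        a = optimize(s, toy_calc, OptSettings())
        b = optimize(s, toy_calc, OptSettings())
        assert np.array_equal(a.positions, b.positions)


class TestLangevinMD:
    def test_seeded_determinism(self, toy_calc, butane):
        md = MDSettings(temperature=300, timestep=0.0005, friction=10,
                        n_steps=50, seed=4)
        t1 = langevin_md(butane, toy_calc, md)
        t2 = langevin_md(butane, toy_calc, md)
        assert all(np.array_equal(a.positions, b.positions)
                   for a, b in zip(t1, t2))

    def test_nve_energy_conservation_short(self, toy_calc):
        """With zero friction the integrator is plain velocity Verlet:
        total energy shows bounded oscillation and no secular drift."""
        s = h2_structure(0.85)
        traj = langevin_md(s, toy_calc, MDSettings(
            temperature=0, timestep=0.0002, friction=0.0, n_steps=2000, seed=0))
        tot = np.array([f.energy + float(f.tags["kinetic_energy"]) for f in traj])
        drift = abs(tot[-100:].mean() - tot[:100].mean())
        assert drift < 0.01

    def test_nonfinite_reports_step(self):
        from bdekit.potentials import Calculator

        class Breaks(Calculator):
            name = "breaks"
            calls = 0

            def evaluate(self, s):
                Breaks.calls += 1
                e = np.nan if Breaks.calls > 3 else 0.0
                return e, np.zeros((s.n_atoms, 3))

        with pytest.raises(RuntimeError, match="step 3"):
            langevin_md(h2_structure(0.74), Breaks(), MDSettings(
                temperature=0, timestep=0.001, friction=0.0, n_steps=10, seed=0))

    def test_frames_carry_energy(self, toy_calc, butane):
        traj = langevin_md(butane, toy_calc, MDSettings(n_steps=5, seed=0))
        assert len(traj) == 6
        assert all(f.energy is not None for f in traj)


class TestSnapshot:
    def test_last_rule(self, butane):
        traj = [butane.copy() for _ in range(3)]
        for k, f in enumerate(traj):
            f.tags["step"] = str(k)
        assert sample_snapshot(traj, "last").tags["step"] == "2"

    def test_random_rule_seeded(self, butane):
        traj = [butane.copy() for _ in range(10)]
        for k, f in enumerate(traj):
            f.tags["step"] = str(k)
        a = sample_snapshot(traj, "random", seed=7)
        b = sample_snapshot(traj, "random", seed=7)
        assert a.tags["step"] == b.tags["step"]

    def test_random_rule_uniform(self, butane):
        traj = [butane.copy() for _ in range(10)]
        for k, f in enumerate(traj):
            f.tags["step"] = str(k)
        counts = np.zeros(10)
        for seed in range(10000):
            counts[int(sample_snapshot(traj, "random", seed=seed).tags["step"])] += 1
        assert np.all(np.abs(counts / 10000 - 0.1) < 0.01)

    def test_empty_trajectory(self):
        with pytest.raises(ValueError):
            sample_snapshot([], "last")


class TestStretchScan:
    def test_targets_hit_and_others_frozen(self, butane):
        distances = [0.8, 1.2, 2.5]
        frames = stretch_scan(butane, 1, 5, distances)
        for fr, d in zip(frames, distances):
            assert fr.distance(1, 5) == pytest.approx(d, abs=1e-10)
            others = [k for k in range(butane.n_atoms) if k != 5]
            assert np.array_equal(fr.positions[others], butane.positions[others])
            assert fr.bonds == butane.bonds

    def test_matches_closed_form_morse_curve(self, toy_params, toy_calc):
        de, a, r0 = toy_params.morse[("H", "H")]
        s = h2_structure(r0)
        distances = list(np.arange(0.6, 5.01, 0.2))
        for fr in stretch_scan(s, 0, 1, distances):
            d = fr.distance(0, 1)
            expect = de * ((1 - np.exp(-a * (d - r0))) ** 2 - 1)
            assert toy_calc.energy(fr) == pytest.approx(expect, abs=1e-8)

    def test_minimum_frame_nearest_equilibrium(self, toy_params, toy_calc):
        _, _, r0 = toy_params.morse[("H", "H")]
        distances = list(np.arange(0.5, 3.0, 0.05))
        frames = stretch_scan(h2_structure(r0), 0, 1, distances)
        energies = [toy_calc.energy(fr) for fr in frames]
        best = distances[int(np.argmin(energies))]
        assert abs(best - r0) <= 0.05 / 2 + 1e-9

    def test_errors(self, butane):
        with pytest.raises(ValueError):
            stretch_scan(butane, 2, 2, [1.0])
        coincident = Structure(["H", "H"], [[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="axis"):
            stretch_scan(coincident, 0, 1, [1.0])
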