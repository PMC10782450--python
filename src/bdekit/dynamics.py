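"""Geometry optimization, Langevin MD sampling and rigid bond scans.

Optimization is the workhorse behind every BDE: both the parent
molecule and each derived radical are relaxed to a local minimum
before their energies enter the dissociation-energy expression.  Two
algorithms are provided: FIRE (default; a velocity-projection scheme
with an explicit descent safeguard so the accepted-step energy log is
non-increasing) and an L-BFGS wrapper around scipy.

Langevin dynamics (BAOAB splitting) emulates the dataset-generation
protocol of sampling one thermalised snapshot per molecule from a hot
trajectory; with friction = 0 the integrator reduces to plain
velocity-Verlet NVE.

Bond-stretch scans are rigid: one atom is translated along the bond
axis, everything else frozen — probing calculator extrapolation along
a dissociation coordinate, not a relaxed path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chemio import ATOMIC_MASSES, Structure
from .potentials import Calculator
from .units import KB_KCAL, KCAL_TO_MD

__all__ = [
    "OptSettings",
    "MDSettings",
    "OptimizationError",
    "optimize",
    "langevin_md",
    "sample_snapshot",
    "stretch_scan",
    "max_force_norm",
]


@dataclass
class OptSettings:
    """Convergence settings for geometry optimization.

    ``fmax`` is the threshold on the largest per-atom force norm in
    kcal/mol/A (default 0.05, ~0.002 eV/A — tight enough that
    minima-matching RMSDs reflect the surfaces, not sloppy
    convergence); ``step_limit`` caps per-atom displacement per step.
    """

    fmax: float = 0.05
    max_steps: int = 2000
    algorithm: str = "fire"
    step_limit: float = 0.2

    def __post_init__(self) -> None:
        if self.fmax <= 0 or self.step_limit <= 0 or self.max_steps < 1:
            raise ValueError("fmax > 0, step_limit > 0, max_steps >= 1 required")
        if self.algorithm not in ("fire", "bfgs"):
            raise ValueError("algorithm must be 'fire' or 'bfgs'")


@dataclass
class MDSettings:
    """Langevin MD settings: temperature (K), timestep (ps),
    friction (1/ps), number of steps and RNG seed."""

    temperature: float = 500.0
    timestep: float = 0.0005
    friction: float = 10.0
    n_steps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature < 0 or self.timestep <= 0 or self.n_steps < 1:
            raise ValueError("temperature >= 0, timestep > 0, n_steps >= 1 required")


class OptimizationError(RuntimeError):
    """Raised when optimization exhausts ``max_steps``.

    Carries the best structure seen (``structure``, with its energy
    attached) and its residual maximum force norm (``residual_force``).
    """

    def __init__(self, message: str, structure: Structure, residual_force: float):
        super().__init__(message)
        self.structure = structure
        self.residual_force = residual_force


def max_force_norm(forces: np.ndarray) -> float:
    """Largest per-atom force norm, kcal/mol/A."""
    return float(np.max(np.linalg.norm(forces, axis=1)))


def _finish(s: Structure, x: np.ndarray, e: float, f: np.ndarray,
            algorithm: str) -> Structure:
    out = s.copy()
    out.positions = x.reshape(-1, 3).copy()
    out.energy = e
    out.forces = f.copy()
    out.tags["opt_algorithm"] = algorithm
    return out


def _optimize_fire(s, calc, opt, history):
    # FIRE parameters.  dt_max is set for bond stiffnesses up to
    # ~1000 kcal/mol/A^2 in the unit-mass fictitious dynamics; stiffer
    # modes are handled by the rejection safeguard shrinking dt.
    dt, dt_max = 0.02, 0.08
    alpha0, f_inc, f_dec, f_alpha, n_min = 0.1, 1.1, 0.5, 0.99, 5
    alpha, n_pos = alpha0, 0

    x = s.positions.copy()
    v = np.zeros_like(x)
    e, f = calc.evaluate(_with_positions(s, x))
    prev_x, prev_e = x.copy(), e
    for _ in range(opt.max_steps):
        fmax = max_force_norm(f)
        if history is not None:
            history.append((e, fmax))
        if fmax <= opt.fmax:
            return _finish(s, x, e, f, "fire")
        p = float(np.sum(f * v))
        if p > 0:
            n_pos += 1
            vn = np.linalg.norm(v)
            fn = np.linalg.norm(f)
            v = (1.0 - alpha) * v + alpha * vn * f / max(fn, 1e-30)
            if n_pos > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            v[:] = 0.0
            dt *= f_dec
            alpha = alpha0
            n_pos = 0
        v = v + dt * f
        dr = dt * v
        norms = np.linalg.norm(dr, axis=1)
        big = norms > opt.step_limit
        if np.any(big):
            dr[big] *= (opt.step_limit / norms[big])[:, None]
        prev_x, prev_e = x.copy(), e
        x = x + dr
        e, f = calc.evaluate(_with_positions(s, x))
        if e > prev_e + 1e-8 * (1.0 + abs(prev_e)):
            # descent safeguard: reject uphill step, restart from rest
            x, v = prev_x.copy(), np.zeros_like(v)
            dt *= f_dec
            n_pos = 0
            e, f = calc.evaluate(_with_positions(s, x))
    best = _finish(s, x, e, f, "fire")
    raise OptimizationError(
        f"FIRE did not reach fmax={opt.fmax} in {opt.max_steps} steps "
        f"(residual {max_force_norm(f):.4f})",
        best,
        max_force_norm(f),
    )


def _optimize_bfgs(s, calc, opt, history):
    from scipy.optimize import minimize

    shape = s.positions.shape

    def fun(xflat):
        e, f = calc.evaluate(_with_positions(s, xflat.reshape(shape)))
        return e, -f.ravel()

    x0 = s.positions.ravel().copy()
    nev = 0
    x = x0
    while True:
        res = minimize(
            fun, x, jac=True, method="L-BFGS-B",
            options={"maxiter": opt.max_steps - nev, "gtol": opt.fmax * 0.2,
                     "ftol": 1e-14},
        )
        x = res.x
        nev += max(res.nit, 1)
        e, f = calc.evaluate(_with_positions(s, x.reshape(shape)))
        if history is not None:
            history.append((e, max_force_norm(f)))
        if max_force_norm(f) <= opt.fmax:
            return _finish(s, x, e, f, "bfgs")
        if nev >= opt.max_steps or res.nit == 0:
            best = _finish(s, x, e, f, "bfgs")
            raise OptimizationError(
                f"L-BFGS did not reach fmax={opt.fmax} "
                f"(residual {max_force_norm(f):.4f})",
                best,
                max_force_norm(f),
            )


def _with_positions(s: Structure, x: np.ndarray) -> Structure:
    out = s.copy()
    out.positions = np.asarray(x, dtype=float).reshape(-1, 3)
    return out


def optimize(
    s: Structure,
    calc: Calculator,
    opt: OptSettings | None = None,
    history: list | None = None,
) -> Structure:
    """Relax ``s`` until the largest per-atom force norm <= ``opt.fmax``.

    The input is not modified; the returned structure carries its
    energy and forces.  Pass a list as ``history`` to receive
    ``(energy, fmax)`` per accepted step.  Deterministic for fixed
    inputs.  Raises :class:`OptimizationError` on non-convergence.
    """
    opt = opt or OptSettings()
    if opt.algorithm == "fire":
        return _optimize_fire(s, calc, opt, history)
    return _optimize_bfgs(s, calc, opt, history)


# ---------------------------------------------------------------------------
# Langevin MD (BAOAB splitting)
# ---------------------------------------------------------------------------

def langevin_md(s: Structure, calc: Calculator, md: MDSettings) -> list[Structure]:
    """Integrate Langevin dynamics; returns the trajectory (initial
    frame included, ``md.n_steps + 1`` frames, each carrying potential
    energy and an instantaneous kinetic temperature tag).

    BAOAB splitting: half-kick, half-drift, Ornstein-Uhlenbeck
    velocity refresh, half-drift, half-kick.  With ``friction == 0``
    the OU step is the identity (temperature ignored) and the scheme
    reduces to velocity-Verlet NVE with zero initial velocities.
    """
    rng = np.random.default_rng(md.seed)
    m = np.array([ATOMIC_MASSES[sym] for sym in s.symbols])[:, None]
    x = s.positions.copy()
    kT = KB_KCAL * md.temperature
    if md.friction > 0 and md.temperature > 0:
        v = rng.standard_normal(x.shape) * np.sqrt(kT * KCAL_TO_MD / m)
    else:
        v = np.zeros_like(x)
    dt = md.timestep
    c1 = float(np.exp(-md.friction * dt)) if md.friction > 0 else 1.0
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))

    def frame(step, e, f):
        fr = _with_positions(s, x)
        fr.energy = e
        fr.forces = f.copy()
        ke = 0.5 * float(np.sum(m * v * v)) / KCAL_TO_MD
        ndof = 3 * s.n_atoms
        fr.tags["step"] = str(step)
        fr.tags["kinetic_energy"] = f"{ke:.8f}"
        fr.tags["temperature"] = f"{2.0 * ke / (ndof * KB_KCAL):.4f}"
        return fr

    e, f = calc.evaluate(_with_positions(s, x))
    traj = [frame(0, e, f)]
    for step in range(1, md.n_steps + 1):
        v = v + 0.5 * dt * KCAL_TO_MD * f / m
        x = x + 0.5 * dt * v
        if md.friction > 0:
            v = c1 * v + c2 * np.sqrt(kT * KCAL_TO_MD / m) * rng.standard_normal(x.shape)
        x = x + 0.5 * dt * v
        e, f = calc.evaluate(_with_positions(s, x))
        if not (np.isfinite(e) and np.all(np.isfinite(f))):
            raise RuntimeError(f"non-finite energy/forces at MD step {step}")
        v = v + 0.5 * dt * KCAL_TO_MD * f / m
        traj.append(frame(step, e, f))
    return traj


def sample_snapshot(
    traj: list[Structure], rule: str = "last", seed: int = 0
) -> Structure:
    """Select one frame from a trajectory: the final one (``last``) or
    a uniformly random one (``random``, seeded)."""
    if not traj:
        raise ValueError("empty trajectory")
    if rule == "last":
        return traj[-1]
    if rule == "random":
        rng = np.random.default_rng(seed)
        return traj[int(rng.integers(len(traj)))]
    raise ValueError(f"unknown snapshot rule {rule!r}")


# ---------------------------------------------------------------------------
# rigid bond-stretch scan
# ---------------------------------------------------------------------------

def stretch_scan(
    s: Structure, i: int, j: int, distances: list[float]
) -> list[Structure]:
    """Rigid scan of the i-j distance: atom ``j`` is translated along
    the i->j axis to each target separation; every other atom (and the
    bond list, charge and multiplicity) is untouched."""
    if i == j:
        raise ValueError("scan atoms must differ")
    axis = s.positions[j] - s.positions[i]
    norm = np.linalg.norm(axis)
    if norm < 1e-10:
        raise ValueError("scan atoms coincide in space: axis undefined")
    axis = axis / norm
    frames = []
    for d in distances:
        if d <= 0:
            raise ValueError("scan distances must be positive")
        fr = s.copy()
        fr.positions[j] = s.positions[i] + d * axis
        fr.tags["scan_distance"] = f"{d:.6f}"
        fr.tags["scan_atoms"] = f"{i},{j}"
        frames.append(fr)
    return frames
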