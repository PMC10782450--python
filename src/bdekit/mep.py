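"""Hydrogen-abstraction endpoints and nudged-elastic-band minimum
energy paths.

The methoxy radical CH3O. is a classic surrogate abstractor for
estimating hydrogen-abstraction activation energies: the reactant is
the substrate plus methoxy poised along the C-H axis, the product is
the substrate radical plus methanol carrying the transferred
hydrogen.  A chain of images between the two endpoints is relaxed
under NEB forces (improved-tangent scheme; optional climbing image
that rides the parallel force up to the saddle).  Non-convergence is
a reported outcome, not an exception — in realistic work a sizeable
fraction of band relaxations stalls, and that fraction is itself a
result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemio import Structure
from .molgraph import RadicalSite
from .potentials import Calculator

__all__ = [
    "MEPResult",
    "StericClashError",
    "build_abstraction_endpoints",
    "interpolate_images",
    "neb",
]


class StericClashError(ValueError):
    """Composite construction placed non-bonded atoms unphysically close."""


@dataclass
class MEPResult:
    """A relaxed (or stalled) chain of images.

    ``barrier_forward`` is ``max(energies) - energies[0]``;
    ``max_force`` the largest NEB-projected per-atom force norm at
    termination (kcal/mol/A).
    """

    images: list[Structure]
    energies: list[float]
    barrier_forward: float
    barrier_reverse: float
    max_force: float
    converged: bool
    n_iterations: int

    def summary(self) -> dict:
        return {
            "n_images": len(self.images),
            "barrier_forward_kcal": self.barrier_forward,
            "barrier_reverse_kcal": self.barrier_reverse,
            "max_force_kcal_per_A": self.max_force,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }


def _methoxy_template():
    from .fixtures import make_fixture, FixtureSpec

    return make_fixture(FixtureSpec(name="methoxy"))


def build_abstraction_endpoints(
    s: Structure,
    site: RadicalSite,
    approach_distance: float = 2.6,
    oh_distance: float = 0.96,
) -> tuple[Structure, Structure]:
    """Construct reactant and product composites for methoxy-mediated
    H abstraction at one sp3 C-H site.

    Reactant: substrate + methoxy radical, O on the extension of the
    C->H axis at ``approach_distance`` from the hydrogen, methyl
    pointing away.  Product: substrate radical + methanol, with the
    transferred H at ``oh_distance`` from O along the same axis.  Both
    composites are doublets with identical atom ordering (substrate
    atoms first, the transferred H keeping its original index,
    abstractor atoms last).
    """
    if s.multiplicity != 1:
        raise ValueError("substrate must be closed shell")
    from scipy.spatial.transform import Rotation

    c, h = site.c_index, site.h_index
    axis = s.positions[h] - s.positions[c]
    axis = axis / np.linalg.norm(axis)

    methoxy = _methoxy_template()
    mo = next(i for i, sym in enumerate(methoxy.symbols) if sym == "O")
    mc = next(i for i, sym in enumerate(methoxy.symbols) if sym == "C")
    oc_dir = methoxy.positions[mc] - methoxy.positions[mo]
    rot, _ = Rotation.align_vectors(axis.reshape(1, 3), oc_dir.reshape(1, 3))
    abstr_pos = rot.apply(methoxy.positions - methoxy.positions[mo])
    o_target = s.positions[h] + approach_distance * axis
    abstr_pos = abstr_pos + o_target

    n_sub = s.n_atoms
    symbols = list(s.symbols) + list(methoxy.symbols)
    o_global = n_sub + mo
    sub_bonds = list(s.bonds or [])
    abstr_bonds = [(i + n_sub, j + n_sub, o) for i, j, o in methoxy.bonds or []]

    reactant = Structure(
        symbols=symbols,
        positions=np.vstack([s.positions, abstr_pos]),
        multiplicity=2,
        bonds=sub_bonds + abstr_bonds,
        tags={**s.tags, "role": "abstraction_reactant", "h_index": str(h)},
    )

    prod_pos = np.vstack([s.positions, abstr_pos])
    prod_pos[h] = o_target - oh_distance * axis
    prod_bonds = [b for b in sub_bonds if {b[0], b[1]} != {c, h}]
    prod_bonds += abstr_bonds + [(min(h, o_global), max(h, o_global), 1)]
    product = Structure(
        symbols=symbols,
        positions=prod_pos,
        multiplicity=2,
        bonds=prod_bonds,
        tags={**s.tags, "role": "abstraction_product", "h_index": str(h)},
    )

    for comp in (reactant, product):
        bonded = {(min(i, j), max(i, j)) for i, j, _ in comp.bonds}
        n = comp.n_atoms
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in bonded:
                    continue
                if np.linalg.norm(comp.positions[i] - comp.positions[j]) < 0.7:
                    raise StericClashError(
                        f"non-bonded atoms {i},{j} closer than 0.7 A in "
                        f"{comp.tags['role']}; try a different approach axis"
                    )
    return reactant, product


def interpolate_images(
    reactant: Structure, product: Structure, n_images: int
) -> list[Structure]:
    """Linear Cartesian interpolation, endpoints included verbatim."""
    if reactant.symbols != product.symbols:
        raise ValueError("endpoint symbol sequences differ")
    if n_images < 3:
        raise ValueError("need at least 3 images")
    images = [reactant.copy()]
    for k in range(1, n_images - 1):
        t = k / (n_images - 1)
        img = reactant.copy()
        img.positions = (1.0 - t) * reactant.positions + t * product.positions
        img.tags["image"] = str(k)
        images.append(img)
    images.append(product.copy())
    return images


def _neb_forces(x, energies, true_forces, k_spring, climbing):
    """Improved-tangent NEB forces for the interior images.

    x: (n_images, n_atoms, 3).  Returns (n_interior, n_atoms, 3).
    """
    n_im = len(x)
    out = np.zeros((n_im - 2,) + x.shape[1:])
    i_climb = -1
    if climbing:
        i_climb = 1 + int(np.argmax(energies[1:-1]))
    for i in range(1, n_im - 1):
        tp = (x[i + 1] - x[i]).ravel()
        tm = (x[i] - x[i - 1]).ravel()
        e0, e1, e2 = energies[i - 1], energies[i], energies[i + 1]
        if e2 > e1 > e0:
            tau = tp
        elif e2 < e1 < e0:
            tau = tm
        else:
            dmax = max(abs(e2 - e1), abs(e0 - e1))
            dmin = min(abs(e2 - e1), abs(e0 - e1))
            tau = tp * dmax + tm * dmin if e2 > e0 else tp * dmin + tm * dmax
        tau = tau / max(np.linalg.norm(tau), 1e-30)
        f_true = true_forces[i].ravel()
        f_par = np.dot(f_true, tau)
        if i == i_climb:
            f = f_true - 2.0 * f_par * tau
        else:
            f_spring = k_spring * (np.linalg.norm(tp) - np.linalg.norm(tm))
            f = (f_true - f_par * tau) + f_spring * tau
        out[i - 1] = f.reshape(x.shape[1:])
    return out


def neb(
    images: list[Structure],
    calc: Calculator,
    k_spring: float = 10.0,
    climbing: bool = True,
    fmax: float = 2.3,
    max_iter: int = 500,
) -> MEPResult:
    """Relax a band of images to a minimum energy path.

    Endpoints are frozen (their coordinates come back bitwise
    unchanged).  Interior images move under the improved-tangent NEB
    force; with ``climbing`` the highest-energy interior image feels
    the inverted parallel true force and no springs, converging onto
    the saddle.  Convergence: largest projected per-atom force norm
    <= ``fmax`` (default 2.3 kcal/mol/A, i.e. 0.1 eV/A).  Exhausting
    ``max_iter`` returns ``converged=False`` rather than raising.
    """
    if len(images) < 3:
        raise ValueError("need at least 3 images")
    symbols = images[0].symbols
    if any(img.symbols != symbols for img in images):
        raise ValueError("inconsistent atom ordering across images")

    x = np.array([img.positions for img in images], dtype=float)
    n_im = len(images)

    def eval_band(xs):
        energies, forces = [], []
        for i in range(n_im):
            img = images[i].copy()
            img.positions = xs[i]
            e, f = calc.evaluate(img)
            energies.append(e)
            forces.append(f)
        return np.array(energies), np.array(forces)

    energies, true_forces = eval_band(x)

    # FIRE on the stacked interior coordinates driven by NEB forces.
    # The projected force field is non-conservative, so the integrator
    # carries a divergence guard: whenever the residual force grows
    # well past the best seen so far, velocities reset and dt shrinks.
    dt, dt_max = 0.02, 0.1
    alpha0, f_inc, f_dec, f_alpha, n_min = 0.1, 1.1, 0.5, 0.99, 5
    alpha, n_pos = alpha0, 0
    v = np.zeros((n_im - 2,) + x.shape[1:])
    step_limit = 0.05

    nf = _neb_forces(x, energies, true_forces, k_spring, climbing)
    max_force = float(np.max(np.linalg.norm(nf, axis=2)))
    best_force = max_force
    n_iter = 0
    converged = max_force <= fmax
    while not converged and n_iter < max_iter:
        n_iter += 1
        p = float(np.sum(nf * v))
        if p > 0:
            n_pos += 1
            vn = np.linalg.norm(v)
            fn = np.linalg.norm(nf)
            v = (1.0 - alpha) * v + alpha * vn * nf / max(fn, 1e-30)
            if n_pos > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            v[:] = 0.0
            dt *= f_dec
            alpha, n_pos = alpha0, 0
        v = v + dt * nf
        dr = dt * v
        norms = np.linalg.norm(dr, axis=2)
        big = norms > step_limit
        if np.any(big):
            dr[big] *= (step_limit / norms[big])[:, None]
        x[1:-1] += dr
        energies, true_forces = eval_band(x)
        if not np.all(np.isfinite(energies)):
            raise RuntimeError(f"non-finite band energy at NEB iteration {n_iter}")
        nf = _neb_forces(x, energies, true_forces, k_spring, climbing)
        max_force = float(np.max(np.linalg.norm(nf, axis=2)))
        if max_force < best_force:
            best_force = max_force
        elif max_force > 10.0 * best_force + 1.0:
            v[:] = 0.0
            dt = max(dt * f_dec, 1e-4)
            alpha, n_pos = alpha0, 0
        converged = max_force <= fmax

    out_images = []
    for i in range(n_im):
        img = images[i].copy()
        if 0 < i < n_im - 1:
            img.positions = x[i].copy()
        img.energy = float(energies[i])
        img.forces = true_forces[i].copy()
        out_images.append(img)
    e = [float(v) for v in energies]
    return MEPResult(
        images=out_images,
        energies=e,
        barrier_forward=max(e) - e[0],
        barrier_reverse=max(e) - e[-1],
        max_force=max_force,
        converged=converged,
        n_iterations=n_iter,
    )
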