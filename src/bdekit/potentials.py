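"""Energy/force calculator contract and the analytic reactive toy force field.

The pipeline is calculator-agnostic: every stage talks to a
:class:`Calculator` that maps a Structure to a total energy (kcal/mol)
and per-atom forces (kcal/mol/A), plus isolated-atom reference energies
(needed because a bond dissociation energy involves the energy of an
isolated hydrogen atom).

The built-in :class:`ToyForceField` is an analytic stand-in for an
ab initio or machine-learned potential.  Its functional form —

    E = sum_bonds  De * [(1 - exp(-a (r - r0)))^2 - 1]
      + sum_angles k * (theta - theta0)^2
      + sum_{pairs >= 3 bonds apart} 4 eps [(sigma/r)^12 - (sigma/r)^6]
      + sum_atoms  E_ref(element)

— uses a Morse bond term whose zero is at dissociation (minimum -De),
so toy bond dissociation energies equal De plus small, exactly
computable relaxation terms.  That gives every downstream stage an
analytic oracle.  Torsions are deliberately omitted (documented
limitation): BDE machinery needs bond/angle energetics, and torsions
would add parameters without adding coverage.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemio import Structure

__all__ = [
    "Calculator",
    "CalculatorUnavailableError",
    "MissingParameterError",
    "ToyFFParams",
    "ToyForceField",
    "toy_ff_energy_forces",
    "radical_energy_convention",
    "AdapterSpec",
    "external_calculator_adapter",
]


class CalculatorUnavailableError(RuntimeError):
    """The requested back end is not importable/executable here."""


class MissingParameterError(KeyError):
    """A required force-field parameter is absent."""


class Calculator:
    """Abstract energy/force back end.

    Subclasses implement :meth:`evaluate` returning
    ``(energy_kcal_per_mol, forces_kcal_per_mol_per_A)`` and must be
    deterministic for a fixed input.  ``atom_reference_energy`` maps an
    element symbol to the energy of the isolated atom under this
    calculator (used as E(H.) in the BDE expression).
    """

    name: str = "calculator"
    atom_reference_energy: dict[str, float] = {}

    def evaluate(self, s: Structure) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    def energy(self, s: Structure) -> float:
        return self.evaluate(s)[0]


# ---------------------------------------------------------------------------
# toy force field
# ---------------------------------------------------------------------------

def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _triple_key(i: str, j: str, k: str) -> tuple[str, str, str]:
    lo, hi = (i, k) if i <= k else (k, i)
    return (lo, j, hi)


@dataclass
class ToyFFParams:
    """Parameters of the toy force field.

    ``morse`` maps an element pair to ``(De, a, r0)`` in
    (kcal/mol, 1/A, A); ``angle`` maps an (outer, centre, outer)
    element triple to ``(k, theta0)`` in (kcal/mol/rad^2, rad);
    ``nonbonded`` maps an element pair to Lennard-Jones
    ``(eps, sigma)`` in (kcal/mol, A), applied to atom pairs three or
    more bonds apart (including disconnected fragments); ``atom_ref``
    maps an element to its isolated-atom energy in kcal/mol.  Lookups
    are symmetric in element order.
    """

    morse: dict[tuple[str, str], tuple[float, float, float]] = field(default_factory=dict)
    angle: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    nonbonded: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    atom_ref: dict[str, float] = field(default_factory=dict)
    #: hyperconjugation-like radical stabilisation: the Morse depth of a
    #: C-H bond is lowered by this amount (kcal/mol) for every heavy
    #: (non-H) neighbour of the carbon, so secondary and alpha-to-O
    #: hydrogens are genuinely easier to abstract than primary ones —
    #: without it every C-H well is identical and within-molecule BDE
    #: spreads collapse to the (tiny) 1-4 LJ differences.
    ch_radical_stabilization: float = 0.0
    version: str = "unversioned"

    def __post_init__(self) -> None:
        self.morse = {_pair_key(*k): tuple(v) for k, v in self.morse.items()}
        self.nonbonded = {_pair_key(*k): tuple(v) for k, v in self.nonbonded.items()}
        self.angle = {_triple_key(*k): tuple(v) for k, v in self.angle.items()}
        for name, vals in (("morse", self.morse), ("nonbonded", self.nonbonded),
                           ("angle", self.angle)):
            for key, v in vals.items():
                if any(x <= 0 for x in v):
                    raise ValueError(f"{name}{key} parameters must all be > 0")
        if self.ch_radical_stabilization < 0:
            raise ValueError("ch_radical_stabilization must be >= 0")

    def get_morse(self, a: str, b: str) -> tuple[float, float, float]:
        try:
            return self.morse[_pair_key(a, b)]
        except KeyError:
            raise MissingParameterError(f"no Morse parameters for pair ({a},{b})")

    def get_angle(self, i: str, j: str, k: str) -> tuple[float, float]:
        try:
            return self.angle[_triple_key(i, j, k)]
        except KeyError:
            raise MissingParameterError(f"no angle parameters for triple ({i},{j},{k})")

    def get_nonbonded(self, a: str, b: str) -> tuple[float, float]:
        try:
            return self.nonbonded[_pair_key(a, b)]
        except KeyError:
            raise MissingParameterError(f"no LJ parameters for pair ({a},{b})")

    def get_atom_ref(self, el: str) -> float:
        try:
            return self.atom_ref[el]
        except KeyError:
            raise MissingParameterError(f"no atom reference energy for element {el}")

    # -- flat key-value config (one section per interaction type) --

    def to_config(self, path: str | Path) -> None:
        import configparser

        cp = configparser.ConfigParser()
        cp["meta"] = {
            "version": self.version,
            "ch_radical_stabilization": str(self.ch_radical_stabilization),
        }
        cp["morse"] = {
            f"{a}-{b}": f"{v[0]} {v[1]} {v[2]}" for (a, b), v in self.morse.items()
        }
        cp["angle"] = {
            f"{i}-{j}-{k}": f"{v[0]} {v[1]}" for (i, j, k), v in self.angle.items()
        }
        cp["nonbonded"] = {
            f"{a}-{b}": f"{v[0]} {v[1]}" for (a, b), v in self.nonbonded.items()
        }
        cp["atom_ref"] = {el: str(e) for el, e in self.atom_ref.items()}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_config(cls, path: str | Path) -> "ToyFFParams":
        import configparser

        cp = configparser.ConfigParser()
        cp.read(path)
        morse = {
            tuple(k.split("-")): tuple(float(x) for x in v.split())
            for k, v in cp["morse"].items()
        }
        angle = {
            tuple(k.split("-")): tuple(float(x) for x in v.split())
            for k, v in cp["angle"].items()
        }
        nb = {
            tuple(k.split("-")): tuple(float(x) for x in v.split())
            for k, v in cp["nonbonded"].items()
        }
        ref = {k: float(v) for k, v in cp["atom_ref"].items()}
        version = cp.get("meta", "version", fallback="unversioned")
        # configparser lowercases keys; restore element capitalisation
        fix = lambda el: el.capitalize()
        return cls(
            morse={tuple(fix(e) for e in k): v for k, v in morse.items()},
            angle={tuple(fix(e) for e in k): v for k, v in angle.items()},
            nonbonded={tuple(fix(e) for e in k): v for k, v in nb.items()},
            atom_ref={fix(k): v for k, v in ref.items()},
            ch_radical_stabilization=float(
                cp.get("meta", "ch_radical_stabilization", fallback="0.0")
            ),
            version=version,
        )


class _Topology:
    """Precompiled interaction lists for one (symbols, bonds) pair."""

    def __init__(self, s: Structure, p: ToyFFParams) -> None:
        if s.bonds is None:
            raise ValueError("toy force field requires an explicit bond list")
        n = s.n_atoms
        adj: dict[int, list[int]] = {i: [] for i in range(n)}
        for i, j, _ in s.bonds:
            adj[i].append(j)
            adj[j].append(i)

        self.bond_idx = np.array([(i, j) for i, j, _ in s.bonds], dtype=int).reshape(-1, 2)
        bp = []
        for i, j, _ in s.bonds:
            de, a_par, r0 = p.get_morse(s.symbols[i], s.symbols[j])
            pair = {s.symbols[i], s.symbols[j]}
            if pair == {"C", "H"} and p.ch_radical_stabilization > 0:
                carbon = i if s.symbols[i] == "C" else j
                n_heavy = sum(1 for v in adj[carbon] if s.symbols[v] != "H")
                de = de - p.ch_radical_stabilization * n_heavy
                if de <= 0:
                    raise ValueError(
                        "ch_radical_stabilization drives a C-H Morse depth below zero"
                    )
            bp.append((de, a_par, r0))
        self.bond_par = np.array(bp, dtype=float).reshape(-1, 3)

        triples = []
        ap = []
        for j in range(n):
            nb = sorted(adj[j])
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    i, k = nb[x], nb[y]
                    triples.append((i, j, k))
                    ap.append(p.get_angle(s.symbols[i], s.symbols[j], s.symbols[k]))
        self.angle_idx = np.array(triples, dtype=int).reshape(-1, 3)
        self.angle_par = np.array(ap, dtype=float).reshape(-1, 2)

        # graph distance by truncated BFS: exclude pairs 1 or 2 bonds apart
        near: set[tuple[int, int]] = set()
        for start in range(n):
            dist = {start: 0}
            q = deque([start])
            while q:
                u = q.popleft()
                if dist[u] == 2:
                    continue
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        q.append(v)
            for u, d in dist.items():
                if 0 < d <= 2:
                    near.add((min(start, u), max(start, u)))
        pairs, lj = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) not in near:
                    pairs.append((i, j))
                    lj.append(p.get_nonbonded(s.symbols[i], s.symbols[j]))
        self.lj_idx = np.array(pairs, dtype=int).reshape(-1, 2)
        self.lj_par = np.array(lj, dtype=float).reshape(-1, 2)

        self.e_ref = float(sum(p.get_atom_ref(sym) for sym in s.symbols))


class ToyForceField(Calculator):
    """Analytic Morse + harmonic-angle + 1-4 Lennard-Jones force field."""

    def __init__(self, params: ToyFFParams, name: str = "toy") -> None:
        self.params = params
        self.name = name
        self._topo_cache: dict[tuple, _Topology] = {}

    @property
    def atom_reference_energy(self) -> dict[str, float]:
        return dict(self.params.atom_ref)

    def _topology(self, s: Structure) -> _Topology:
        key = (tuple(s.symbols), tuple(s.bonds or ()))
        topo = self._topo_cache.get(key)
        if topo is None:
            topo = _Topology(s, self.params)
            self._topo_cache[key] = topo
        return topo

    def evaluate(self, s: Structure) -> tuple[float, np.ndarray]:
        topo = self._topology(s)
        pos = s.positions
        n = s.n_atoms
        energy = topo.e_ref
        forces = np.zeros((n, 3))

        if len(topo.bond_idx):
            i, j = topo.bond_idx[:, 0], topo.bond_idx[:, 1]
            de, a, r0 = topo.bond_par.T
            rij = pos[i] - pos[j]
            r = np.linalg.norm(rij, axis=1)
            ex = np.exp(-a * (r - r0))
            energy += float(np.sum(de * ((1.0 - ex) ** 2 - 1.0)))
            dEdr = 2.0 * de * a * ex * (1.0 - ex)
            fvec = (dEdr / r)[:, None] * rij  # dE/dri
            np.add.at(forces, i, -fvec)
            np.add.at(forces, j, fvec)

        if len(topo.angle_idx):
            ai, aj, ak = topo.angle_idx.T
            k_par, th0 = topo.angle_par.T
            u = pos[ai] - pos[aj]
            v = pos[ak] - pos[aj]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            cos_t = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
            theta = np.arccos(cos_t)
            sin_t = np.sqrt(np.maximum(1.0 - cos_t ** 2, 1e-12))
            energy += float(np.sum(k_par * (theta - th0) ** 2))
            dEdt = 2.0 * k_par * (theta - th0)
            dti = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
            dtk = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
            fi = -dEdt[:, None] * dti
            fk = -dEdt[:, None] * dtk
            np.add.at(forces, ai, fi)
            np.add.at(forces, ak, fk)
            np.add.at(forces, aj, -(fi + fk))

        if len(topo.lj_idx):
            i, j = topo.lj_idx[:, 0], topo.lj_idx[:, 1]
            eps, sig = topo.lj_par.T
            rij = pos[i] - pos[j]
            r = np.linalg.norm(rij, axis=1)
            sr6 = (sig / r) ** 6
            energy += float(np.sum(4.0 * eps * (sr6 ** 2 - sr6)))
            dEdr = 4.0 * eps * (-12.0 * sr6 ** 2 + 6.0 * sr6) / r
            fvec = (dEdr / r)[:, None] * rij
            np.add.at(forces, i, -fvec)
            np.add.at(forces, j, fvec)

        return energy, forces


def toy_ff_energy_forces(
    s: Structure, p: ToyFFParams
) -> tuple[float, np.ndarray]:
    """Functional entry point: energy and analytic forces under ``p``."""
    return ToyForceField(p).evaluate(s)


def radical_energy_convention(s: Structure, p: ToyFFParams) -> float:
    """Energy of an open-shell (doublet) structure under the toy FF.

    Identical functional form evaluated on the radical's own bond
    graph: the homolysed bond simply contributes no term.  No explicit
    spin terms exist in the toy model.
    """
    if s.multiplicity != 2:
        raise ValueError("radical energy convention expects multiplicity 2")
    return toy_ff_energy_forces(s, p)[0]


# ---------------------------------------------------------------------------
# external back-end adapter
# ---------------------------------------------------------------------------

@dataclass
class AdapterSpec:
    """Settings for wrapping an external back end.

    ``backend`` is either a :class:`Calculator` or a callable
    ``Structure -> (energy, forces)`` in the back end's native units;
    conversion factors map those onto kcal/mol and kcal/mol/A.
    """

    name: str
    backend: object = None
    energy_to_kcal: float = 1.0
    force_to_kcal_per_A: float | None = None
    atom_reference_energy: dict[str, float] = field(default_factory=dict)


class _AdapterCalculator(Calculator):
    def __init__(self, spec: AdapterSpec) -> None:
        self.name = spec.name
        self._spec = spec
        fconv = spec.force_to_kcal_per_A
        self._fconv = spec.energy_to_kcal if fconv is None else fconv
        if isinstance(spec.backend, Calculator):
            self._eval = spec.backend.evaluate
            base_ref = spec.backend.atom_reference_energy
        elif callable(spec.backend):
            self._eval = spec.backend
            base_ref = {}
        else:
            raise CalculatorUnavailableError(
                f"back end for adapter {spec.name!r} is unavailable"
            )
        ref = {k: v * spec.energy_to_kcal for k, v in base_ref.items()}
        ref.update(spec.atom_reference_energy)
        self.atom_reference_energy = ref

    def evaluate(self, s: Structure) -> tuple[float, np.ndarray]:
        e, f = self._eval(s)
        return e * self._spec.energy_to_kcal, np.asarray(f) * self._fconv


def external_calculator_adapter(spec: AdapterSpec) -> Calculator:
    """Wrap an external back end as a :class:`Calculator`.

    Availability is checked at construction time, not at first
    evaluate; unit conversion is applied at the boundary.
    """
    return _AdapterCalculator(spec)
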