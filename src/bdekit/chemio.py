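"""Structure container and file IO for XYZ, extended XYZ and SDF V2000.

The :class:`Structure` is the single in-memory molecular representation
used by every stage of the pipeline: chemical symbols, Cartesian
coordinates in Angstrom, integer charge and spin multiplicity, an
optional explicit bond list, and optional attached energy (kcal/mol)
and forces (kcal/mol/A).  Atom indexing is 0-based everywhere;
formats using 1-based indices (SDF) are converted at the boundary.
"""

from __future__ import annotations

import math
import shlex
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Structure",
    "ParseError",
    "UnsupportedDialectError",
    "CollapsedGeometryError",
    "COVALENT_RADII",
    "ATOMIC_MASSES",
    "read_xyz",
    "write_xyz",
    "read_extxyz",
    "write_extxyz",
    "read_sdf_v2000",
    "perceive_bonds",
]


class ParseError(ValueError):
    """Raised for malformed input files."""


class UnsupportedDialectError(ParseError):
    """Raised for recognised-but-unsupported file dialects (e.g. SDF V3000)."""


class CollapsedGeometryError(ValueError):
    """Raised when two atoms sit unphysically close together."""


# Cordero-style single-bond covalent radii, Angstrom.  Embedded so bond
# perception is reproducible independent of any external library version.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "S": 1.05,
    "Cl": 1.02,
    "Ne": 0.58,
}

# Most-abundant-isotope atomic masses, amu.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.0030740,
    "O": 15.9949146,
    "F": 18.9984032,
    "S": 31.9720707,
    "Cl": 34.9688527,
    "Ne": 19.9924402,
}

_KNOWN_ELEMENTS = set(COVALENT_RADII) | {
    "He", "Li", "Be", "B", "Na", "Mg", "Al", "Si", "P", "Ar", "Br", "I",
}


@dataclass
class Structure:
    """A molecule or radical: atoms in 3D with chemical metadata.

    Parameters
    ----------
    symbols
        Chemical element symbols, one per atom.
    positions
        Cartesian coordinates, shape ``(n_atoms, 3)``, Angstrom.
    charge
        Net integer charge (0 throughout this work).
    multiplicity
        Spin multiplicity; 1 = closed shell, 2 = doublet radical.
    bonds
        Optional list of ``(i, j, order)`` with 0-based atom indices.
    energy
        Optional total energy, kcal/mol.
    forces
        Optional per-atom forces, shape ``(n_atoms, 3)``, kcal/mol/A.
    tags
        Free-form string metadata.
    """

    symbols: list[str]
    positions: np.ndarray
    charge: int = 0
    multiplicity: int = 1
    bonds: list[tuple[int, int, int]] | None = None
    energy: float | None = None
    forces: np.ndarray | None = None
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = list(self.symbols)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.positions) != len(self.symbols):
            raise ValueError(
                f"{len(self.symbols)} symbols but {len(self.positions)} positions"
            )
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float).reshape(-1, 3)
            if len(self.forces) != len(self.symbols):
                raise ValueError("forces must supply one 3-vector per atom")
        if self.bonds is not None:
            n = len(self.symbols)
            seen: set[tuple[int, int]] = set()
            norm: list[tuple[int, int, int]] = []
            for i, j, order in self.bonds:
                if not (0 <= i < n and 0 <= j < n):
                    raise ValueError(f"bond ({i},{j}) index out of range for {n} atoms")
                if i == j:
                    raise ValueError(f"self-bond on atom {i}")
                key = (min(i, j), max(i, j))
                if key in seen:
                    raise ValueError(f"duplicate bond {key}")
                seen.add(key)
                norm.append((key[0], key[1], int(order)))
            self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.positions[i] - self.positions[j]))

    def copy(self) -> "Structure":
        return Structure(
            symbols=list(self.symbols),
            positions=self.positions.copy(),
            charge=self.charge,
            multiplicity=self.multiplicity,
            bonds=None if self.bonds is None else list(self.bonds),
            energy=self.energy,
            forces=None if self.forces is None else self.forces.copy(),
            tags=dict(self.tags),
        )


# ---------------------------------------------------------------------------
# plain XYZ
# ---------------------------------------------------------------------------

def _check_symbol(sym: str, lineno: int) -> str:
    s = sym.capitalize() if len(sym) <= 2 else sym
    if s not in _KNOWN_ELEMENTS:
        raise ParseError(f"line {lineno}: unknown element symbol {sym!r}")
    return s


def read_xyz(path: str | Path) -> list[Structure]:
    """Read a (possibly multi-frame) plain XYZ file.

    Bonds are not populated; use :func:`perceive_bonds` if connectivity
    is needed downstream.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Structure] = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            nat = int(lines[k].split()[0])
        except (ValueError, IndexError):
            raise ParseError(f"line {k + 1}: malformed atom-count line {lines[k]!r}")
        if k + 1 + nat >= len(lines) + 1 and nat > 0 and k + 1 + nat > len(lines):
            raise ParseError(f"line {k + 1}: frame declares {nat} atoms but file ends early")
        comment = lines[k + 1] if k + 1 < len(lines) else ""
        symbols, pos = [], []
        for a in range(nat):
            ln = k + 2 + a
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"line {ln + 1}: expected 'symbol x y z'")
            symbols.append(_check_symbol(parts[0], ln + 1))
            pos.append([float(x) for x in parts[1:4]])
        frames.append(
            Structure(symbols, np.array(pos).reshape(-1, 3), tags={"comment": comment})
        )
        k += 2 + nat
    return frames


def write_xyz(path: str | Path, structures: Structure | list[Structure]) -> None:
    """Write one or more frames as plain XYZ (8-decimal coordinates)."""
    if isinstance(structures, Structure):
        structures = [structures]
    out = []
    for s in structures:
        out.append(str(s.n_atoms))
        out.append(s.tags.get("comment", ""))
        for sym, p in zip(s.symbols, s.positions):
            out.append(f"{sym:<3s} {p[0]:16.8f} {p[1]:16.8f} {p[2]:16.8f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def _parse_extxyz_comment(comment: str, lineno: int):
    """Parse key=value tokens of an extxyz comment line."""
    kv: dict[str, str] = {}
    for tok in shlex.split(comment):
        if "=" in tok:
            k, v = tok.split("=", 1)
            kv[k] = v
    props = kv.get("Properties", "species:S:1:pos:R:3")
    fields = props.split(":")
    if len(fields) % 3 != 0:
        raise ParseError(f"line {lineno}: malformed Properties declaration {props!r}")
    columns: list[tuple[str, int]] = []
    for i in range(0, len(fields), 3):
        name, _kind, width = fields[i], fields[i + 1], int(fields[i + 2])
        columns.append((name, width))
    return kv, columns


def read_extxyz(path: str | Path) -> list[Structure]:
    """Read extended XYZ: per-frame ``energy`` and per-atom ``forces``
    are populated when declared.  Lattice keys are ignored (gas phase
    molecules only).  Accepts both ``energy`` and ``Energy`` keys.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Structure] = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            nat = int(lines[k].split()[0])
        except (ValueError, IndexError):
            raise ParseError(f"line {k + 1}: malformed atom-count line {lines[k]!r}")
        kv, columns = _parse_extxyz_comment(lines[k + 1], k + 2)
        ncols = sum(w for _, w in columns)
        symbols: list[str] = []
        pos_rows, force_rows = [], []
        for a in range(nat):
            ln = k + 2 + a
            parts = lines[ln].split()
            if len(parts) != ncols:
                raise ParseError(
                    f"line {ln + 1}: {len(parts)} columns but Properties declares {ncols}"
                )
            off = 0
            for name, width in columns:
                vals = parts[off : off + width]
                off += width
                if name == "species":
                    symbols.append(_check_symbol(vals[0], ln + 1))
                elif name == "pos":
                    pos_rows.append([float(x) for x in vals])
                elif name == "forces":
                    force_rows.append([float(x) for x in vals])
        energy = None
        for key in ("energy", "Energy"):
            if key in kv:
                energy = float(kv[key])
                break
        frames.append(
            Structure(
                symbols,
                np.array(pos_rows).reshape(-1, 3),
                energy=energy,
                forces=np.array(force_rows) if force_rows else None,
            )
        )
        k += 2 + nat
    return frames


def write_extxyz(path: str | Path, structures: Structure | list[Structure]) -> None:
    """Write frames as extended XYZ, declaring forces when present."""
    if isinstance(structures, Structure):
        structures = [structures]
    out = []
    for s in structures:
        out.append(str(s.n_atoms))
        props = "species:S:1:pos:R:3"
        if s.forces is not None:
            props += ":forces:R:3"
        comment = f"Properties={props}"
        if s.energy is not None:
            comment += f" energy={s.energy!r}"
        for k, v in s.tags.items():
            if k != "comment" and " " not in str(v):
                comment += f" {k}={v}"
        out.append(comment)
        for a in range(s.n_atoms):
            row = f"{s.symbols[a]:<3s} " + " ".join(
                f"{x:18.10f}" for x in s.positions[a]
            )
            if s.forces is not None:
                row += " " + " ".join(f"{x:18.10f}" for x in s.forces[a])
            out.append(row)
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# SDF V2000 (read only)
# ---------------------------------------------------------------------------

_RDKIT_BOND_ORDER = {"SINGLE": 1, "DOUBLE": 2, "TRIPLE": 3, "AROMATIC": 4}


def read_sdf_v2000(path: str | Path) -> list[Structure]:
    """Read a multi-record SDF file (V2000 dialect only).

    Bond orders come from the bond block (aromatic encoded as 4), the
    net charge from ``M  CHG`` lines; multiplicity defaults to 1.
    """
    from rdkit import Chem

    text = Path(path).read_text()
    # Validate dialect per record before handing to RDKit: the counts
    # line is line 4 of each record.
    for rec in text.split("$$$$"):
        lines = rec.strip("\n").splitlines()
        if len(lines) >= 4 and "V3000" in lines[3]:
            raise UnsupportedDialectError(
                "SDF V3000 records are not supported; convert to V2000"
            )

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    structures: list[Structure] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"SDF record {idx}: unparseable (counts line mismatch?)")
        conf = mol.GetConformer()
        symbols = [a.GetSymbol() for a in mol.GetAtoms()]
        pos = np.array(
            [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
             for i in range(mol.GetNumAtoms())]
        )
        bonds = []
        for b in mol.GetBonds():
            order = _RDKIT_BOND_ORDER.get(str(b.GetBondType()), 1)
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        charge = sum(a.GetFormalCharge() for a in mol.GetAtoms())
        structures.append(Structure(symbols, pos, charge=charge, bonds=bonds))
    return structures


# ---------------------------------------------------------------------------
# bond perception
# ---------------------------------------------------------------------------

def perceive_bonds(s: Structure, scale: float = 1.2) -> Structure:
    """Assign single bonds from covalent radii.

    A bond (order 1) is added between atoms i, j iff
    ``d(i, j) <= scale * (r_cov(i) + r_cov(j))``.  Existing bonds are
    replaced.  Returns a new Structure; the input is untouched.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not np.all(np.isfinite(s.positions)):
        raise ValueError("positions must be finite")
    n = s.n_atoms
    radii = np.array([COVALENT_RADII[sym] for sym in s.symbols])
    out = s.copy()
    bonds: list[tuple[int, int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            d = s.distance(i, j)
            if d < 0.4:
                raise CollapsedGeometryError(
                    f"atoms {i} and {j} are only {d:.3f} A apart: collapsed geometry"
                )
            if d <= scale * (radii[i] + radii[j]):
                bonds.append((i, j, 1))
    out.bonds = bonds
    return out
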