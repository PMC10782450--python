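"""BDE computation, the per-molecule pipeline, cross-relaxation minima
matching, Kabsch RMSD and error summaries.

The homolytic bond dissociation energy of an R-H bond is

    BDE = E(R.) + E(H.) - E(RH)

with all three energies from the same calculator and the molecule and
radical each relaxed to a local minimum.  Comparing two calculators
on this quantity is subtle: relaxing the same start S with calculator
A (-> M) and calculator B (-> D) can land in *different* local minima,
so the M-vs-D displacement mixes genuine surface error with optimizer
indeterminacy.  The cross-relaxation protocol removes the ambiguity by
re-relaxing each result with the other method (M -> D', D -> M'): D'
vs M and D vs M' compare matched minima only.  Every BDE record is
therefore labelled with the geometry policy that produced it —
conflating the schemes changes the apparent error substantially.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chemio import Structure
from .dynamics import OptimizationError, OptSettings, optimize
from .molgraph import RadicalSite, enumerate_sp3_ch_sites, hydrogen_equivalence_classes, make_radical
from .potentials import Calculator

__all__ = [
    "BDERecord",
    "CrossRelaxResult",
    "ErrorSummary",
    "compute_bde",
    "bde_pipeline",
    "kabsch_rmsd",
    "cross_relax",
    "bde_error_summary",
]

log = logging.getLogger(__name__)


@dataclass
class BDERecord:
    """One site's dissociation energy and its constituent energies.

    ``geometry_policy`` names the relaxation scheme of the geometries
    the energies were evaluated on (``M`` = relaxed with the same
    calculator, the single-calculator default; ``D``/``Dprime``/
    ``Mprime`` in cross-calculator workflows).
    """

    site: RadicalSite
    e_parent: float
    e_radical: float
    e_h: float
    bde: float
    geometry_policy: str = "M"
    converged: bool = True

    def __post_init__(self) -> None:
        expect = self.e_radical + self.e_h - self.e_parent
        if abs(self.bde - expect) > 1e-9:
            raise ValueError("bde must equal e_radical + e_h - e_parent")


@dataclass
class CrossRelaxResult:
    """The five-geometry quartet-plus-start of the minima-matching
    protocol, with the four pairwise RMSDs (A)."""

    S: Structure
    D: Structure
    M: Structure
    Dprime: Structure
    Mprime: Structure
    rmsd: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class ErrorSummary:
    """RMSE and MAE in kcal/mol; MARE in percent."""

    rmse: float
    mae: float
    mare: float


def compute_bde(e_parent: float, e_radical: float, e_h: float) -> float:
    """Homolytic bond dissociation energy,
    ``E(radical) + E(H atom) - E(parent)``, kcal/mol."""
    return e_radical + e_h - e_parent


def _h_reference(calc: Calculator) -> float:
    ref = calc.atom_reference_energy
    if "H" not in ref:
        raise ValueError(
            f"calculator {calc.name!r} defines no isolated-H reference energy"
        )
    return ref["H"]


def bde_pipeline(
    s: Structure,
    calc: Calculator,
    opt: OptSettings | None = None,
    dedup: bool = False,
) -> list[BDERecord]:
    """Full per-molecule BDE computation.

    The parent is optimized once; each sp3 C-H site (or, with
    ``dedup``, the lowest-index member of each symmetry-equivalence
    class) yields a radical built from the relaxed parent and
    independently optimized.  E(H.) comes from the calculator's
    isolated-atom reference.  Records are sorted by ``h_index``.
    Non-convergent optimizations flag the record (best-so-far
    energies) instead of aborting the molecule.
    """
    opt = opt or OptSettings()
    sites = enumerate_sp3_ch_sites(s)
    sites = hydrogen_equivalence_classes(s, sites)
    if dedup:
        first: dict[int, RadicalSite] = {}
        for site in sites:
            first.setdefault(site.eq_class, site)
        sites = sorted(first.values(), key=lambda t: t.h_index)
    e_h = _h_reference(calc)

    parent_ok = True
    try:
        parent = optimize(s, calc, opt)
    except OptimizationError as err:
        parent = err.structure
        parent_ok = False
        log.warning("parent optimization failed: %s", err)

    records = []
    failures = []
    for site in sites:
        radical = make_radical(parent, site)
        rad_ok = True
        try:
            rad_opt = optimize(radical, calc, opt)
        except OptimizationError as err:
            rad_opt = err.structure
            rad_ok = False
            failures.append(site.h_index)
        bde = compute_bde(parent.energy, rad_opt.energy, e_h)
        records.append(
            BDERecord(
                site=site,
                e_parent=parent.energy,
                e_radical=rad_opt.energy,
                e_h=e_h,
                bde=bde,
                geometry_policy="M",
                converged=parent_ok and rad_ok,
            )
        )
    if failures:
        log.warning(
            "%d/%d radical optimizations did not converge (h_index: %s)",
            len(failures), len(sites), failures,
        )
    return sorted(records, key=lambda r: r.site.h_index)


# ---------------------------------------------------------------------------
# Kabsch RMSD
# ---------------------------------------------------------------------------

def kabsch_rmsd(a: Structure, b: Structure) -> float:
    """Minimum RMSD between two same-ordering structures over proper
    rotations and translations (Kabsch superposition, det(R) = +1
    enforced — mirror matching would mask chirality differences).
    All atoms enter with equal weight, hydrogens included.
    """
    if a.symbols != b.symbols:
        raise ValueError("symbol sequences differ; reordering is out of scope")
    p = a.positions - a.positions.mean(axis=0)
    q = b.positions - b.positions.mean(axis=0)
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # apply the rotation explicitly: the singular-value shortcut for
    # the residual loses ~1e-7 A to cancellation, this stays exact
    diff = p @ rot.T - q
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def cross_relax(
    S: Structure,
    calcA: Calculator,
    calcB: Calculator,
    opt: OptSettings | None = None,
) -> CrossRelaxResult:
    """Minima-matching protocol between two calculators.

    From start S: ``M = optimize(S, calcA)``, ``D = optimize(S, calcB)``,
    ``Dprime = optimize(M, calcB)``, ``Mprime = optimize(D, calcA)``.
    The matched-minima comparisons are (Dprime, M) and (D, Mprime);
    (D, M) mixes in basin mismatch and (Dprime, D) measures it on one
    surface alone.
    """
    opt = opt or OptSettings()

    def leg(start, calc, name):
        try:
            out = optimize(start, calc, opt)
        except OptimizationError as err:
            raise OptimizationError(
                f"cross-relaxation leg {name} did not converge: {err}",
                err.structure, err.residual_force,
            )
        out.tags["crossrelax_leg"] = name
        return out

    M = leg(S, calcA, "S->M")
    D = leg(S, calcB, "S->D")
    Dprime = leg(M, calcB, "M->D'")
    Mprime = leg(D, calcA, "D->M'")
    rmsd = {
        ("D", "M"): kabsch_rmsd(D, M),
        ("Dprime", "M"): kabsch_rmsd(Dprime, M),
        ("D", "Mprime"): kabsch_rmsd(D, Mprime),
        ("Dprime", "D"): kabsch_rmsd(Dprime, D),
    }
    return CrossRelaxResult(S=S.copy(), D=D, M=M, Dprime=Dprime, Mprime=Mprime, rmsd=rmsd)


def bde_error_summary(pred: list[float], ref: list[float]) -> ErrorSummary:
    """RMSE, MAE (kcal/mol) and MARE (%) of predicted vs reference BDEs."""
    pred_a = np.asarray(pred, dtype=float)
    ref_a = np.asarray(ref, dtype=float)
    if pred_a.shape != ref_a.shape or pred_a.size == 0:
        raise ValueError("pred and ref must have equal nonzero length")
    if np.any(ref_a == 0):
        raise ValueError("MARE undefined: reference contains zero values")
    diff = pred_a - ref_a
    return ErrorSummary(
        rmse=float(np.sqrt(np.mean(diff**2))),
        mae=float(np.mean(np.abs(diff))),
        mare=float(np.mean(np.abs(diff) / np.abs(ref_a)) * 100.0),
    )
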