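# bdekit

A calculator-agnostic pipeline for homolytic sp³ C–H **bond dissociation
energies** (BDEs) and the machinery needed to evaluate any energy/force
back end on that task: radical enumeration, geometry optimization,
cross-relaxation minima matching, BDE rank evaluation with Kendall's τ,
rigid bond-stretch scans, Langevin snapshot sampling and
hydrogen-abstraction minimum energy paths (climbing-image NEB).

## Who this is for

Aliphatic hydroxylation by cytochrome P450 enzymes — the dominant
phase-I route of drug metabolism — is rate-limited by hydrogen-atom
abstraction from an sp³ C–H bond. The BDE of each candidate bond,

    BDE = E(R•) + E(H•) − E(RH),

with molecule and radical each relaxed to a local minimum, is a practical
proxy for the relative reactivity of the sites, and the *rank* of BDEs
within a molecule points at the likely site of metabolism. `bdekit`
provides the full workflow around any calculator that can supply
energies and forces (a semi-empirical method, a machine-learned
interatomic potential, a force field), plus the evaluation protocols a
method developer needs:

- **Cross-relaxation minima matching.** Relaxing the same start S with
  two methods (S→M with method A, S→D with method B) can land in
  *different* local minima, so the D-vs-M displacement conflates genuine
  surface error with optimizer indeterminacy. Re-relaxing each result
  with the other method (M→D′, D→M′) guarantees matched minima: D′-vs-M
  and D-vs-M′ isolate the true disagreement. Every comparison is
  labelled with its geometry policy because the two conventions give
  systematically different error statistics.
- **Rank evaluation.** Per-molecule BDE ranks compared via tie-corrected
  Kendall τ-b, summarised as one τ per molecule and their mean.
- **Reaction paths.** Methoxy-radical hydrogen abstraction endpoints and
  improved-tangent climbing-image NEB with a convergence threshold of
  0.1 eV/Å (≈ 2.3 kcal/mol/Å).

Everything is exercisable at desk scale with no external data through a
built-in analytic reactive toy force field (Morse bonds with the zero at
dissociation, harmonic angles, 1-4+ Lennard-Jones) whose BDEs are known
in closed form — every pipeline stage ships with an exact oracle.

## Worked example

```python
from bdekit import (FixtureSpec, OptSettings, ToyForceField,
                    bde_pipeline, default_toy_params, make_fixture)

calc = ToyForceField(default_toy_params())
butane = make_fixture(FixtureSpec(name="butane"))
for r in bde_pipeline(butane, calc, OptSettings(fmax=0.01, algorithm="bfgs"),
                      dedup=True):
    print(f"H{r.site.h_index} (class {r.site.eq_class}): "
          f"BDE = {r.bde:.2f} kcal/mol")
```

prints

```
H4 (class 0): BDE = 96.99 kcal/mol
H7 (class 1): BDE = 94.02 kcal/mol
```

Butane's ten sp³ hydrogens fall into two symmetry classes (methyl and
methylene); with deduplication one radical per class is optimized. The
secondary (methylene) C–H is ~3 kcal/mol weaker than the primary one —
the toy analogue of radical stabilisation by alkyl substitution, and the
reason secondary sites are the usual oxidation targets.

The `examples/` directory holds one short script per capability: site
enumeration, the BDE pipeline, cross-relaxation, rank correlation under
noise, NEB barriers against grid-scan saddles, and MD sampling plus
rigid scans. A thin CLI mirrors the library:

```bash
bdekit fixtures butane --out out
bdekit bde out/butane.xyz --dedup --out out
bdekit crossrelax out/butane.xyz --out out
```

## Scope

Single-geometry BDEs only: no conformer ensembles or free energies, no
zero-point or thermal enthalpy corrections, no electronic-structure
computation (spin-state crossings along dissociation are outside any
single-surface model), and no transition-state refinement beyond the
climbing image. Periodic systems and SDF V3000 are unsupported.
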