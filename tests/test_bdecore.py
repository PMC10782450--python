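"""BDE arithmetic and pipeline, Kabsch RMSD, cross-relaxation and
error metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import grid_search_rmsd, hand_summed_toy_energy
from bdekit.bdecore import (
    BDERecord,
    bde_error_summary,
    bde_pipeline,
    compute_bde,
    cross_relax,
    kabsch_rmsd,
)
from bdekit.chemio import Structure
from bdekit.dynamics import OptSettings, optimize
from bdekit.fixtures import (
    FixtureSpec,
    default_toy_params,
    make_double_well_pair,
    make_fixture,
)
from bdekit.molgraph import RadicalSite, enumerate_sp3_ch_sites
from bdekit.potentials import ToyForceField, radical_energy_convention


class TestComputeBDE:
    @pytest.mark.parametrize("e_parent,e_radical,e_h,expect", [
        (-10.0, -5.0, 0.0, 5.0),
        (0.0, 0.0, 0.0, 0.0),
    ])
    def test_arithmetic(self, e_parent, e_radical, e_h, expect):
        assert compute_bde(e_parent, e_radical, e_h) == expect

    def test_frozen_ch_morse_equals_well_depth(self, toy_params, toy_calc):
        """At frozen geometries an isolated C-H Morse bond dissociates
        by exactly its well depth."""
        de, _, r0 = toy_params.morse[("C", "H")]
        ch = Structure(["C", "H"], [[0, 0, 0], [r0, 0, 0]], bonds=[(0, 1, 1)])
        carbon = Structure(["C"], [[0, 0, 0]], multiplicity=2, bonds=[])
        bde = compute_bde(
            toy_calc.energy(ch),
            radical_energy_convention(carbon, toy_params),
            toy_params.atom_ref["H"],
        )
        assert bde == pytest.approx(de, abs=1e-6)

    def test_relaxed_methane_matches_hand_summed_oracle(self, toy_params, toy_calc):
        s = make_fixture(FixtureSpec(name="methane"))
        recs = bde_pipeline(s, toy_calc, OptSettings(fmax=1e-5))
        sites = enumerate_sp3_ch_sites(s)
        parent = optimize(s, toy_calc, OptSettings(fmax=1e-5))
        from bdekit.molgraph import make_radical

        for rec, site in zip(recs, sites):
            rad = optimize(make_radical(parent, site), toy_calc,
                           OptSettings(fmax=1e-5))
            oracle = (
                hand_summed_toy_energy(rad, toy_params)
                + toy_params.atom_ref["H"]
                - hand_summed_toy_energy(parent, toy_params)
            )
            assert rec.bde == pytest.approx(oracle, abs=1e-6)

    def test_record_consistency_enforced(self):
        site = RadicalSite("m", 1, 0)
        with pytest.raises(ValueError):
            BDERecord(site, e_parent=-10, e_radical=-5, e_h=0, bde=4.0)


class TestPipeline:
    def test_butane_site_and_dedup_counts(self, toy_calc, butane):
        full = bde_pipeline(butane, toy_calc)
        dedup = bde_pipeline(butane, toy_calc, dedup=True)
        assert len(full) == 10
        assert len(dedup) == 2
        assert [r.site.h_index for r in full] == sorted(
            r.site.h_index for r in full
        )
        # dedup picks the lowest-index member of each class
        classes = {}
        for r in full:
            classes.setdefault(r.site.eq_class, []).append(r.site.h_index)
        assert sorted(r.site.h_index for r in dedup) == sorted(
            min(v) for v in classes.values()
        )

    def test_well_depth_shift_propagates(self, butane):
        base = default_toy_params()
        raised = default_toy_params()
        de, a, r0 = raised.morse[("C", "H")]
        raised.morse[("C", "H")] = (de + 10.0, a, r0)
        b0 = [r.bde for r in bde_pipeline(butane, ToyForceField(base))]
        b1 = [r.bde for r in bde_pipeline(butane, ToyForceField(raised))]
        for x, y in zip(b0, b1):
            assert y - x == pytest.approx(10.0, abs=1.0)

    def test_h2_yields_no_records(self, toy_calc):
        h2 = Structure(["H", "H"], [[0, 0, 0], [0.74, 0, 0]], bonds=[(0, 1, 1)])
        assert bde_pipeline(h2, toy_calc) == []

    def test_energy_scale_shifts(self, butane):
        """Per-atom reference shifts cancel out of the BDE (the atom
        that leaves takes its own reference along); a per-structure
        constant shift moves every BDE by exactly the shift the
        isolated H atom picks up."""
        shift = 7.5
        base = default_toy_params()
        per_atom = default_toy_params()
        per_atom.atom_ref = {k: v + shift for k, v in per_atom.atom_ref.items()}
        b0 = bde_pipeline(butane, ToyForceField(base))
        b1 = bde_pipeline(butane, ToyForceField(per_atom))
        for x, y in zip(b0, b1):
            assert y.bde - x.bde == pytest.approx(0.0, abs=1e-6)

        class Shifted(ToyForceField):
            def evaluate(self, s):
                e, f = super().evaluate(s)
                return e + shift, f

            @property
            def atom_reference_energy(self):
                return {k: v + shift
                        for k, v in super().atom_reference_energy.items()}

        b2 = bde_pipeline(butane, Shifted(base))
        for x, y in zip(b0, b2):
            assert y.bde - x.bde == pytest.approx(shift, abs=1e-6)


class TestKabsch:
    def test_identity(self, butane):
        assert kabsch_rmsd(butane, butane) < 1e-12

    def test_rigid_motion_invariance(self, butane):
        rng = np.random.default_rng(5)
        for _ in range(20):
            moved = butane.copy()
            moved.positions = Rotation.random(rng=rng).apply(butane.positions)
            moved.positions += rng.standard_normal(3) * 5
            assert kabsch_rmsd(butane, moved) < 1e-10

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(12)
        for trial in range(3):
            base = rng.standard_normal((4, 3)) * 1.5
            a = Structure(["C", "H", "H", "O"], base)
            moved = base.copy()
            moved[trial] += rng.standard_normal(3) * 0.5
            b = Structure(["C", "H", "H", "O"],
                          Rotation.random(rng=rng).apply(moved) + 2.0)
            assert kabsch_rmsd(a, b) == pytest.approx(
                grid_search_rmsd(a, b), abs=1e-4
            )

    def test_symbol_mismatch_rejected(self):
        a = Structure(["C", "H"], [[0, 0, 0], [1, 0, 0]])
        b = Structure(["H", "C"], [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            kabsch_rmsd(a, b)


class TestCrossRelax:
    def test_identical_surfaces_give_zero_rmsd(self, toy_calc):
        s = make_fixture(FixtureSpec(name="propane", perturbation=0.05, seed=2))
        res = cross_relax(s, toy_calc, toy_calc,
                          OptSettings(fmax=1e-4, algorithm="bfgs"))
        assert res.rmsd[("D", "M")] < 1e-6
        assert res.rmsd[("Dprime", "D")] < 1e-6

    def test_double_well_basin_mismatch_pattern(self):
        """A start that falls in different basins under the two
        surfaces: same-start comparison sees the inter-basin distance,
        re-relaxed comparisons see only the basin offset."""
        offset = 0.3
        a, b = make_double_well_pair(offset=offset, barrier_shift=1.0)
        start = a.minimum_structure("right")
        start.positions[0] = [0.15, 0.05, -0.02]
        res = cross_relax(start, a, b, OptSettings(fmax=1e-4))
        ideal = {
            "M": a.minimum_structure("right"),
            "D": b.minimum_structure("left"),
            "Dprime": b.minimum_structure("right"),
            "Mprime": a.minimum_structure("left"),
        }
        for pair in (("D", "M"), ("Dprime", "M"), ("D", "Mprime"), ("Dprime", "D")):
            oracle = kabsch_rmsd(ideal[pair[0]], ideal[pair[1]])
            assert res.rmsd[pair] == pytest.approx(oracle, abs=1e-3)
        assert res.rmsd[("Dprime", "M")] < 0.25 * res.rmsd[("D", "M")]

    def test_role_swap_consistency(self):
        a, b = make_double_well_pair(offset=0.3, barrier_shift=1.0)
        start = a.minimum_structure("right")
        start.positions[0] = [0.15, 0.05, -0.02]
        fwd = cross_relax(start, a, b, OptSettings(fmax=1e-4))
        rev = cross_relax(start, b, a, OptSettings(fmax=1e-4))
        # swapping roles relabels the quartet: M<->D, D'<->M'
        assert fwd.rmsd[("D", "M")] == pytest.approx(rev.rmsd[("D", "M")], abs=1e-6)
        assert fwd.rmsd[("Dprime", "M")] == pytest.approx(
            rev.rmsd[("D", "Mprime")], abs=1e-6
        )

    def test_provenance_tags(self, toy_calc):
        s = make_fixture(FixtureSpec(name="ethane"))
        res = cross_relax(s, toy_calc, toy_calc, OptSettings())
        assert res.M.tags["crossrelax_leg"] == "S->M"
        assert res.Dprime.tags["crossrelax_leg"] == "M->D'"

    def test_triangle_like_bound_on_quartet(self, toy_calc):
        s = make_fixture(FixtureSpec(name="ethanol", perturbation=0.04, seed=7))
        res = cross_relax(s, toy_calc, toy_calc,
                          OptSettings(fmax=1e-4, algorithm="bfgs"))
        assert res.rmsd[("Dprime", "M")] <= (
            res.rmsd[("D", "M")] + res.rmsd[("Dprime", "D")] + 1e-9
        )


class TestErrorSummary:
    def test_identity(self):
        s = bde_error_summary([1.0, 2.0], [1.0, 2.0])
        assert (s.rmse, s.mae, s.mare) == (0.0, 0.0, 0.0)

    def test_two_element_arithmetic(self):
        s = bde_error_summary([2.0, 4.0], [1.0, 2.0])
        assert s.rmse == pytest.approx(np.sqrt(2.5))
        assert s.mae == 1.5
        assert s.mare == pytest.approx(100.0)

    def test_against_naive_reimplementation(self):
        rng = np.random.default_rng(3)
        pred = rng.standard_normal(1000) * 5 + 100
        ref = rng.standard_normal(1000) * 5 + 100
        s = bde_error_summary(list(pred), list(ref))
        diffs = [p - r for p, r in zip(pred, ref)]
        assert s.rmse == pytest.approx(
            (sum(d * d for d in diffs) / 1000) ** 0.5, abs=1e-12)
        assert s.mae == pytest.approx(sum(abs(d) for d in diffs) / 1000, abs=1e-12)
        assert s.mare == pytest.approx(
            sum(abs(d) / abs(r) for d, r in zip(diffs, ref)) / 1000 * 100,
            abs=1e-12)
        assert s.rmse >= s.mae >= 0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="MARE"):
            bde_error_summary([1.0], [0.0])
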