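"""Enumerate abstractable sp3 C-H sites and their symmetry classes.

Builds butane and ethanol, lists every hydrogen bonded to an sp3
carbon, and groups the symmetry-equivalent ones.  Equivalent sites
yield the same radical up to relabelling, so only one member of each
class needs an expensive calculation.
"""

from bdekit import (
    FixtureSpec,
    enumerate_sp3_ch_sites,
    hydrogen_equivalence_classes,
    make_fixture,
)

for name in ("butane", "ethanol"):
    mol = make_fixture(FixtureSpec(name=name))
    sites = hydrogen_equivalence_classes(mol, enumerate_sp3_ch_sites(mol))
    classes = {}
    for s in sites:
        classes.setdefault(s.eq_class, []).append(s.h_index)
    print(f"{name}: {len(sites)} sp3 C-H sites, {len(classes)} classes")
    for c, members in classes.items():
        print(f"  class {c}: hydrogens {members}")
# Butane shows 10 sites in 2 classes (6 methyl + 4 methylene H);
# ethanol's hydroxyl hydrogen is not listed - it sits on oxygen.
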