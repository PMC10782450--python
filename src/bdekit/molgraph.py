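"""Molecular-graph operations: sp3 C-H site enumeration, hydrogen
symmetry-equivalence classes and radical generation.

A "site" is one abstractable hydrogen on an sp3 carbon, the precursor
of a carbon radical produced by homolytic C-H cleavage.  sp3 is defined
purely topologically: a carbon with exactly four neighbours, all via
single bonds.  This is robust to geometric distortion (e.g. hot MD
snapshots), where a hybridisation test based on angles would not be.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .chemio import Structure

__all__ = [
    "RadicalSite",
    "MissingBondsError",
    "enumerate_sp3_ch_sites",
    "hydrogen_equivalence_classes",
    "make_radical",
    "sites_to_tsv",
]


class MissingBondsError(ValueError):
    """Structure has no bond list; perceive or supply connectivity first."""


@dataclass
class RadicalSite:
    """One abstractable sp3 C-H hydrogen.

    ``eq_class`` is -1 until assigned by
    :func:`hydrogen_equivalence_classes`.
    """

    parent_id: str
    h_index: int
    c_index: int
    eq_class: int = -1


def _adjacency(s: Structure) -> dict[int, list[tuple[int, int]]]:
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(s.n_atoms)}
    for i, j, order in s.bonds or []:
        adj[i].append((j, order))
        adj[j].append((i, order))
    return adj


def enumerate_sp3_ch_sites(s: Structure) -> list[RadicalSite]:
    """Enumerate hydrogens bonded to sp3 carbons, ascending ``h_index``.

    Hydrogens on oxygen (or any atom that is not a four-coordinate
    all-single-bond carbon) are excluded: only aliphatic C-H homolysis
    is in scope.
    """
    if s.bonds is None:
        raise MissingBondsError(
            "structure has no bonds; call perceive_bonds or load from SDF"
        )
    if s.multiplicity != 1:
        raise ValueError("site enumeration expects a closed-shell parent")
    adj = _adjacency(s)
    parent_id = s.tags.get("name", "structure")
    sites = []
    for h in range(s.n_atoms):
        if s.symbols[h] != "H" or len(adj[h]) != 1:
            continue
        c, order = adj[h][0]
        if order != 1 or s.symbols[c] != "C":
            continue
        if len(adj[c]) == 4 and all(o == 1 for _, o in adj[c]):
            sites.append(RadicalSite(parent_id=parent_id, h_index=h, c_index=c))
    return sites


def _refine_labels(s: Structure) -> list[tuple]:
    """Morgan-style iterative neighbourhood refinement.

    Labels are full tuples (not hashes), so two atoms share a final
    label only if their entire refinement histories coincide — hash
    collisions cannot merge inequivalent atoms.
    """
    adj = _adjacency(s)
    labels: list[tuple] = [
        (s.symbols[i], len(adj[i]), tuple(sorted(o for _, o in adj[i])))
        for i in range(s.n_atoms)
    ]

    def partition(ls):
        groups: dict[tuple, list[int]] = {}
        for i, l in enumerate(ls):
            groups.setdefault(l, []).append(i)
        return sorted(tuple(v) for v in groups.values())

    for _ in range(s.n_atoms + 1):
        old_part = partition(labels)
        new = [
            (labels[i], tuple(sorted(labels[j] for j, _ in adj[i])))
            for i in range(s.n_atoms)
        ]
        if partition(new) == old_part:
            break
        labels = new
    return labels


def hydrogen_equivalence_classes(
    s: Structure, sites: list[RadicalSite]
) -> list[RadicalSite]:
    """Group sites whose hydrogens are graph-equivalent.

    Hydrogens with identical refined neighbourhood labels share an
    ``eq_class``; class ids are renumbered 0..k-1 in order of first
    appearance along ascending ``h_index``.  Returns new site objects;
    the inputs are untouched.
    """
    labels = _refine_labels(s)
    class_of: dict[tuple, int] = {}
    out = []
    for site in sites:
        lab = labels[site.h_index]
        if lab not in class_of:
            class_of[lab] = len(class_of)
        out.append(
            RadicalSite(site.parent_id, site.h_index, site.c_index, class_of[lab])
        )
    return out


def make_radical(s: Structure, site: RadicalSite) -> Structure:
    """Delete the site's hydrogen, producing the doublet radical.

    Surviving atoms keep their coordinates exactly; bonds are
    re-indexed; tags record provenance (parent id and deleted index).
    """
    if s.multiplicity != 1:
        raise ValueError("parent must be closed shell (multiplicity 1)")
    h = site.h_index
    if not (0 <= h < s.n_atoms) or s.symbols[h] != "H":
        raise ValueError(f"site.h_index {h} is not a hydrogen of this structure")
    keep = [i for i in range(s.n_atoms) if i != h]
    remap = {old: new for new, old in enumerate(keep)}
    bonds = None
    if s.bonds is not None:
        bonds = [
            (remap[i], remap[j], o)
            for i, j, o in s.bonds
            if i != h and j != h
        ]
    tags = dict(s.tags)
    tags["parent_id"] = site.parent_id
    tags["deleted_h_index"] = str(h)
    return Structure(
        symbols=[s.symbols[i] for i in keep],
        positions=s.positions[keep].copy(),
        charge=s.charge,
        multiplicity=2,
        bonds=bonds,
        tags=tags,
    )


def sites_to_tsv(sites: list[RadicalSite], path: str | Path) -> None:
    """Export sites as TSV: parent_id, h_index, c_index, eq_class."""
    rows = ["parent_id\th_index\tc_index\teq_class"]
    rows += [
        f"{t.parent_id}\t{t.h_index}\t{t.c_index}\t{t.eq_class}" for t in sites
    ]
    Path(path).write_text("\n".join(rows) + "\n")
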