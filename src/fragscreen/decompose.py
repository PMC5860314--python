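"""Rigid-fragment decomposition of compounds.

A fragment is a connected heavy-atom substructure with no internal torsional
degree of freedom: rotating about any bond inside it moves only hydrogens.
Compounds are split so that every fragment is rigid in this sense, which lets
a docking engine place each fragment once, with no conformational search.

The algorithm has four stages:

1. **Bond classification** — every bond is RIGID or CLEAVABLE.  Ring bonds
   are rigid (all ring systems are treated as rigid, including saturated
   rings like cyclohexane, whose ring puckering is ignored); double, triple
   and aromatic bonds are rigid; acyclic single bonds between two sp/sp2
   atoms (conjugation) and amide C–N bonds are rigid.  Everything else is
   cleavable.  Two exceptions restore strict heavy-atom rigidity: an acyclic
   single bond joining two ring atoms (a biaryl-type linkage) is cleavable
   even when both atoms are sp2, because the rings twist freely about it;
   and every acyclic single bond at a hypervalent or non-organic-subset atom
   is cleavable (conservative treatment of exotic chemistry).
2. **Rigid-group determination** — connected components over rigid bonds.
   Components with >= 2 heavy atoms are rigid groups; every remaining heavy
   atom is a *solitary* group.
3. **Solitary merging** — a solitary atom with one or two adjacent groups, at
   least one of them non-solitary, is merged into *each* adjacent non-solitary
   group (so a CH2 bridging two rings is duplicated into both ring
   fragments).  A solitary atom with three or more adjacent groups stays a
   single-atom fragment, as does a solitary atom adjacent only to other
   solitary atoms.  Merging is single-pass: merged atoms never seed further
   merges, which would create heavy-atom rotors.
4. **Capping** — each final group is extracted as a molecule and every
   valence vacated by a broken bond is filled with one hydrogen.  Single-atom
   fragments cap to the corresponding hydride (CH4, NH3, ...).

The cleaved-bond count records how many parent bonds ended up inside no
fragment; it is the decomposition-aggressiveness covariate used by the linear
score-fitting model.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum

from rdkit import Chem

from .chemio import Molecule

log = logging.getLogger(__name__)

__all__ = [
    "BondLabel",
    "Group",
    "GroupAssignment",
    "Decomposition",
    "classify_bonds",
    "find_groups",
    "merge_solitary",
    "cap_and_extract",
    "decompose",
]

# Elements whose bonding we trust for the conjugation/amide rigidity rules.
_ORGANIC_SUBSET = {1, 5, 6, 7, 8, 9, 15, 16, 17, 35, 53}

_PT = Chem.GetPeriodicTable()


class BondLabel(str, Enum):
    RIGID = "RIGID"
    CLEAVABLE = "CLEAVABLE"


def _is_exotic(atom: Chem.Atom) -> bool:
    """Non-organic-subset or hypervalent atom: cleave all its single acyclic bonds."""
    if atom.GetAtomicNum() not in _ORGANIC_SUBSET:
        return True
    default = _PT.GetDefaultValence(atom.GetAtomicNum())
    if default < 0:
        return True
    # formal charge shifts the accessible valence (e.g. N+ carries 4 bonds)
    return atom.GetTotalValence() > default + atom.GetFormalCharge()


def _is_pi_hybrid(atom: Chem.Atom) -> bool:
    return atom.GetHybridization() in (
        Chem.HybridizationType.SP,
        Chem.HybridizationType.SP2,
    )


def _is_amide_cn(a: Chem.Atom, b: Chem.Atom) -> bool:
    """Single C–N bond where the carbon bears a double bond to oxygen."""
    for n_atom, c_atom in ((a, b), (b, a)):
        if n_atom.GetAtomicNum() == 7 and c_atom.GetAtomicNum() == 6:
            for bond in c_atom.GetBonds():
                other = bond.GetOtherAtom(c_atom)
                if (other.GetAtomicNum() == 8
                        and bond.GetBondType() == Chem.BondType.DOUBLE):
                    return True
    return False


def classify_bonds(m: Molecule) -> list[BondLabel]:
    """Label every bond of ``m`` RIGID or CLEAVABLE (indexed by RDKit bond index)."""
    labels: list[BondLabel] = []
    for bond in m.mol.GetBonds():
        labels.append(_classify_bond(bond))
    return labels


def _classify_bond(bond: Chem.Bond) -> BondLabel:
    if bond.IsInRing():
        return BondLabel.RIGID
    if bond.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE,
                              Chem.BondType.AROMATIC):
        return BondLabel.RIGID
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    # conservative cleavage around exotic/hypervalent centres
    if _is_exotic(a) or _is_exotic(b):
        return BondLabel.CLEAVABLE
    # biaryl-type exception: two ring systems joined by an acyclic single
    # bond twist freely, whatever the hybridization says
    if a.IsInRing() and b.IsInRing():
        return BondLabel.CLEAVABLE
    if _is_pi_hybrid(a) and _is_pi_hybrid(b):
        return BondLabel.RIGID
    if _is_amide_cn(a, b):
        return BondLabel.RIGID
    return BondLabel.CLEAVABLE


@dataclass(frozen=True)
class Group:
    atoms: frozenset[int]
    solitary: bool

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class GroupAssignment:
    """Groups over parent heavy atoms plus the cleavable-bond adjacency between them."""

    groups: list[Group]
    # (group_i, group_j, parent bond index) for every CLEAVABLE bond
    edges: list[tuple[int, int, int]]

    def adjacent(self, gi: int) -> set[int]:
        out = set()
        for a, b, _ in self.edges:
            if a == gi:
                out.add(b)
            elif b == gi:
                out.add(a)
        return out


def find_groups(m: Molecule, labels: list[BondLabel]) -> GroupAssignment:
    """Connected components over RIGID bonds; singletons become solitary groups."""
    n = m.mol.GetNumAtoms()
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for bond in m.mol.GetBonds():
        if labels[bond.GetIdx()] is BondLabel.RIGID:
            ra, rb = find(bond.GetBeginAtomIdx()), find(bond.GetEndAtomIdx())
            if ra != rb:
                parent[ra] = rb

    comp: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        comp[find(i)].append(i)

    # deterministic group order: by smallest member atom index
    members = sorted(comp.values(), key=lambda atoms: min(atoms))
    groups = [Group(atoms=frozenset(a), solitary=len(a) == 1) for a in members]
    atom_to_group = {a: gi for gi, g in enumerate(groups) for a in g.atoms}

    edges = []
    for bond in m.mol.GetBonds():
        if labels[bond.GetIdx()] is BondLabel.CLEAVABLE:
            gi = atom_to_group[bond.GetBeginAtomIdx()]
            gj = atom_to_group[bond.GetEndAtomIdx()]
            edges.append((gi, gj, bond.GetIdx()))
    return GroupAssignment(groups=groups, edges=edges)


def merge_solitary(m: Molecule, g: GroupAssignment,
                   merge_mode: str = "duplicate") -> list[frozenset[int]]:
    """Apply the solitary-merging rule; returns the final fragment atom sets.

    ``merge_mode="duplicate"`` (default) copies a solitary atom bridging two
    non-solitary groups into both; ``"unique"`` assigns it to the larger
    adjacent group only (tie broken by lower canonical atom rank), giving a
    strict partition of the parent atoms.
    """
    if merge_mode not in ("duplicate", "unique"):
        raise ValueError(f"unknown merge_mode {merge_mode!r}")

    final: list[set[int]] = [set(grp.atoms) for grp in g.groups]
    keep = [True] * len(g.groups)
    ranks = None

    for gi, grp in enumerate(g.groups):
        if not grp.solitary:
            continue
        adj = g.adjacent(gi)
        nonsol = [gj for gj in adj if not g.groups[gj].solitary]
        if len(adj) >= 3 or not nonsol:
            continue  # Fig-2-type branching atom, or solitary-only neighborhood
        targets = nonsol
        if merge_mode == "unique" and len(nonsol) > 1:
            if ranks is None:
                ranks = list(Chem.CanonicalRankAtoms(m.mol, breakTies=True))
            targets = [min(nonsol,
                           key=lambda gj: (-len(g.groups[gj]),
                                           min(ranks[a] for a in g.groups[gj].atoms)))]
        atom = next(iter(grp.atoms))
        for gj in targets:
            final[gj].add(atom)
        keep[gi] = False

    out = [frozenset(s) for s, k in zip(final, keep) if k]
    return sorted(out, key=min)


@dataclass
class Decomposition:
    """Capped rigid fragments of one compound plus provenance."""

    parent_id: str
    fragments: list[Molecule]
    # fragment atom index -> parent atom index, one tuple per fragment
    atom_maps: list[tuple[int, ...]]
    cleaved_bond_count: int
    merge_mode: str = "duplicate"

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


def _extract_fragment(parent: Chem.Mol, atoms: frozenset[int]) -> tuple[Chem.Mol, tuple[int, ...]]:
    """Extract ``atoms`` as a connected molecule, hydrogen-capping broken valences."""
    rw = Chem.RWMol(parent)
    for atom in rw.GetAtoms():
        atom.SetIntProp("_parentIdx", atom.GetIdx())

    severed: dict[int, int] = defaultdict(int)
    for bond in parent.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (i in atoms) != (j in atoms):
            severed[i if i in atoms else j] += 1

    for idx, k in severed.items():
        atom = rw.GetAtomWithIdx(idx)
        atom.SetNumExplicitHs(atom.GetNumExplicitHs() + k)
        # cleavage destroys the stereo context at the cut point
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)

    # drop double-bond stereo whose reference atoms are being removed
    for bond in rw.GetBonds():
        if bond.GetStereo() != Chem.BondStereo.STEREONONE:
            if any(a not in atoms for a in bond.GetStereoAtoms()) or \
               bond.GetBeginAtomIdx() not in atoms or bond.GetEndAtomIdx() not in atoms:
                bond.SetStereo(Chem.BondStereo.STEREONONE)

    for idx in sorted(set(range(parent.GetNumAtoms())) - atoms, reverse=True):
        rw.RemoveAtom(idx)

    frag = rw.GetMol()
    Chem.SanitizeMol(frag)
    Chem.AssignStereochemistry(frag, cleanIt=True, force=True)
    if len(Chem.GetMolFrags(frag)) != 1:
        raise RuntimeError("internal error: extracted fragment is disconnected")
    atom_map = tuple(a.GetIntProp("_parentIdx") for a in frag.GetAtoms())
    return frag, atom_map


def cap_and_extract(m: Molecule, atom_sets: list[frozenset[int]],
                    merge_mode: str = "duplicate") -> Decomposition:
    """Extract and hydrogen-cap every final group; count cleaved parent bonds."""
    fragments: list[Molecule] = []
    atom_maps: list[tuple[int, ...]] = []
    covered: set[int] = set()

    for i, atoms in enumerate(atom_sets):
        frag, amap = _extract_fragment(m.mol, atoms)
        fragments.append(Molecule(mol=frag, id=f"{m.id}_f{i}"))
        atom_maps.append(amap)
        for bond in m.mol.GetBonds():
            if bond.GetBeginAtomIdx() in atoms and bond.GetEndAtomIdx() in atoms:
                covered.add(bond.GetIdx())

    cleaved = m.mol.GetNumBonds() - len(covered)
    return Decomposition(parent_id=m.id, fragments=fragments, atom_maps=atom_maps,
                         cleaved_bond_count=cleaved, merge_mode=merge_mode)


def decompose(m: Molecule, merge_mode: str = "duplicate") -> Decomposition:
    """Full decomposition: classify -> group -> merge -> cap.

    Deterministic: the same molecule (under any atom numbering) yields the
    same multiset of fragment keys and the same cleaved-bond count.
    """
    labels = classify_bonds(m)
    assignment = find_groups(m, labels)
    atom_sets = merge_solitary(m, assignment, merge_mode=merge_mode)
    return cap_and_extract(m, atom_sets, merge_mode=merge_mode)
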