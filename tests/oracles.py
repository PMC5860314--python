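"""Independent brute-force checkers used by unit and acceptance tests.

These re-derive expected quantities from first principles, without calling
the code paths they validate.
"""

from collections import Counter

from rdkit import Chem


def rotor_violations(frag_mol: Chem.Mol) -> list[int]:
    """Bond indices about which rotation would move a heavy atom.

    A rigid fragment must have none: every internal single acyclic bond that
    is not torsion-locked (amide C-N, or sp/sp2 conjugation outside a
    ring-ring linkage) must have at least one terminal endpoint, so that only
    hydrogens move when it turns.
    """
    bad = []
    for bond in frag_mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() < 2 or b.GetDegree() < 2:  # heavy-atom degree
            continue  # terminal bond: rotation moves hydrogens only
        if _amide_cn(a, b):
            continue
        pi = (Chem.HybridizationType.SP, Chem.HybridizationType.SP2)
        if (a.GetHybridization() in pi and b.GetHybridization() in pi
                and not (a.IsInRing() and b.IsInRing())):
            continue  # conjugation-locked (but biaryl-type linkages do twist)
        bad.append(bond.GetIdx())
    return bad


def _amide_cn(a, b):
    for n_atom, c_atom in ((a, b), (b, a)):
        if n_atom.GetAtomicNum() == 7 and c_atom.GetAtomicNum() == 6:
            for bond in c_atom.GetBonds():
                if (bond.GetOtherAtom(c_atom).GetAtomicNum() == 8
                        and bond.GetBondType() == Chem.BondType.DOUBLE):
                    return True
    return False


def check_decomposition_invariants(molecule, decomposition) -> None:
    """Assert ring preservation, atom coverage/duplication and rigidity."""
    parent = molecule.mol
    n = parent.GetNumAtoms()

    coverage = Counter()
    for amap in decomposition.atom_maps:
        for idx in amap:
            coverage[idx] += 1

    # every heavy atom appears in at least one fragment, never in three
    assert set(coverage) == set(range(n)), \
        f"{molecule.id}: atoms {set(range(n)) - set(coverage)} missing from fragments"
    assert max(coverage.values()) <= 2, f"{molecule.id}: atom in >2 fragments"

    # no ring bond is ever cleaved: both its atoms co-occur in some fragment
    atom_sets = [set(amap) for amap in decomposition.atom_maps]
    for bond in parent.GetBonds():
        if bond.IsInRing():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            assert any(i in s and j in s for s in atom_sets), \
                f"{molecule.id}: ring bond {i}-{j} cleaved"

    # duplicated atoms are exactly the 2-neighbor bridging solitaries:
    # duplication implies presence in exactly two fragments (checked above);
    # here, every duplicated atom must be terminal in both its fragments
    for idx, count in coverage.items():
        if count == 2:
            for amap in decomposition.atom_maps:
                if idx in amap:
                    s = set(amap)
                    heavy_neighbors = sum(
                        1 for nb in parent.GetAtomWithIdx(idx).GetNeighbors()
                        if nb.GetIdx() in s)
                    assert heavy_neighbors == 1, \
                        f"{molecule.id}: duplicated atom {idx} not terminal"

    for frag in decomposition.fragments:
        bad = rotor_violations(frag.mol)
        assert not bad, (f"{molecule.id}: fragment {Chem.MolToSmiles(frag.mol)} "
                         f"has heavy-atom rotors at bonds {bad}")


def independent_zhao(m) -> float:
    """Volume formula recomputed with separate bond/ring bookkeeping."""
    from fragscreen.screen import ZHAO_ATOM_VOLUMES
    mol = m.mol
    v, bonds = 0.0, 0
    for atom in mol.GetAtoms():
        v += ZHAO_ATOM_VOLUMES[atom.GetSymbol()]
        v += atom.GetTotalNumHs() * 7.24
        bonds += atom.GetTotalNumHs()
        bonds += sum(1 for _ in atom.GetBonds())
    bonds -= sum(1 for _ in mol.GetBonds())  # heavy bonds were double-counted
    v -= 5.92 * bonds
    for ring in mol.GetRingInfo().AtomRings():
        aromatic = all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
        v -= 14.7 if aromatic else 3.8
    return v


def brute_force_ef(ranked_ids, actives, fraction) -> float:
    """Direct counting of the enrichment-factor definition."""
    n = len(ranked_ids)
    top = max(1, int(fraction * n))
    pos_x = len([c for c in ranked_ids[:top] if c in actives])
    pos_100 = len([c for c in ranked_ids if c in actives])
    return (pos_x / top) / (pos_100 / n)
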