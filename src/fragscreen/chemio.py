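"""Molecular I/O and identity.

This module owns the molecular data model (a thin identified wrapper around an
RDKit ``Mol``), reading and writing of SMILES / SDF libraries, canonical
fragment keys, and scalar molecular properties (molecular weight, logP).

The canonical fragment key is the deduplication primitive of the whole
pipeline: two capped fragments with the same heavy-atom + hydrogen-count
structure must map to the same key regardless of input atom ordering, so that
a docking score computed once can be shared by every compound containing the
fragment.  The key dialect is RDKit canonical isomeric SMILES; stereocentres
destroyed by bond cleavage are wiped by the decomposer before keying.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors
from rdkit import RDLogger

log = logging.getLogger(__name__)

# RDKit is chatty on stderr during batch parsing; errors are reported through
# our own logging/exceptions instead.
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "Molecule",
    "MoleculeError",
    "ParseError",
    "DuplicateIDError",
    "parse_smiles",
    "read_library",
    "write_smiles",
    "write_sdf",
    "canonical_key",
    "molecular_weight",
    "logp",
]


class MoleculeError(ValueError):
    """Base error for molecular parsing/identity failures."""


class ParseError(MoleculeError):
    pass


class DuplicateIDError(MoleculeError):
    pass


@dataclass
class Molecule:
    """An identified molecule: RDKit ``Mol`` plus a compound ID.

    The wrapped mol is sanitized (aromaticity, hybridization and implicit
    hydrogens perceived, ring membership set).  Atom indices are the RDKit
    indices, contiguous from 0.
    """

    mol: Chem.Mol
    id: str = ""

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def num_hetero_atoms(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Molecule(id={self.id!r}, smiles={self.to_smiles()!r})"


def parse_smiles(text: str, id: str = "") -> Molecule:
    """Parse one SMILES record into a perceived :class:`Molecule`.

    Multi-component SMILES (salts, mixtures) are reduced to the largest
    covalent component; the event is logged.

    Raises
    ------
    ParseError
        On malformed SMILES or a valence violation, naming the record.
    """
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ParseError(f"record {id or '<anonymous>'}: cannot parse SMILES {text!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        log.info("record %s: multi-component input, keeping largest of %d components",
                 id or "<anonymous>", len(frags))
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return Molecule(mol=mol, id=id)


def _iter_smi(path: Path) -> Iterator[tuple[str, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            yield smiles, mol_id


def read_library(path: str | Path, format: str | None = None) -> list[Molecule]:
    """Read a compound library from a ``.smi`` or SDF file.

    Molecules are returned in file order.  Malformed records are skipped and
    logged (counted); duplicate compound IDs are an error.

    Parameters
    ----------
    path
        Input file.  ``format`` is inferred from the suffix when not given
        (``.smi``/``.txt`` -> smi, ``.sdf``/``.mol`` -> sdf).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "sdf" if path.suffix.lower() in (".sdf", ".mol") else "smi"
    if format not in ("smi", "sdf"):
        raise ValueError(f"unknown library format {format!r}")

    mols: list[Molecule] = []
    seen: set[str] = set()
    n_skipped = 0

    if format == "smi":
        for smiles, mol_id in _iter_smi(path):
            try:
                m = parse_smiles(smiles, id=mol_id)
            except ParseError as exc:
                log.warning("skipping record: %s", exc)
                n_skipped += 1
                continue
            if m.id in seen:
                raise DuplicateIDError(f"duplicate compound ID {m.id!r} in {path}")
            seen.add(m.id)
            mols.append(m)
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                log.warning("skipping unparseable SDF record %d in %s", i, path)
                n_skipped += 1
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record{i}"
            if mol_id in seen:
                raise DuplicateIDError(f"duplicate compound ID {mol_id!r} in {path}")
            seen.add(mol_id)
            mols.append(Molecule(mol=mol, id=mol_id))

    if not mols:
        log.warning("library %s: no parseable records", path)
    log.info("read %d molecules from %s (%d skipped)", len(mols), path, n_skipped)
    return mols


def write_smiles(mols: Iterable[Molecule], path: str | Path) -> int:
    """Write molecules as ``SMILES<TAB>ID`` lines; returns the record count."""
    n = 0
    with open(path, "w") as fh:
        for m in mols:
            fh.write(f"{m.to_smiles()}\t{m.id}\n")
            n += 1
    return n


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> int:
    """Write molecules to an SDF V2000 file (ID on the title line)."""
    writer = Chem.SDWriter(str(path))
    n = 0
    for m in mols:
        mol = Chem.Mol(m.mol)
        mol.SetProp("_Name", m.id)
        writer.write(mol)
        n += 1
    writer.close()
    return n


def canonical_key(fragment: Molecule) -> str:
    """Canonical key of a capped fragment (RDKit canonical SMILES).

    Deterministic and invariant to atom renumbering.  The input must be a
    single connected component (a capped fragment has no dangling bonds).
    """
    if len(Chem.GetMolFrags(fragment.mol)) != 1:
        raise MoleculeError(
            f"fragment {fragment.id!r} is disconnected; canonical keys are "
            "defined for connected capped fragments only")
    return Chem.MolToSmiles(fragment.mol)


def molecular_weight(m: Molecule) -> float:
    """Average molecular weight in Da, implicit hydrogens included."""
    for atom in m.mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            raise MoleculeError(f"molecule {m.id!r} contains an unknown element (dummy atom)")
    return Descriptors.MolWt(m.mol)


def logp(m: Molecule) -> tuple[float, str]:
    """Octanol/water logP estimate with the method name.

    Returns ``(value, "Crippen-Wildman")``: the atomic-contribution method of
    Wildman & Crippen as implemented in RDKit.  Different logP methods differ
    by several tenths of a unit, so the method name travels with the value.
    """
    return Crippen.MolLogP(m.mol), "Crippen-Wildman"
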