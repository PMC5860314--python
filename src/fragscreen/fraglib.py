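"""Deduplicated fragment libraries.

Derivative-rich compound libraries share fragments heavily: keying every
capped fragment canonically and storing each unique fragment once means a
docking backend scores each fragment a single time, however many compounds
contain it.  The library also keeps, per compound, the multiset of fragment
keys (multiplicity matters for SUM/GS aggregation) and the cleaved-bond
count.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .chemio import Molecule, canonical_key, parse_smiles
from .decompose import decompose

log = logging.getLogger(__name__)

__all__ = ["CompoundRecord", "FragmentLibrary", "build_library",
           "reduction_ratio", "fragments_of"]

FRAGMENTS_TSV = "fragments.tsv"
MAPPING_TSV = "mapping.tsv"


@dataclass
class CompoundRecord:
    keys: Counter  # fragment key -> multiplicity
    cleaved_bonds: int

    @property
    def n_fragments(self) -> int:
        return sum(self.keys.values())


@dataclass
class FragmentLibrary:
    """Unique capped fragments plus the compound -> fragment-key mapping."""

    unique_fragments: dict[str, Molecule] = field(default_factory=dict)
    records: dict[str, CompoundRecord] = field(default_factory=dict)
    merge_mode: str = "duplicate"

    @property
    def n_compounds(self) -> int:
        return len(self.records)

    @property
    def n_unique_fragments(self) -> int:
        return len(self.unique_fragments)

    def add_compound(self, m: Molecule) -> None:
        if m.id in self.records:
            raise ValueError(f"duplicate compound ID {m.id!r}")
        dec = decompose(m, merge_mode=self.merge_mode)
        keys: Counter = Counter()
        for frag in dec.fragments:
            key = canonical_key(frag)
            keys[key] += 1
            if key not in self.unique_fragments:
                self.unique_fragments[key] = Molecule(mol=frag.mol, id=key)
        self.records[m.id] = CompoundRecord(keys=keys,
                                            cleaved_bonds=dec.cleaved_bond_count)

    def save(self, out_dir: str | Path) -> None:
        """Persist as two TSVs (diff-able, tool-agnostic)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / FRAGMENTS_TSV, "w") as fh:
            fh.write("fragment_key\tsmiles\n")
            for key in sorted(self.unique_fragments):
                fh.write(f"{key}\t{self.unique_fragments[key].to_smiles()}\n")
        with open(out_dir / MAPPING_TSV, "w") as fh:
            fh.write("compound_id\tfragment_key\tmultiplicity\tcleaved_bonds\n")
            for cid, rec in self.records.items():
                for key in sorted(rec.keys):
                    fh.write(f"{cid}\t{key}\t{rec.keys[key]}\t{rec.cleaved_bonds}\n")

    @classmethod
    def load(cls, in_dir: str | Path, merge_mode: str = "duplicate") -> "FragmentLibrary":
        in_dir = Path(in_dir)
        lib = cls(merge_mode=merge_mode)
        frags = pd.read_csv(in_dir / FRAGMENTS_TSV, sep="\t")
        for _, row in frags.iterrows():
            lib.unique_fragments[row.fragment_key] = parse_smiles(
                row.smiles, id=row.fragment_key)
        mapping = pd.read_csv(in_dir / MAPPING_TSV, sep="\t")
        for cid, grp in mapping.groupby("compound_id", sort=False):
            keys = Counter(dict(zip(grp.fragment_key, grp.multiplicity)))
            lib.records[str(cid)] = CompoundRecord(
                keys=keys, cleaved_bonds=int(grp.cleaved_bonds.iloc[0]))
        unknown = set().union(*(r.keys for r in lib.records.values())) \
            - set(lib.unique_fragments) if lib.records else set()
        if unknown:
            raise ValueError(f"mapping references unknown fragment keys: {sorted(unknown)[:3]}...")
        return lib


def build_library(compounds: Iterable[Molecule],
                  merge_mode: str = "duplicate") -> FragmentLibrary:
    """Decompose, key and deduplicate every compound.

    A compound whose decomposition fails is skipped and logged rather than
    aborting the batch.  The resulting library is independent of input order
    (dict insertion order aside, which the save format normalizes).
    """
    lib = FragmentLibrary(merge_mode=merge_mode)
    n_failed = 0
    for m in compounds:
        try:
            lib.add_compound(m)
        except ValueError:
            raise
        except Exception as exc:  # decomposition/sanitization failure
            log.warning("skipping compound %s: %s", m.id, exc)
            n_failed += 1
    log.info("built library: %d compounds, %d unique fragments (%d skipped)",
             lib.n_compounds, lib.n_unique_fragments, n_failed)
    return lib


def reduction_ratio(lib: FragmentLibrary) -> float:
    """Compounds per unique fragment — the docking-work reduction factor."""
    if lib.n_unique_fragments == 0:
        raise ValueError("empty library has no reduction ratio")
    return lib.n_compounds / lib.n_unique_fragments


def fragments_of(lib: FragmentLibrary, compound_id: str) -> Counter:
    """The stored fragment-key multiset of one compound."""
    if compound_id not in lib.records:
        raise KeyError(f"unknown compound ID {compound_id!r}")
    return Counter(lib.records[compound_id].keys)
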