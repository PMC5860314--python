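"""Synthetic libraries and planted-signal benchmarks.

Real screening libraries are derivative-rich: many compounds share ring
cores and substituents, which is exactly what makes fragment deduplication
pay off.  This module emulates that structure with a hard-coded scaffold
vocabulary — saturated ring cores and aromatic ring substituents, chosen so
that every capped fragment is pairwise non-isomorphic — joined by one
cleavable single bond.  A cores x substituents grid therefore decomposes to
exactly ``n_cores + n_substituents`` unique fragments, an exact oracle for
the deduplication machinery.

Benchmarks plant a signal through fragment composition, not 3D
complementarity: actives are built from a small "privileged" substituent
subset whose mock docking scores are shifted by -delta (more favorable),
decoys sample the rest of the grid.  Passing benchmarks therefore validates
the aggregation/ranking machinery, not docking physics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chemio import Molecule, parse_smiles, canonical_key
from .docking import MockScorerParams, ScoreTable, score_library
from .fraglib import FragmentLibrary, build_library

log = logging.getLogger(__name__)

__all__ = ["CORES", "SUBSTITUENTS", "LINKERS", "FixtureSpec", "Benchmark",
           "gen_combinatorial", "gen_benchmark", "gen_random_library",
           "write_labels"]

# Saturated ring cores.  The last-written atom is always a ring carbon: the
# substituent SMILES is appended directly, bonding its first atom there.
CORES: tuple[str, ...] = (
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCCCCC1", "C1CCCCCCC1",
    "C1OC1", "C1OCC1", "C1OCCC1", "C1OCCCC1", "C1OCCCCC1",
    "C1NCC1", "C1NCCC1", "C1NCCCC1", "C1NCCCCC1",
    "C1SCC1", "C1SCCC1", "C1SCCCC1", "C1SCCCCC1",
    "C1OCOC1", "C1OCCOC1", "C1OCOCC1", "C1OCCNC1", "C1NCCNC1", "C1SCCNC1",
    "C1SCSC1", "C1SCCSC1",
    "C1CC2CCC1CC2", "C1CCC2CCCCC2C1", "C1CC2CCC1C2",
    "C1CCC2(CC1)CCCC2", "C1CCC2(C1)CCC2",
    "CC1CCOCC1", "CC1CCNCC1", "CC1CCSCC1", "CC1CCCCC1",
)

# Aromatic ring substituents; the first-written atom (the attachment point)
# is always an aromatic carbon.  Decorations (halogens, methyl, vinyl, ...)
# stay within one rigid fragment after decomposition.
SUBSTITUENTS: tuple[str, ...] = (
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1cnccn1", "c1ccnnc1", "c1ncncn1",
    "c1ccco1", "c1cccs1", "c1ccc[nH]1", "c1cnc[nH]1", "c1cn[nH]c1",
    "c1ocnc1", "c1scnc1", "c1cnoc1",
    "c1ccc2ccccc2c1", "c1ccc2ncccc2c1", "c1ccc2cnccc2c1",
    "c1ccc2[nH]ccc2c1", "c1ccc2occc2c1", "c1ccc2sccc2c1",
    "c1ccc(F)cc1", "c1ccc(Cl)cc1", "c1ccc(Br)cc1", "c1ccc(I)cc1",
    "c1ccc(C)cc1", "c1ccc(O)cc1", "c1ccc(N)cc1",
    "c1ccc(F)c(F)c1", "c1cc(C)cc(C)c1", "c1cc(F)cc(F)c1",
    "c1ccc(C#N)cc1", "c1ccc(C=C)cc1", "c1ccc(C=O)cc1",
    "c1ccc(cc1)C(C)=O", "c1ccc(cc1)C(N)=O",
)

# Acyclic linkers for randomized stress libraries (may introduce solitary
# atoms, conjugated bridges, amides and branching atoms).
LINKERS: tuple[str, ...] = (
    "", "C", "CC", "CCC", "CO", "CN", "CS", "OC", "NC", "SC",
    "C(C)C", "C(C)(C)", "C=C", "CC=C", "C#C", "C(=O)", "C(=O)N", "C(=O)O",
    "OCC", "CNC", "COC",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters; generation is a pure function of this spec."""

    n_cores: int = 10
    n_substituents: int = 10
    n_actives: int = 25
    n_decoys: int = 2475
    n_privileged: int = 3
    delta: float = 4.0  # score offset (kcal/mol-like) planted on privileged fragments
    seed: int = 0

    def __post_init__(self):
        if self.n_cores < 1 or self.n_substituents < 1:
            raise ValueError("counts must be >= 1")
        if self.n_cores > len(CORES) or self.n_substituents > len(SUBSTITUENTS):
            raise ValueError(
                f"scaffold vocabulary holds {len(CORES)} cores and "
                f"{len(SUBSTITUENTS)} substituents; requested "
                f"{self.n_cores} x {self.n_substituents}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


def gen_combinatorial(spec: FixtureSpec) -> list[tuple[str, str]]:
    """The full cores x substituents grid as (id, SMILES) records.

    Every record is valence-correct, the core-substituent bond is the only
    cleavable bond, and the grid decomposes to exactly
    ``n_cores + n_substituents`` unique fragments.
    """
    out = []
    for i in range(spec.n_cores):
        for j in range(spec.n_substituents):
            out.append((f"C{i:02d}S{j:02d}", CORES[i] + SUBSTITUENTS[j]))
    return out


@dataclass
class Benchmark:
    """A planted-signal active/decoy benchmark."""

    molecules: list[Molecule]
    actives: set[str]
    score_table: ScoreTable
    privileged_keys: set[str]
    library: FragmentLibrary

    @property
    def labels(self) -> dict[str, str]:
        return {m.id: ("active" if m.id in self.actives else "decoy")
                for m in self.molecules}


def gen_benchmark(spec: FixtureSpec) -> Benchmark:
    """Build a benchmark with actives enriched in down-shifted fragments.

    Actives draw their substituent from ``n_privileged`` privileged
    substituents; decoys draw from the remainder (with replacement, so decoy
    counts are not capacity-limited).  The mock score of every privileged
    capped substituent is shifted by ``-delta``.  Byte-reproducible from
    (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_privileged >= spec.n_substituents:
        raise ValueError("need at least one non-privileged substituent for decoys")
    priv = sorted(rng.choice(spec.n_substituents, spec.n_privileged, replace=False))
    nonpriv = [j for j in range(spec.n_substituents) if j not in priv]

    capacity = spec.n_cores * spec.n_privileged
    if spec.n_actives > capacity:
        raise ValueError(
            f"n_actives={spec.n_actives} exceeds privileged capacity {capacity}")
    active_pairs = [(p // spec.n_privileged, priv[p % spec.n_privileged])
                    for p in rng.choice(capacity, spec.n_actives, replace=False)]

    molecules: list[Molecule] = []
    actives: set[str] = set()
    for n, (i, j) in enumerate(active_pairs):
        m = parse_smiles(CORES[i] + SUBSTITUENTS[j], id=f"A{n:05d}")
        molecules.append(m)
        actives.add(m.id)
    for n in range(spec.n_decoys):
        i = int(rng.integers(spec.n_cores))
        j = nonpriv[int(rng.integers(len(nonpriv)))]
        molecules.append(parse_smiles(CORES[i] + SUBSTITUENTS[j], id=f"D{n:05d}"))

    lib = build_library(molecules)
    table = score_library(lib, MockScorerParams(seed=spec.seed))
    privileged_keys = {canonical_key(parse_smiles(SUBSTITUENTS[j])) for j in priv}
    for key in privileged_keys & set(table.scores):
        table.scores[key] -= spec.delta
    table.metadata["planted_delta"] = spec.delta
    return Benchmark(molecules=molecules, actives=actives, score_table=table,
                     privileged_keys=privileged_keys, library=lib)


def gen_random_library(n: int, seed: int) -> list[Molecule]:
    """Randomized core-linker-substituent molecules for stress testing.

    Linkers add acyclic chains, conjugated bridges, amide bonds and branching
    atoms on top of the combinatorial grid, exercising every bond-
    classification rule.  Deterministic given (n, seed).
    """
    rng = np.random.default_rng(seed)
    out = []
    for idx in range(n):
        core = CORES[int(rng.integers(len(CORES)))]
        linker = LINKERS[int(rng.integers(len(LINKERS)))]
        sub = SUBSTITUENTS[int(rng.integers(len(SUBSTITUENTS)))]
        out.append(parse_smiles(core + linker + sub, id=f"R{idx:05d}"))
    return out


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\tlabel\n")
        for cid in sorted(labels):
            fh.write(f"{cid}\t{labels[cid]}\n")
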