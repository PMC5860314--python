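"""Fragment-scoring backends.

The pipeline is backend-agnostic: any docking engine that can emit a scalar
score per fragment can drive it.  Fragments are exported once per unique key
(SDF, single conformer — a rigid fragment needs no conformer ensemble), the
engine docks each fragment to its best location independently of all others,
and the per-key best (most negative, ΔG-like) score is ingested back.

For tests and desk-scale benchmarks a deterministic mock scorer stands in:
a pure function of the canonical fragment key and a seed, with a size term
that mimics docking's known bias toward larger molecules.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem

from .chemio import Molecule, canonical_key, parse_smiles
from .fraglib import FragmentLibrary

log = logging.getLogger(__name__)

__all__ = ["MockScorerParams", "ScoreTable", "mock_score", "score_library",
           "ingest_scores", "write_scores", "export_fragments"]


@dataclass(frozen=True)
class MockScorerParams:
    """Parameters of the deterministic mock scorer.

    score = -(size_weight * n_heavy + hetero_weight * n_hetero
              + noise_scale * u(key, seed))

    with ``u`` a hash-derived uniform deviate in [0, 1).  ``size_weight``
    defaults to 0.3 kcal/mol per heavy atom (a typical ligand-efficiency
    magnitude), so more atoms score generally more favorably, as real docking
    scores do.
    """

    size_weight: float = 0.3
    hetero_weight: float = 0.1
    noise_scale: float = 1.0
    seed: int = 0


@dataclass
class ScoreTable:
    """Best raw docking score per fragment key (more negative = better)."""

    scores: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __contains__(self, key: str) -> bool:
        return key in self.scores

    def __getitem__(self, key: str) -> float:
        return self.scores[key]

    def record(self, key: str, score: float) -> None:
        """Keep the most favorable (minimum) score seen for ``key``."""
        if not _finite(score):
            raise ValueError(f"non-finite score for {key!r}: {score}")
        if key not in self.scores or score < self.scores[key]:
            self.scores[key] = score


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def _uniform_hash(key: str, seed: int) -> float:
    """Process-independent uniform deviate in [0, 1) from (key, seed)."""
    digest = hashlib.sha256(f"{key}|{seed}".encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


def mock_score(fragment: Molecule | str, params: MockScorerParams) -> float:
    """Deterministic pseudo-docking score of one capped fragment.

    Depends only on the canonical key and ``params``: permuted atom orders
    and repeated calls (across processes) give the identical value.
    """
    if isinstance(fragment, str):
        key = fragment
        mol = parse_smiles(key, id=key)
    else:
        key = canonical_key(fragment)
        mol = fragment
    noise = params.noise_scale * _uniform_hash(key, params.seed)
    return -(params.size_weight * mol.num_heavy_atoms
             + params.hetero_weight * mol.num_hetero_atoms
             + noise)


def score_library(lib: FragmentLibrary, params: MockScorerParams) -> ScoreTable:
    """Mock-score every unique fragment of a library once."""
    table = ScoreTable(metadata={"backend": "mock", **asdict(params)})
    for key, frag in lib.unique_fragments.items():
        table.record(key, mock_score(frag, params))
    return table


def ingest_scores(path: str | Path) -> ScoreTable:
    """Read a ``fragment_key<TAB>score`` TSV, keeping the per-key minimum.

    Multiple rows per key (poses, repeated runs) collapse to the best score.
    Lines starting with '#' and a ``fragment_key`` header line are ignored.
    """
    path = Path(path)
    table = ScoreTable(metadata={"backend": "ingest", "source": str(path)})
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if parts[0] == "fragment_key":  # header line
                continue
            key, raw = parts[0], parts[1]
            try:
                score = float(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
            table.record(key, score)
            n_rows += 1
    if n_rows == 0:
        log.warning("score table %s is empty", path)
    return table


def write_scores(table: ScoreTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in sorted(table.metadata.items()):
            fh.write(f"# {k}: {v}\n")
        fh.write("fragment_key\tscore\n")
        for key in sorted(table.scores):
            fh.write(f"{key}\t{table.scores[key]:.6f}\n")


def export_fragments(lib: FragmentLibrary, path: str | Path,
                     embed_seed: int = 0xF00D) -> int:
    """Write one SDF record per unique fragment for an external docking tool.

    The fragment key sits on the title line so external scores can be joined
    back by key.  A single ETKDG conformer is embedded (rigid fragments need
    only one); on embedding failure the fragment is written with 2D
    coordinates and flagged.
    """
    writer = Chem.SDWriter(str(path))
    n = 0
    for key in sorted(lib.unique_fragments):
        mol = Chem.AddHs(Chem.Mol(lib.unique_fragments[key].mol))
        params = AllChem.ETKDGv3()
        params.randomSeed = embed_seed
        ok = AllChem.EmbedMolecule(mol, params)
        mol = Chem.RemoveHs(mol)
        if ok != 0:
            AllChem.Compute2DCoords(mol)
            mol.SetProp("embedding", "2D")
            log.warning("3D embedding failed for %s; wrote 2D coordinates", key)
        mol.SetProp("_Name", key)
        writer.write(mol)
        n += 1
    writer.close()
    return n
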