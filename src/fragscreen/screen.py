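"""Screening protocol: volume cutoff, enrichment factors, two-stage screens.

Pieces around the fragment scores that turn them into a screen:

* a large-compound cutoff comparing an atomic-contribution estimate of the
  compound volume Vc against the protein-cavity volume Vp scaled by a
  flexibility multiplier k (default 1.5; compounds with Vc > k*Vp cannot fit
  and are omitted before scoring);
* enrichment factors EF_x% = (Pos_x/All_x) / (Pos_100/All_100), the standard
  active-enrichment metric of a ranked screen;
* the two-stage protocol: pre-screen the library by fragment scores, keep
  the top a%, re-rank the survivors with an expensive reference score, and
  evaluate EF_b% against the FULL library (actives lost at pre-screening
  count against the method);
* structural-diversity helpers (max Tanimoto over 2048-bit radius-2 Morgan
  fingerprints, the ECFP4-equivalent);
* a config-driven end-to-end pipeline producing a reproducible report.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chemio import Molecule, read_library
from .docking import MockScorerParams, ScoreTable, ingest_scores, score_library
from .fraglib import FragmentLibrary, build_library
from .scoring import FormulaSpec, rank_compounds, score_all

log = logging.getLogger(__name__)

__all__ = ["ZHAO_ATOM_VOLUMES", "CutoffConfig", "ScreenReport", "zhao_volume",
           "apply_cutoff", "enrichment_factor", "nested_screen", "morgan_fp",
           "max_tanimoto", "run_pipeline"]

# Atomic van der Waals volume contributions (A^3) of the Zhao-Abraham-Zissimos
# fast-estimation scheme; the molecular volume is the atom sum corrected for
# bond overlap and ring fusion:
#   V = sum(atoms) - 5.92*N_bonds - 14.7*N_aromatic_rings - 3.8*N_nonaromatic_rings
# with hydrogens and their bonds counted, and rings taken from the SSSR.
ZHAO_ATOM_VOLUMES: dict[str, float] = {
    "H": 7.24, "C": 20.58, "N": 15.60, "O": 14.71, "F": 13.31,
    "Cl": 22.45, "Br": 26.52, "I": 32.52, "P": 24.43, "S": 24.43,
    "As": 26.52, "B": 40.48, "Si": 38.79, "Se": 28.73, "Te": 36.62,
}

_BOND_TERM = 5.92
_AROMATIC_RING_TERM = 14.7
_NONAROMATIC_RING_TERM = 3.8


def zhao_volume(m: Molecule) -> float:
    """Atomic-contribution estimate of the molecular volume Vc in A^3."""
    total = 0.0
    n_h = 0
    for atom in m.mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ZHAO_ATOM_VOLUMES:
            raise ValueError(
                f"molecule {m.id!r}: element {sym!r} not in the volume-contribution table")
        total += ZHAO_ATOM_VOLUMES[sym]
        n_h += atom.GetTotalNumHs()
    total += n_h * ZHAO_ATOM_VOLUMES["H"]
    n_bonds = m.mol.GetNumBonds() + n_h  # each hydrogen adds one bond
    total -= _BOND_TERM * n_bonds
    for ring in m.mol.GetRingInfo().BondRings():
        aromatic = all(m.mol.GetBondWithIdx(b).GetIsAromatic() for b in ring)
        total -= _AROMATIC_RING_TERM if aromatic else _NONAROMATIC_RING_TERM
    return total


@dataclass(frozen=True)
class CutoffConfig:
    """Large-compound cutoff: omit compounds with Vc > k * Vp.

    ``vp`` is the protein-cavity volume in A^3 (supplied by the user, e.g.
    from a pocket-detection tool); ``k`` absorbs cavity flexibility — k = 1
    is too strict for a flexible pocket, the 1.5 default favors keeping
    borderline compounds (false negatives are costlier than false positives
    in a pre-screen).
    """

    vp: float
    k: float = 1.5

    def __post_init__(self):
        if self.vp <= 0 or self.k <= 0:
            raise ValueError("cutoff requires vp > 0 and k > 0")

    @property
    def threshold(self) -> float:
        return self.k * self.vp


def apply_cutoff(compounds: Sequence[Molecule],
                 cfg: CutoffConfig) -> tuple[list[str], list[str]]:
    """Split compound IDs into (kept, omitted) by the volume cutoff.

    The boundary Vc == k*Vp is kept: omission requires strictly exceeding
    the threshold.
    """
    kept, omitted = [], []
    for m in compounds:
        (omitted if zhao_volume(m) > cfg.threshold else kept).append(m.id)
    return kept, omitted


def enrichment_factor(ranked_ids: Sequence[str], actives: set[str],
                      fraction: float) -> float:
    """EF at the top ``fraction`` of a ranking.

    EF_x = (Pos_x / All_x) / (Pos_100 / All_100), with All_x =
    max(1, floor(x * All_100)).  Requires at least one active in the ranked
    set (the base rate must be defined).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    all_100 = len(ranked_ids)
    if all_100 == 0:
        raise ValueError("empty ranking")
    pos_100 = sum(1 for cid in ranked_ids if cid in actives)
    if pos_100 == 0:
        raise ValueError("no active compounds in the ranked set; EF undefined")
    all_x = max(1, math.floor(fraction * all_100))
    pos_x = sum(1 for cid in ranked_ids[:all_x] if cid in actives)
    return (pos_x / all_x) / (pos_100 / all_100)


def nested_screen(prescreen_scores: Mapping[str, float],
                  rescore_scores: Mapping[str, float],
                  a: float, b: float, actives: set[str]) -> float:
    """Two-stage screen: keep top a% by pre-screen, re-rank by rescore, EF_b%.

    The EF denominator refers to the full compound set, so actives discarded
    by the pre-screen count against it.  ``rescore_scores`` needs entries at
    least for the pre-screen survivors.
    """
    if b > a:
        raise ValueError(f"rescore fraction b={b} cannot exceed pre-screen fraction a={a}")
    full_ranked = [cid for cid, _, _ in rank_compounds(prescreen_scores)]
    n = len(full_ranked)
    survivors = full_ranked[:max(1, math.floor(a * n))]
    missing = [cid for cid in survivors if cid not in rescore_scores]
    if missing:
        raise KeyError(f"no rescore score for pre-screen survivors: {missing[:3]}...")
    reranked = [cid for cid, _, _ in
                rank_compounds({cid: rescore_scores[cid] for cid in survivors})]

    all_100 = n
    pos_100 = sum(1 for cid in full_ranked if cid in actives)
    if pos_100 == 0:
        raise ValueError("no active compounds in the screened set; EF undefined")
    all_b = max(1, math.floor(b * all_100))
    pos_b = sum(1 for cid in reranked[:all_b] if cid in actives)
    return (pos_b / all_b) / (pos_100 / all_100)


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def morgan_fp(m: Molecule):
    """2048-bit radius-2 circular substructure fingerprint (ECFP4-equivalent)."""
    return _FP_GEN.GetFingerprint(m.mol)


def max_tanimoto(query_fp, refs: Sequence) -> float:
    """Maximum Tanimoto similarity of a query fingerprint over a reference set."""
    if len(refs) == 0:
        raise ValueError("reference fingerprint set is empty")
    if query_fp.GetNumOnBits() == 0:
        warnings.warn("query fingerprint has no bits set; max Tanimoto = 0")
        return 0.0
    return max(DataStructs.TanimotoSimilarity(query_fp, ref) for ref in refs)


@dataclass
class ScreenReport:
    """Per-compound ranking plus run-level evaluation and configuration echo."""

    formula: str
    gs_exponent: float | None
    config: dict = field(default_factory=dict)
    # compound_id -> {score, rank, n_fragments, cleaved_bonds, volume, kept}
    compounds: dict[str, dict] = field(default_factory=dict)
    n_omitted: int = 0
    enrichment: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "formula": self.formula,
            "gs_exponent": self.gs_exponent,
            "config": self.config,
            "n_compounds": len(self.compounds),
            "n_omitted": self.n_omitted,
            "enrichment": self.enrichment,
            "compounds": self.compounds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def write_ranking(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("compound_id\tscore\trank\tn_fragments\tcleaved_bonds\n")
            ranked = sorted((c for c in self.compounds.items() if c[1]["rank"] is not None),
                            key=lambda kv: kv[1]["rank"])
            for cid, rec in ranked:
                fh.write(f"{cid}\t{rec['score']:.6f}\t{rec['rank']}\t"
                         f"{rec['n_fragments']}\t{rec['cleaved_bonds']}\n")


def _read_labels(path: str | Path) -> set[str]:
    actives = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("compound_id"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2 or parts[1] not in ("active", "decoy"):
                raise ValueError(f"{path}:{lineno}: expected 'compound_id<TAB>active|decoy'")
            if parts[1] == "active":
                actives.add(parts[0])
    return actives


def run_pipeline(config: Mapping, out_dir: str | Path | None = None) -> ScreenReport:
    """Run the full screen from a plain config mapping.

    Recognized keys: ``library`` (path, .smi/.sdf), ``scores`` (TSV path) or
    ``backend: mock`` with ``seed``, ``formula`` (sum|max|gs), ``x`` (GS
    exponent), ``vp`` + ``k`` (optional volume cutoff), ``labels`` (optional
    active/decoy TSV), ``fractions`` (EF fractions, default [0.01, 0.02]),
    ``merge_mode``.  Rerunning an identical config reproduces the report
    byte-for-byte.
    """
    cfg = dict(config)
    mols = read_library(cfg["library"])
    spec = FormulaSpec(formula=cfg.get("formula", "gs"), x=float(cfg.get("x", 3.0)))

    volumes = {m.id: zhao_volume(m) for m in mols}
    if cfg.get("vp") is not None:
        cut = CutoffConfig(vp=float(cfg["vp"]), k=float(cfg.get("k", 1.5)))
        kept_ids, omitted_ids = apply_cutoff(mols, cut)
        kept_set = set(kept_ids)
        screened = [m for m in mols if m.id in kept_set]
    else:
        omitted_ids = []
        screened = list(mols)

    lib = build_library(screened, merge_mode=cfg.get("merge_mode", "duplicate"))
    if cfg.get("scores"):
        table = ingest_scores(cfg["scores"])
    else:
        table = score_library(lib, MockScorerParams(seed=int(cfg.get("seed", 0))))

    scores = score_all(lib, table, spec)
    ranking = rank_compounds(scores)

    report = ScreenReport(
        formula=spec.formula,
        gs_exponent=spec.x if spec.formula == "gs" else None,
        config={k: cfg[k] for k in sorted(cfg)},
        n_omitted=len(omitted_ids),
    )
    for cid, score, rank in ranking:
        rec = lib.records[cid]
        report.compounds[cid] = {
            "score": round(score, 9), "rank": rank,
            "n_fragments": rec.n_fragments, "cleaved_bonds": rec.cleaved_bonds,
            "volume": round(volumes[cid], 4), "kept": True,
        }
    for cid in omitted_ids:
        report.compounds[cid] = {
            "score": None, "rank": None, "n_fragments": None,
            "cleaved_bonds": None, "volume": round(volumes[cid], 4), "kept": False,
        }

    if cfg.get("labels"):
        actives = _read_labels(cfg["labels"])
        ranked_ids = [cid for cid, _, _ in ranking]
        fractions = cfg.get("fractions", [0.01, 0.02])
        for frac in fractions:
            report.enrichment[f"EF{100 * float(frac):g}%"] = round(
                enrichment_factor(ranked_ids, actives, float(frac)), 6)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_json(out_dir / "report.json")
        report.write_ranking(out_dir / "ranking.tsv")
    return report
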