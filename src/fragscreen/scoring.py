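"""Compound evaluation from fragment docking scores.

Raw docking scores are ΔG-like (negative = favorable).  They are first
*inverted* to a non-negative "bigger is better" scale, s -> max(0, -s):
a fragment with a positive (unfavorable) raw score contributes nothing.
Inversion is applied uniformly before every aggregation formula so that all
three share the same orientation.

Aggregation formulas over a compound's inverted fragment scores s_f
(multiplicity-expanded — a fragment occurring twice contributes two copies):

* SUM  = sum_f s_f            — rough upper bound of the compound score;
                                grows with fragment count.
* MAX  = max_f s_f            — rough lower bound; best single fragment.
* GS_x = (sum_f s_f^x)^(1/x)  — power-mean-style interpolation: GS_1 = SUM,
                                GS_inf = MAX.  The exponent weights the
                                top-scoring fragments; x = 3 is the default,
                                which beats both extremes in practice
                                (a few best fragments are more informative
                                than either all of them or only one).

The module also provides the deterministic compound ranking and a two-factor
OLS model (SUM score + cleaved-bond count) for fitting against a reference
whole-compound docking score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .docking import ScoreTable
from .fraglib import FragmentLibrary

log = logging.getLogger(__name__)

__all__ = ["FormulaSpec", "FittedModel", "invert", "aggregate",
           "score_compound", "score_all", "rank_compounds", "fit_linear"]

FORMULAS = ("sum", "max", "gs")


@dataclass(frozen=True)
class FormulaSpec:
    """Aggregation formula choice; ``x`` applies to GS only and must be >= 1."""

    formula: str = "gs"
    x: float = 3.0

    def __post_init__(self):
        if self.formula not in FORMULAS:
            raise ValueError(f"unknown formula {self.formula!r}; choose from {FORMULAS}")
        if self.formula == "gs" and self.x < 1:
            raise ValueError(f"GS exponent must be >= 1, got {self.x}")


def invert(raw: Iterable[float]) -> np.ndarray:
    """Map raw ΔG-like scores to the non-negative scale: s -> max(0, -s)."""
    arr = np.asarray(list(raw), dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("raw scores must be finite")
    return np.maximum(0.0, -arr)


def aggregate(s: np.ndarray | Sequence[float], f: FormulaSpec) -> float:
    """Aggregate inverted (non-negative) fragment scores; higher = better."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        warnings.warn("aggregating an empty fragment-score set; score = 0")
        return 0.0
    if np.any(s < 0):
        raise ValueError("aggregate expects inverted, non-negative scores")
    if f.formula == "sum":
        return float(s.sum())
    if f.formula == "max":
        return float(s.max())
    m = float(s.max())
    if m == 0.0:
        return 0.0
    # factor out the max so s^x cannot overflow at large exponents
    return m * float(np.sum((s / m) ** f.x)) ** (1.0 / f.x)


def score_compound(lib: FragmentLibrary, table: ScoreTable, compound_id: str,
                   f: FormulaSpec = FormulaSpec(),
                   missing: str = "zero") -> float:
    """Evaluation score of one compound from its fragments' docking scores.

    ``missing`` controls fragments absent from the score table: ``"zero"``
    (default) treats them as contributing nothing, with a warning;
    ``"strict"`` raises.
    """
    if compound_id not in lib.records:
        raise KeyError(f"unknown compound ID {compound_id!r}")
    if missing not in ("zero", "strict"):
        raise ValueError(f"unknown missing-score policy {missing!r}")
    raw: list[float] = []
    for key, mult in lib.records[compound_id].keys.items():
        if key not in table:
            if missing == "strict":
                raise KeyError(f"no score for fragment {key!r} of compound {compound_id!r}")
            log.warning("compound %s: fragment %s has no score; contributes 0",
                        compound_id, key)
            raw.extend([0.0] * mult)  # inverts to 0
            continue
        raw.extend([table[key]] * mult)
    return aggregate(invert(raw), f)


def score_all(lib: FragmentLibrary, table: ScoreTable,
              f: FormulaSpec = FormulaSpec(),
              missing: str = "zero") -> dict[str, float]:
    return {cid: score_compound(lib, table, cid, f, missing=missing)
            for cid in lib.records}


def rank_compounds(scores: Mapping[str, float]) -> list[tuple[str, float, int]]:
    """Descending by score, ties broken lexicographically by ID; 1-based ranks."""
    for cid, s in scores.items():
        if not np.isfinite(s):
            raise ValueError(f"non-finite score for compound {cid!r}")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(cid, s, i + 1) for i, (cid, s) in enumerate(ordered)]


@dataclass
class FittedModel:
    """Two-factor affine model: prediction = b0 + b1*score_sum + b2*cleaved_bonds."""

    intercept: float
    coef_sum: float
    coef_cleaved: float
    r_train: float

    def predict(self, score_sum, cleaved_bonds) -> np.ndarray:
        return (self.intercept
                + self.coef_sum * np.asarray(score_sum, dtype=float)
                + self.coef_cleaved * np.asarray(cleaved_bonds, dtype=float))


def fit_linear(features: Sequence[tuple[float, float]],
               target: Sequence[float]) -> FittedModel:
    """OLS fit of a reference compound score on (SUM score, cleaved bonds).

    Requires at least 3 observations and a full-rank design; a degenerate
    (constant or collinear) feature is named in the error.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("features must be (n, 2): (score_sum, cleaved_bonds)")
    n = X.shape[0]
    if n < 3 or y.shape[0] != n:
        raise ValueError(f"need >= 3 matched observations, got {n}")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < 3:
        names = ("score_sum", "cleaved_bonds")
        for j, name in enumerate(names):
            if np.ptp(X[:, j]) == 0:
                raise ValueError(f"degenerate design: feature {name!r} is constant")
        raise ValueError("degenerate design: features are collinear")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ beta
    if np.ptp(y) == 0 or np.ptp(pred) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(pred, y)[0, 1])
    return FittedModel(intercept=float(beta[0]), coef_sum=float(beta[1]),
                       coef_cleaved=float(beta[2]), r_train=r)
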