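"""CASP-style contact evaluation.

A contact is a residue pair with Cbeta (Calpha for glycine) distance
strictly below 8 Å.  Pairs are stratified by sequence separation —
short (6-11), mid (12-23), long (>= 24); separations below 6 are excluded.
Within each range, predictions are ranked by probability, the top
min(L, #in-range pairs) are called contacts, and precision is normalized
by min(L, #true contacts) so a perfect predictor scores 100% even when
fewer than L true contacts exist.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .io_formats import StructureChain
from .labeling import cb_coordinate

CONTACT_DISTANCE = 8.0  # Å, strict upper bound

RANGES = {"short": (6, 11), "mid": (12, 23), "long": (24, None)}


def true_contacts(chain: StructureChain) -> set[tuple[int, int]]:
    """Unordered residue pairs (i < j) in contact; unresolved residues are
    excluded."""
    coords = [cb_coordinate(r) for r in chain.residues]
    out: set[tuple[int, int]] = set()
    for i in range(len(coords)):
        if coords[i] is None:
            continue
        for j in range(i + 1, len(coords)):
            if coords[j] is None:
                continue
            if np.linalg.norm(coords[i] - coords[j]) < CONTACT_DISTANCE:
                out.add((i, j))
    return out


def range_of(pair: tuple[int, int]) -> str | None:
    """Sequence-separation stratum of a pair, or None when |i-j| < 6."""
    i, j = pair
    if i == j:
        raise ValueError("range_of requires i != j")
    sep = abs(i - j)
    for name, (lo, hi) in RANGES.items():
        if sep >= lo and (hi is None or sep <= hi):
            return name
    return None


def _in_range_pairs(L: int, which: str) -> list[tuple[int, int]]:
    lo, hi = RANGES[which]
    pairs = []
    for i in range(L):
        for j in range(i + lo, L if hi is None else min(i + hi + 1, L)):
            pairs.append((i, j))
    return pairs


def topL_normalized_accuracy(P: np.ndarray, truth: set[tuple[int, int]],
                             L: int, which: str) -> float | None:
    """Normalized top-L contact precision in one separation range.

    The min(L, #in-range pairs) highest-probability pairs are selected
    (ties broken by ascending (i, j)); the score is TP / min(L, T) with T
    the number of true in-range contacts, or None when T = 0.
    """
    pairs = _in_range_pairs(P.shape[0], which)
    true_in_range = {p for p in truth if range_of(p) == which}
    if not true_in_range:
        return None
    # stable sort on -probability keeps lexicographic (i, j) order for ties
    probs = np.array([P[i, j] for i, j in pairs])
    order = np.argsort(-probs, kind="stable")
    n_select = min(L, len(pairs))
    selected = {pairs[k] for k in order[:n_select]}
    tp = len(selected & true_in_range)
    return tp / min(L, len(true_in_range))


@dataclasses.dataclass
class TargetScore:
    target_id: str
    length: int
    msa_depth: int
    scores: dict[str, float | None]  # per range; None when undefined

    @property
    def average(self) -> float | None:
        vals = [v for v in self.scores.values() if v is not None]
        return float(np.mean(vals)) if vals else None


@dataclasses.dataclass
class EvalReport:
    """Per-target normalized accuracies plus per-set averages."""

    targets: list[TargetScore]

    def set_average(self, which: str) -> float | None:
        vals = [t.scores[which] for t in self.targets
                if t.scores.get(which) is not None]
        return float(np.mean(vals)) if vals else None

    def averages(self) -> dict[str, float | None]:
        out = {k: self.set_average(k) for k in RANGES}
        avgs = [t.average for t in self.targets if t.average is not None]
        out["average"] = float(np.mean(avgs)) if avgs else None
        return out

    def to_rows(self) -> list[dict]:
        return [
            {"target": t.target_id, "L": t.length, "msa_depth": t.msa_depth,
             **{k: t.scores.get(k) for k in RANGES}, "average": t.average}
            for t in self.targets
        ]


def score_target(target_id: str, P: np.ndarray, chain: StructureChain,
                 msa_depth: int = 0) -> TargetScore:
    truth = true_contacts(chain)
    L = P.shape[0]
    scores = {which: topL_normalized_accuracy(P, truth, L, which)
              for which in RANGES}
    return TargetScore(target_id=target_id, length=L, msa_depth=msa_depth,
                       scores=scores)


def accuracy_depth_correlation(report: EvalReport,
                               depth_threshold: int = 400
                               ) -> dict[str, float | None]:
    """Pearson r of average accuracy against MSA depth within each depth
    stratum (split at ``depth_threshold``), and against length overall.

    Strata with fewer than 3 scored targets, or with zero variance in
    either variable, report None.
    """
    def pearson(x: list[float], y: list[float]) -> float | None:
        if len(x) < 3:
            warnings.warn("fewer than 3 targets in stratum; r undefined")
            return None
        x_arr, y_arr = np.asarray(x, float), np.asarray(y, float)
        if x_arr.std() == 0 or y_arr.std() == 0:
            return None
        return float(np.corrcoef(x_arr, y_arr)[0, 1])

    scored = [(t.msa_depth, t.length, t.average) for t in report.targets
              if t.average is not None]
    shallow = [(d, a) for d, _, a in scored if d < depth_threshold]
    deep = [(d, a) for d, _, a in scored if d >= depth_threshold]
    return {
        "r_depth_shallow": pearson([d for d, _ in shallow],
                                   [a for _, a in shallow]),
        "r_depth_deep": pearson([d for d, _ in deep], [a for _, a in deep]),
        "r_length": pearson([l for _, l, _ in scored],
                            [a for _, _, a in scored]),
    }
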