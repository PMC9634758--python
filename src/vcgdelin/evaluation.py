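"""Detector scoring: Se/P+, delineation error statistics, and the
single-lead to multi-lead annotation reduction rule.

Beat matching is greedy one-to-one within a +-75 ms window; sensitivity
and positive predictivity follow Se = TP/(TP+FN), P+ = TP/(TP+FP).
Boundary errors are signed differences (detected - reference) in ms,
summarised as mean and sample standard deviation, with a helper comparing
them against published two-standard-deviation tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np


@dataclass
class DetectionScore:
    tp: int
    fn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        """Se in percent."""
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def positive_predictivity(self) -> float:
        """P+ in percent."""
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else float("nan")

    def __add__(self, other: "DetectionScore") -> "DetectionScore":
        return DetectionScore(self.tp + other.tp, self.fn + other.fn,
                              self.fp + other.fp)


@dataclass
class ReductionRule:
    """Nearest-neighbour reduction of per-lead annotations (k=1, delta ms)."""

    k: int = 1
    delta_ms: float = 6.0

    def __post_init__(self) -> None:
        if self.k < 1 or self.delta_ms <= 0:
            raise ValueError("need k >= 1 and delta > 0")


def match_beats(detected_ms: Sequence[float], truth_ms: Sequence[float],
                tol_ms: float = 75.0
                ) -> Tuple[DetectionScore, np.ndarray]:
    """Greedy one-to-one matching of detections to truth beats.

    Both inputs must be time-sorted.  Returns the score and an index array
    ``pairs`` of shape (TP, 2) mapping detection -> truth.
    """
    det = np.asarray(detected_ms, dtype=float)
    tru = np.asarray(truth_ms, dtype=float)
    used = np.zeros(tru.size, dtype=bool)
    pairs = []
    for j, t in enumerate(det):
        cand = np.flatnonzero(~used & (np.abs(tru - t) <= tol_ms))
        if cand.size:
            best = cand[np.argmin(np.abs(tru[cand] - t))]
            used[best] = True
            pairs.append((j, int(best)))
    tp = len(pairs)
    score = DetectionScore(tp=tp, fn=int(tru.size - tp),
                           fp=int(det.size - tp))
    return score, np.asarray(pairs, dtype=int).reshape(-1, 2)


def delineation_errors(detected_ms: Sequence[float],
                       reference_ms: Sequence[float]
                       ) -> Tuple[float, float]:
    """(mu, sigma) of signed detected-minus-reference differences in ms;
    sigma is the sample (n-1) standard deviation."""
    det = np.asarray(detected_ms, dtype=float)
    ref = np.asarray(reference_ms, dtype=float)
    if det.shape != ref.shape:
        raise ValueError("matched arrays must have equal length")
    if det.size < 2:
        raise ValueError("need at least 2 matched beats for sigma")
    diff = det - ref
    return float(diff.mean()), float(diff.std(ddof=1))


def within_tolerance(sigma_ms: float, tol_2sd_ms: float) -> bool:
    """Compare an error standard deviation against a published
    two-standard-deviation acceptance bound."""
    return sigma_ms <= tol_2sd_ms


def reduce_multilead(times_ms: Sequence[float], which: str,
                     rule: Optional[ReductionRule] = None) -> float:
    """Collapse three per-lead boundary annotations into one.

    The three times are ordered; each annotation's distance to its nearest
    neighbour is computed, and among the annotations with the minimal
    nearest-neighbour distance (within delta where satisfiable, otherwise
    the tightest pair regardless) the earliest is returned for an onset
    and the latest for an end.  Ties between equally tight pairs resolve
    toward the earlier pair.
    """
    rule = rule or ReductionRule()
    if which not in ("onset", "end"):
        raise ValueError("which must be 'onset' or 'end'")
    v = np.sort(np.asarray(times_ms, dtype=float))
    if v.size != 3 or not np.all(np.isfinite(v)):
        raise ValueError("need three finite per-lead times")
    d01, d12 = v[1] - v[0], v[2] - v[1]
    nn = np.array([d01, min(d01, d12), d12])
    best = nn.min()
    cand = np.flatnonzero(nn == best)
    return float(v[cand[0]] if which == "onset" else v[cand[-1]])


def score_record(detected_r_ms: Sequence[float],
                 truth_r_ms: Sequence[float],
                 tol_ms: float = 75.0) -> DetectionScore:
    """Convenience wrapper returning only the detection score."""
    score, _ = match_beats(detected_r_ms, truth_r_ms, tol_ms)
    return score
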