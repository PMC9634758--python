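"""Isoelectric PQ window, record-global loop boundaries, and loop alignment.

The PQ segment between the P-wave end and the QRS onset is electrically
silent, so a 20 ms window with minimal regression slope just before the
detected onset estimates the isoelectric level.  Loop boundaries boundL and
boundR are record-global sample counts left/right of the synchronising
lead-X R peak (medians over beats of the farthest PQ begin and QRS end),
and the per-loop isoelectric coordinates ISO[i, k] are the mean voltage
over the strict interior of the PQ window.  Subtracting ISO and cutting
[r - boundL, r + boundR] yields spatiotemporally aligned QRS loops.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Tuple

import numpy as np

from .config import PipelineConfig
from .peaks import _round_half_away
from .record import FiducialTable, LoopSummary, VcgRecord


def regression_slope(y: np.ndarray) -> float:
    """Least-squares line slope of y against its sample index."""
    y = np.asarray(y, dtype=float)
    x = np.arange(y.size, dtype=float)
    x = x - x.mean()
    return float((x @ (y - y.mean())) / (x @ x))


def detect_pq(f: np.ndarray, q: int,
              cfg: Optional[PipelineConfig] = None) -> Tuple[int, int]:
    """Flattest TW1-sample window in [q-START1, q+STOP1-1].

    Windows slide in DELTA1 steps; the one with minimum |regression slope|
    wins, ties broken toward the earliest window.  Returns (begin, end)
    inclusive; (-1, -1) when the search range leaves the record.
    """
    cfg = cfg or PipelineConfig()
    n = f.size
    best: Tuple[float, int] | None = None
    for sh in range(0, cfg.start1 + cfg.stop1 - cfg.tw1 + 1, cfg.delta1):
        w0 = q - cfg.start1 + sh
        w1 = w0 + cfg.tw1 - 1
        if w0 < 0 or w1 > n - 1:
            continue
        slope = abs(regression_slope(f[w0:w1 + 1]))
        if best is None or slope < best[0]:
            best = (slope, w0)
    if best is None:
        warnings.warn(f"PQ search range around q={q} leaves the record")
        return -1, -1
    return best[1], best[1] + cfg.tw1 - 1


def loop_boundaries(r: np.ndarray, pq_begin: np.ndarray,
                    s: np.ndarray) -> Tuple[int, int]:
    """Record-global (boundL, boundR) from medians over beats.

    For beat k, dL_k = max_i (r1k - PQ_begin[i,k]) and
    dR_k = max_i (s[i,k] - r1k); the medians over k (mean of the central
    pair for an even count, rounded) give the global boundaries.  Beats
    with a missing PQ window or end are excluded with a warning.
    """
    p = r.shape[1]
    if p == 0:
        raise ValueError("need at least one beat")
    dl, dr = [], []
    skipped = 0
    for k in range(p):
        if np.any(pq_begin[:, k] < 0) or np.any(s[:, k] < 0):
            skipped += 1
            continue
        r1 = r[0, k]
        dl.append(int(np.max(r1 - pq_begin[:, k])))
        dr.append(int(np.max(s[:, k] - r1)))
    if skipped:
        warnings.warn(f"{skipped} beat(s) excluded from loop boundaries "
                      "(missing PQ window or QRS end)")
    if not dl:
        raise ValueError("no beat with complete fiducials")
    return (_round_half_away(float(np.median(dl))),
            _round_half_away(float(np.median(dr))))


def iso_coordinates(f: np.ndarray, pq: Tuple[int, int]) -> float:
    """Mean of f over the strict interior of the PQ window."""
    begin, end = int(pq[0]), int(pq[1])
    if end - begin + 1 < 3:
        raise ValueError("degenerate PQ window: fewer than 3 samples")
    return float(np.mean(f[begin + 1:end]))


def summarize_loops(record: VcgRecord,
                    table: FiducialTable) -> LoopSummary:
    """LoopSummary (boundL, boundR, ISO matrix) for a delineated record."""
    bound_l, bound_r = loop_boundaries(table.r, table.pq_begin, table.s)
    p = table.n_beats
    iso = np.full((3, p), np.nan)
    for i in range(3):
        for k in range(p):
            if table.pq_begin[i, k] >= 0:
                iso[i, k] = iso_coordinates(
                    record.leads[i],
                    (table.pq_begin[i, k], table.pq_end[i, k]))
    return LoopSummary(bound_l=bound_l, bound_r=bound_r, iso=iso)


def align_loops(record: VcgRecord, table: FiducialTable,
                summary: LoopSummary
                ) -> Tuple[np.ndarray, List[int]]:
    """Extract offset-free loops of identical length.

    Each loop is f over [r1k - boundL, r1k + boundR] minus its per-lead
    isoelectric coordinate; loops that would cross a record edge are
    dropped with a warning.  Returns (loops, kept_beat_indices) with
    ``loops`` of shape (n_kept, 3, boundL + boundR + 1).
    """
    n = record.n_samples
    length = summary.bound_l + summary.bound_r + 1
    loops, kept = [], []
    for k in range(table.n_beats):
        r1 = int(table.r[0, k])
        lo = r1 - summary.bound_l
        hi = r1 + summary.bound_r
        if lo < 0 or hi > n - 1 or np.any(np.isnan(summary.iso[:, k])):
            warnings.warn(f"loop {k} dropped (crosses a record edge or "
                          "lacks an isoelectric coordinate)")
            continue
        loops.append(record.leads[:, lo:hi + 1]
                     - summary.iso[:, k][:, None])
        kept.append(k)
    arr = (np.stack(loops) if loops
           else np.zeros((0, 3, length)))
    return arr, kept
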