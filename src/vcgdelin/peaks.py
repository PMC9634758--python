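"""QRS peak detection with three-lead consensus on scale-30 coefficients.

Per lead, samples where |W30| exceeds RATIO_O times its record maximum are
grouped into beats by the TTG gap rule and pruned within each group by
RATIO_A of the group maximum.  Beats are then reconciled across the three
leads: a beat seen in only one lead is discarded, a beat seen in two leads
gains a synthesised candidate in the third, and beats within TTE samples of
either record edge are dropped.  The surviving per-beat representatives are
finally refined to the extremum of |f| within +-eps samples, giving the R
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .config import PipelineConfig
from .record import VcgRecord
from .wavelet import WaveletStack


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class LeadCandidates:
    """Beat candidates of a single lead: member samples and representative."""

    groups: List[np.ndarray] = field(default_factory=list)
    peaks: List[int] = field(default_factory=list)   # argmax |W30| per group


@dataclass
class BeatCandidates:
    """Cross-lead aligned candidates; index k runs over surviving beats."""

    groups: List[List[np.ndarray]] = field(default_factory=list)  # [lead][k]
    bpeak: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 0), dtype=int))      # (3, p)

    @property
    def n_beats(self) -> int:
        return self.bpeak.shape[1]


def threshold_candidates(w30: np.ndarray,
                         cfg: PipelineConfig) -> LeadCandidates:
    """Single-lead thresholding, TTG grouping, and RATIO_A pruning."""
    absw = np.abs(np.asarray(w30, dtype=float))
    peak = absw.max() if absw.size else 0.0
    if peak == 0.0:
        return LeadCandidates()
    th = cfg.ratio_o * peak
    members = np.flatnonzero(absw > th)
    if members.size == 0:
        return LeadCandidates()
    splits = np.flatnonzero(np.diff(members) > cfg.ttg) + 1
    out = LeadCandidates()
    for grp in np.split(members, splits):
        gmax = absw[grp].max()
        grp = grp[absw[grp] >= cfg.ratio_a * gmax]
        out.groups.append(grp)
        out.peaks.append(int(grp[np.argmax(absw[grp])]))
    return out


def cross_lead_consensus(per_lead: List[LeadCandidates],
                         stack: WaveletStack, n_samples: int,
                         cfg: PipelineConfig) -> BeatCandidates:
    """Reconcile single-lead candidates into beats present in all leads."""
    if len(per_lead) != 3:
        raise ValueError("need candidates for exactly three leads")
    events = sorted(
        (t, i, g) for i, lc in enumerate(per_lead)
        for t, g in zip(lc.peaks, lc.groups))
    clusters: List[dict] = []
    for t, i, g in events:
        placed = False
        for cl in clusters:
            if i not in cl and abs(t - cl["_t0"]) <= cfg.ttg:
                cl[i] = (t, g)
                placed = True
                break
        if not placed:
            clusters.append({"_t0": t, i: (t, g)})

    groups: List[List[np.ndarray]] = [[], [], []]
    bpeaks: List[List[int]] = [[], [], []]
    for cl in clusters:
        present = [i for i in range(3) if i in cl]
        if len(present) < 2:
            continue                       # 1-of-3: exclude the beat
        if len(present) == 2:
            missing = ({0, 1, 2} - set(present)).pop()
            centre = np.mean([cl[i][0] for i in present])
            half = cfg.ttg // 2
            lo = max(0, _round_half_away(centre - half))
            hi = min(n_samples - 1, _round_half_away(centre + half))
            w = np.abs(stack.coeff(missing, 30)[lo:hi + 1])
            t_new = lo + int(np.argmax(w))
            cl[missing] = (t_new, np.array([t_new], dtype=int))
        reps = [cl[i][0] for i in range(3)]
        if min(reps) < cfg.tte or max(reps) > n_samples - 1 - cfg.tte:
            continue                       # edge exclusion, all leads
        for i in range(3):
            bpeaks[i].append(cl[i][0])
            groups[i].append(cl[i][1])

    order = np.argsort(bpeaks[0]) if bpeaks[0] else np.array([], dtype=int)
    bp = np.array([[bpeaks[i][j] for j in order] for i in range(3)],
                  dtype=int).reshape(3, -1)
    return BeatCandidates(
        groups=[[groups[i][j] for j in order] for i in range(3)], bpeak=bp)


def refine_peaks(record: VcgRecord, cands: BeatCandidates,
                 cfg: PipelineConfig) -> np.ndarray:
    """R[i, k]: extremum of |f_i| within +-eps of the W30 representative;
    ties resolve to the earliest sample."""
    n = record.n_samples
    r = np.empty_like(cands.bpeak)
    for i in range(3):
        absf = np.abs(record.leads[i])
        for k in range(cands.n_beats):
            bp = cands.bpeak[i, k]
            lo = max(0, bp - cfg.eps_refine)
            hi = min(n - 1, bp + cfg.eps_refine)
            r[i, k] = lo + int(np.argmax(absf[lo:hi + 1]))
    return r


def detect_peaks(record: VcgRecord, stack: WaveletStack,
                 cfg: Optional[PipelineConfig] = None
                 ) -> tuple[BeatCandidates, np.ndarray]:
    """Full peak stage: thresholding, consensus, amplitude refinement."""
    cfg = cfg or PipelineConfig()
    per_lead = [threshold_candidates(stack.coeff(i, 30), cfg)
                for i in range(3)]
    cands = cross_lead_consensus(per_lead, stack, record.n_samples, cfg)
    return cands, refine_peaks(record, cands, cfg)
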