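"""QRS onset and end delineation.

Per beat and lead the onset (end) is found from the zero crossings of the
scale-30 coefficient trace W30 left (right) of the beat peak:

1. zero crossings within +-TTLS of the peak are listed outward;
2. each inter-crossing interval is flagged suitable when max |W30| inside
   it exceeds THLS = RATIO_LS * max |W30| over the beat window;
3. scanning outward, suitable intervals extend the QRS; a lone unsuitable
   interval shorter than TTSN is forgiven; the scan stops at a run of >= 2
   unsuitable intervals or a single one longer than TTLN; the stop boundary
   is the onset zero point z_on;
4. the onset is traced inside the interval just outward of z_on as the
   outermost downward crossing of |W30| below gamma * THLS.

A QRS whose scalogram energy at scale 120 doubles that at scale 70 around
the fiducial (with a quiet near zone) is wide; its boundary is re-derived
with the same logic on W70 around the local |W70| maximum.  The boundary is
then adjusted in the time domain by sliding slope windows on f itself, and
finally reconciled across the three leads: when the spread exceeds TTBS
samples the farthest lead is replaced by the mean of the other two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig
from .peaks import BeatCandidates, _round_half_away
from .record import VcgRecord
from .wavelet import WaveletStack

LEFT, RIGHT = "left", "right"


# --------------------------------------------------------------------------
# zero-crossing machinery (shared by the W30 and W70 passes)
# --------------------------------------------------------------------------

def find_zero_crossings(w: np.ndarray, bpeak: int, side: str,
                        ttls: int) -> np.ndarray:
    """Zero points of ``w`` within +-ttls of ``bpeak``, ordered outward.

    A sign change between neighbouring samples is located by linear
    interpolation and rounded to the nearest sample; an exact zero sample
    is its own crossing.
    """
    n = w.size
    if side == LEFT:
        lo, hi = max(0, bpeak - ttls), bpeak
    elif side == RIGHT:
        lo, hi = bpeak, min(n - 1, bpeak + ttls)
    else:
        raise ValueError("side must be 'left' or 'right'")
    seg = w[lo:hi + 1]
    if seg.size < 2:
        return np.array([], dtype=int)
    zeros: List[int] = []
    exact = np.flatnonzero(seg == 0.0)
    zeros.extend(lo + exact)
    sgn = np.sign(seg)
    flips = np.flatnonzero((sgn[:-1] * sgn[1:]) < 0)
    for j in flips:
        frac = seg[j] / (seg[j] - seg[j + 1])
        zeros.append(lo + j + int(round(frac)))
    out = np.unique(np.asarray(zeros, dtype=int))
    return out[::-1] if side == LEFT else out


def classify_intervals(w: np.ndarray, zeros: np.ndarray,
                       thls: float) -> np.ndarray:
    """Suitability flag per inter-crossing interval (outward order):
    1 iff max |W| inside the interval exceeds ``thls``."""
    flags = np.zeros(max(0, zeros.size - 1), dtype=int)
    for s in range(flags.size):
        a, b = sorted((zeros[s], zeros[s + 1]))
        if np.max(np.abs(w[a:b + 1])) > thls:
            flags[s] = 1
    return flags


def select_boundary_zero(flags: np.ndarray, lengths: np.ndarray,
                         ttsn: int, ttln: int) -> int:
    """Index into the zero-point list where the outward scan stops.

    Returns ``s`` such that ``zeros[s]`` is the boundary zero point; if the
    scan never stops the outermost zero point is selected.
    """
    eff = flags.copy()
    for s in range(eff.size):
        # forgive a lone short unsuitable interval annexed to suitable
        # territory; runs of unsuitable intervals are never forgiven
        if (eff[s] == 0 and lengths[s] < ttsn
                and (s + 1 >= eff.size or flags[s + 1] == 1)):
            eff[s] = 1
    m = eff.size
    for s in range(m):
        if eff[s] == 1:
            continue
        if lengths[s] > ttln:
            return s
        if s + 1 < m and eff[s + 1] == 0:
            return s
    return flags.size                    # outermost zero point


def trace_boundary(w: np.ndarray, zeros: np.ndarray, s_stop: int,
                   bpeak: int, side: str, ttls: int,
                   threshold: float) -> int:
    """Fine boundary inside the interval outward of ``zeros[s_stop]``.

    Traversing the interval inward (outer end towards z_on), the boundary
    is the last crossing of |W| through ``threshold``; for the typical
    residual lobe this is the point where activity finally drops away just
    outward of z_on.  Degenerate cases: |W| below the threshold throughout
    extends the boundary to the interval's outer end, |W| above throughout
    (e.g. a zero tracing threshold) keeps it at z_on.
    """
    z_on = int(zeros[s_stop])
    if s_stop + 1 < zeros.size:
        outer = int(zeros[s_stop + 1])
    else:
        outer = max(0, bpeak - ttls) if side == LEFT \
            else min(w.size - 1, bpeak + ttls)
    if outer == z_on:
        return z_on
    step = 1 if side == LEFT else -1          # inward traversal
    path = np.arange(outer, z_on + step, step)
    above = np.abs(w[path]) >= threshold
    events = np.flatnonzero(above[1:] != above[:-1])
    if events.size == 0:
        return z_on if above.all() else outer
    return int(path[events[-1] + 1])


def _delineate_on_scale(w: np.ndarray, bpeak: int, side: str, ttls: int,
                        cfg: PipelineConfig) -> Tuple[int, bool]:
    """Full zero-crossing pass on one coefficient trace.

    Returns (boundary sample, confident).  Without any zero crossing the
    boundary falls back to the window edge and is flagged low-confidence.
    """
    lo = max(0, bpeak - ttls)
    hi = min(w.size - 1, bpeak + ttls)
    thls = cfg.ratio_ls * np.max(np.abs(w[lo:hi + 1]))
    zeros = find_zero_crossings(w, bpeak, side, ttls)
    if zeros.size == 0:
        return (lo if side == LEFT else hi), False
    flags = classify_intervals(w, zeros, thls)
    lengths = np.abs(np.diff(zeros.astype(float))).astype(int)
    # the stretch from the outermost zero point to the window edge acts as
    # one more interval, so a trailing unsuitable interval can still form a
    # stopping pair when the coefficient trace stops crossing zero
    edge = lo if side == LEFT else hi
    vlen = abs(edge - int(zeros[-1]))
    if vlen > 0:
        a, b = sorted((edge, int(zeros[-1])))
        vflag = 1 if np.max(np.abs(w[a:b + 1])) > thls else 0
        flags = np.append(flags, vflag)
        lengths = np.append(lengths, vlen)
    s_stop = min(select_boundary_zero(flags, lengths, cfg.ttsn, cfg.ttln),
                 zeros.size - 1)
    q = trace_boundary(w, zeros, s_stop, bpeak, side, ttls,
                       cfg.trace_gamma * thls)
    return q, True


# --------------------------------------------------------------------------
# wide-QRS scale switching
# --------------------------------------------------------------------------

def is_wide_qrs(ep70: np.ndarray, ep120: np.ndarray, fiducial: int,
                window: int, eps_near: int, cfg: PipelineConfig) -> bool:
    """Wide-QRS criterion at one boundary.

    Wide iff the scale-120 energy in the ``window``-sample span centred on
    the fiducial reaches ``wide_energy_ratio`` times the scale-70 energy,
    and no cell within the +-``eps_near`` near zone reaches
    ``wide_energy_near_ratio`` of the window's maximum cell (energy packed
    against the boundary itself indicates a sharp transition already well
    delineated on scale 30).
    """
    n = ep70.size
    lo = max(0, fiducial - window // 2)
    hi = min(n - 1, fiducial + window // 2)
    s70 = float(ep70[lo:hi + 1].sum())
    s120 = float(ep120[lo:hi + 1].sum())
    if s120 < cfg.wide_energy_ratio * s70:
        return False
    e_max = max(ep70[lo:hi + 1].max(), ep120[lo:hi + 1].max())
    if e_max == 0:
        return False
    nl = max(0, fiducial - eps_near)
    nh = min(n - 1, fiducial + eps_near)
    near = max(ep70[nl:nh + 1].max(), ep120[nl:nh + 1].max())
    return near < cfg.wide_energy_near_ratio * e_max


def redelineate_wide(w70: np.ndarray, group: np.ndarray, side: str,
                     cfg: PipelineConfig) -> Tuple[int, bool]:
    """Boundary re-derived on W70 around its local maximum near the beat."""
    n = w70.size
    lo = max(0, int(np.min(group)) - cfg.ttar)
    hi = min(n - 1, int(np.max(group)) + cfg.ttar)
    bpeak70 = lo + int(np.argmax(np.abs(w70[lo:hi + 1])))
    return _delineate_on_scale(w70, bpeak70, side, cfg.tt3ls, cfg)


# --------------------------------------------------------------------------
# time-domain slope adjustment
# --------------------------------------------------------------------------

def adjust_by_slope(f: np.ndarray, fiducial: int, side: str,
                    cfg: PipelineConfig) -> int:
    """Time-domain boundary adjustment with sliding slope windows.

    TW-sample windows march towards the QRS in DELTA steps across the
    investigation zone — [fid-START, fid+STOP] before an onset, mirrored
    to [fid-STOP, fid+START] after an end.  The slope of a window is
    |f(end) - f(start)| / (TW - 1) in GAIN*mV per sample.  If a window
    whose accumulated shift exceeds ``slope_trigger_shift`` samples is
    steeper than THSLOPE, the boundary retreats to the nearest preceding
    window flatter than THSLOPE (its QRS-side edge); with no flat window
    at all it falls back to the far point of the zone (fid -+ START).  A
    flat zone leaves the boundary untouched.
    """
    n = f.size
    # (shift, slope, QRS-side edge); shift 0 at the far end of the zone
    slopes: List[Tuple[int, float, int]] = []
    for sh in range(0, cfg.start + cfg.stop - cfg.tw + 1, cfg.delta):
        if side == LEFT:
            w0 = fiducial - cfg.start + sh
            w1 = w0 + cfg.tw - 1
            edge = w1
        else:
            w1 = fiducial + cfg.start - sh
            w0 = w1 - cfg.tw + 1
            edge = w0
        if w0 < 0 or w1 > n - 1:
            continue                            # clamped out of the record
        # slope from the window endpoints only
        slope = abs(f[w1] - f[w0]) / (cfg.tw - 1)
        slopes.append((sh, slope, edge))
    fired_at = None
    for j, (sh, slope, _) in enumerate(slopes):
        if sh > cfg.slope_trigger_shift and slope > cfg.thslope:
            fired_at = j
            break
    if fired_at is None:
        return fiducial
    for sh, slope, edge in reversed(slopes[:fired_at]):
        if slope < cfg.thslope:
            return edge
    far = fiducial - cfg.start if side == LEFT else fiducial + cfg.start
    return int(np.clip(far, 0, n - 1))


# --------------------------------------------------------------------------
# inter-lead alignment
# --------------------------------------------------------------------------

def align_across_leads(values: Sequence[int], ttbs: int) -> np.ndarray:
    """If the pairwise spread exceeds ``ttbs``, replace the farthest lead's
    value with the rounded mean of the other two."""
    v = np.asarray(values, dtype=float)
    if v.size != 3:
        raise ValueError("alignment needs exactly three per-lead values")
    d = np.abs(v[:, None] - v[None, :])
    if d.max() <= ttbs:
        return v.astype(int)
    far = int(np.argmax(d.sum(axis=1)))
    rest = [j for j in range(3) if j != far]
    v[far] = _round_half_away(float(v[rest].mean()))
    return v.astype(int)


# --------------------------------------------------------------------------
# orchestration over beats
# --------------------------------------------------------------------------

@dataclass
class DelineationResult:
    q: np.ndarray               # (3, p) QRS onsets
    s: np.ndarray               # (3, p) QRS ends
    wide_onset: np.ndarray      # (3, p) bool: onset re-derived on W70
    wide_end: np.ndarray        # (3, p) bool
    confident: np.ndarray       # (3, p) bool: zero-crossing logic applied


def delineate(record: VcgRecord, stack: WaveletStack, cands: BeatCandidates,
              r_matrix: np.ndarray,
              cfg: Optional[PipelineConfig] = None) -> DelineationResult:
    """Run the full onset/end chain for every (lead, beat)."""
    cfg = cfg or PipelineConfig()
    p = cands.n_beats
    q = np.zeros((3, p), dtype=int)
    s = np.zeros((3, p), dtype=int)
    wide_on = np.zeros((3, p), dtype=bool)
    wide_off = np.zeros((3, p), dtype=bool)
    conf = np.ones((3, p), dtype=bool)

    for i in range(3):
        w30 = stack.coeff(i, 30)
        w70 = stack.coeff(i, 70)
        ep70 = stack.energy_at(i, 70)
        ep120 = stack.energy_at(i, 120)
        for k in range(p):
            bp = int(cands.bpeak[i, k])
            group = cands.groups[i][k]
            for side in (LEFT, RIGHT):
                fid, ok = _delineate_on_scale(w30, bp, side, cfg.ttls, cfg)
                window = cfg.tt1ls if side == LEFT else cfg.tt2ls
                eps_near = cfg.eps1 if side == LEFT else cfg.eps2
                wide = is_wide_qrs(ep70, ep120, fid, window, eps_near, cfg)
                if wide:
                    fid, ok = redelineate_wide(w70, group, side, cfg)
                fid = adjust_by_slope(record.leads[i], fid, side, cfg)
                if side == LEFT:
                    q[i, k], wide_on[i, k] = fid, wide
                else:
                    s[i, k], wide_off[i, k] = fid, wide
                conf[i, k] &= ok

    for k in range(p):
        q[:, k] = align_across_leads(q[:, k], cfg.ttbs)
        s[:, k] = align_across_leads(s[:, k], cfg.ttbs)
        # alignment may not break the per-beat ordering invariant
        for i in range(3):
            q[i, k] = min(q[i, k], r_matrix[i, k] - 1)
            s[i, k] = max(s[i, k], r_matrix[i, k] + 1)

    return DelineationResult(q=q, s=s, wide_onset=wide_on,
                             wide_end=wide_off, confident=conf)
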