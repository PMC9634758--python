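"""Seedable synthetic three-lead VCG records with exact ground truth.

Beats are built from Gaussian wave atoms (P, Q, R, S, T, plus optional
extra QRS lobes for wide morphologies), shared across leads up to per-lead
gains, so every fiducial has an analytic location: the true QRS onset (end)
is the first (last) sample where the summed absolute QRS-atom envelope
exceeds 1% of the effective R amplitude, and the true P end follows the
same rule on the P atom.  Noise — white Gaussian, sinusoidal baseline
wander, and powerline — is added after the truth is recorded, so the truth
describes the clean signal exactly.

Three presets emulate the morphology classes the delineator must cover:
``hc`` (narrow QRS, prominent R), ``mi_low_amp`` (small R relative to P/T
plus extra high-frequency noise), and ``bbb_wide`` (QRS > 120 ms with
dominant low-frequency content).  Amplitudes are in GAIN*mV (GAIN = 2000);
times in ms relative to the beat anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .record import GroundTruth, VcgRecord

#: fraction of the effective R amplitude defining the true onset/end
TRUTH_ENVELOPE_FRACTION = 0.01
#: atom support used when rendering, in standard deviations
_ATOM_SUPPORT_SD = 4.0
#: effective beat extent used by the overlap precondition (99.7% mass)
_OVERLAP_SD = 3.0
#: first/last beat anchor margin from the record edges, seconds
_EDGE_MARGIN_S = 0.6


@dataclass(frozen=True)
class WaveAtom:
    """One Gaussian wave: amplitude (GAIN*mV), centre and sigma (ms)."""

    amplitude: float
    center_ms: float
    width_ms: float


@dataclass
class SynthSpec:
    fs: float = 1000.0
    duration_s: float = 60.0
    rr_mean_s: float = 0.9
    rr_jitter_s: float = 0.2          # uniform +- jitter around the mean
    waves: Dict[str, WaveAtom] = field(default_factory=dict)
    lead_gains: Tuple[float, float, float] = (1.0, 0.7, -0.9)
    qrs_class: str = "narrow"         # 'narrow' | 'wide'
    noise_white_sigma: float = 0.0    # GAIN*mV; ignored when snr_db is set
    snr_db: Optional[float] = None    # white-noise level from clean-signal rms
    baseline_amp: float = 0.0         # GAIN*mV
    baseline_freq_hz: float = 0.25
    powerline_amp: float = 0.0        # GAIN*mV
    powerline_freq_hz: float = 50.0
    seed: int = 0

    def qrs_atoms(self) -> Dict[str, WaveAtom]:
        return {n: w for n, w in self.waves.items() if n[0] in "QRS"}


_PRESETS: Dict[str, SynthSpec] = {
    # narrow QRS, dominant R; typical healthy-control amplitudes
    "hc": SynthSpec(
        waves={
            "P": WaveAtom(200.0, -170.0, 18.0),
            "Q": WaveAtom(-300.0, -28.0, 4.0),
            "R": WaveAtom(2200.0, 0.0, 9.0),
            "S": WaveAtom(-500.0, 30.0, 6.0),
            "T": WaveAtom(500.0, 270.0, 45.0),
        },
        qrs_class="narrow",
    ),
    # small R against prominent P/T plus extra wideband noise
    "mi_low_amp": SynthSpec(
        waves={
            "P": WaveAtom(240.0, -170.0, 20.0),
            "Q": WaveAtom(-100.0, -25.0, 4.0),
            "R": WaveAtom(700.0, 0.0, 8.0),
            "S": WaveAtom(-250.0, 28.0, 6.0),
            "T": WaveAtom(600.0, 280.0, 50.0),
        },
        qrs_class="narrow",
        noise_white_sigma=15.0,
    ),
    # broad notched QRS (> 120 ms), low-frequency dominated
    "bbb_wide": SynthSpec(
        waves={
            "P": WaveAtom(200.0, -190.0, 16.0),
            "R": WaveAtom(1400.0, -20.0, 15.0),
            "R2": WaveAtom(-1100.0, 40.0, 15.0),
            "T": WaveAtom(500.0, 300.0, 50.0),
        },
        qrs_class="wide",
    ),
}


def preset(name: str, **overrides) -> SynthSpec:
    """Named morphology preset; keyword overrides replace spec fields."""
    try:
        spec = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return replace(spec, **overrides)


def _atom_trace(atom: WaveAtom, n: int, anchors: np.ndarray,
                fs: float) -> np.ndarray:
    """Superposition of one atom across all beats, unit lead gain."""
    out = np.zeros(n)
    sigma = atom.width_ms * fs / 1000.0
    center = atom.center_ms * fs / 1000.0
    half = int(np.ceil(_ATOM_SUPPORT_SD * sigma))
    for a in anchors:
        c = a + center
        lo = max(0, int(np.floor(c - half)))
        hi = min(n - 1, int(np.ceil(c + half)))
        b = np.arange(lo, hi + 1)
        out[lo:hi + 1] += atom.amplitude * np.exp(
            -0.5 * ((b - c) / sigma) ** 2)
    return out


def _envelope_bounds(atoms: Dict[str, WaveAtom], anchor: int,
                     ref_amp: float, fs: float, n: int
                     ) -> Tuple[int, int]:
    """First/last sample where the summed |atom| envelope of one beat
    exceeds TRUTH_ENVELOPE_FRACTION * ref_amp."""
    centers = [a.center_ms * fs / 1000.0 for a in atoms.values()]
    sigmas = [a.width_ms * fs / 1000.0 for a in atoms.values()]
    lo = int(np.floor(anchor + min(c - _ATOM_SUPPORT_SD * s
                                   for c, s in zip(centers, sigmas))))
    hi = int(np.ceil(anchor + max(c + _ATOM_SUPPORT_SD * s
                                  for c, s in zip(centers, sigmas))))
    lo, hi = max(0, lo), min(n - 1, hi)
    b = np.arange(lo, hi + 1, dtype=float)
    env = np.zeros(b.size)
    for atom in atoms.values():
        c = anchor + atom.center_ms * fs / 1000.0
        s = atom.width_ms * fs / 1000.0
        env += abs(atom.amplitude) * np.exp(-0.5 * ((b - c) / s) ** 2)
    above = np.flatnonzero(env > TRUTH_ENVELOPE_FRACTION * ref_amp)
    if above.size == 0:
        raise ValueError("wave envelope never exceeds the truth threshold")
    return lo + int(above[0]), lo + int(above[-1])


def generate(spec: SynthSpec) -> Tuple[VcgRecord, GroundTruth]:
    """Deterministically generate a record and its exact ground truth."""
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    if spec.duration_s < 2 * spec.rr_mean_s:
        raise ValueError("duration must cover at least two mean RR intervals")
    if not spec.waves or "R" not in spec.waves:
        raise ValueError("spec must define at least an R wave")
    extent_lo = min(w.center_ms - _OVERLAP_SD * w.width_ms
                    for w in spec.waves.values())
    extent_hi = max(w.center_ms + _OVERLAP_SD * w.width_ms
                    for w in spec.waves.values())
    rr_min_ms = (spec.rr_mean_s - spec.rr_jitter_s) * 1000.0
    if extent_hi - extent_lo > rr_min_ms:
        raise ValueError("RR too short: beat waves would overlap")

    rng = np.random.default_rng(spec.seed)
    anchors = []
    t = _EDGE_MARGIN_S * fs
    stop = n - _EDGE_MARGIN_S * fs
    while t <= stop:
        anchors.append(int(round(t)))
        t += (spec.rr_mean_s
              + rng.uniform(-spec.rr_jitter_s, spec.rr_jitter_s)) * fs
    anchors = np.asarray(anchors, dtype=int)
    p = anchors.size

    base = np.zeros(n)
    for atom in spec.waves.values():
        base += _atom_trace(atom, n, anchors, fs)
    clean = np.vstack([g * base for g in spec.lead_gains])

    qrs = spec.qrs_atoms()
    ref_amp = abs(spec.waves["R"].amplitude)
    onset = np.empty((3, p), dtype=int)
    end = np.empty((3, p), dtype=int)
    r_true = np.empty((3, p), dtype=int)
    p_end = np.empty((3, p), dtype=int)
    iso_level = np.empty((3, p))
    for k, a in enumerate(anchors):
        on_k, end_k = _envelope_bounds(qrs, a, ref_amp, fs, n)
        if "P" in spec.waves:
            _, pe_k = _envelope_bounds({"P": spec.waves["P"]}, a,
                                       abs(spec.waves["P"].amplitude), fs, n)
        else:
            pe_k = on_k - 1
        for i in range(3):
            onset[i, k], end[i, k], p_end[i, k] = on_k, end_k, pe_k
            seg = np.abs(clean[i, on_k:end_k + 1])
            r_true[i, k] = on_k + int(np.argmax(seg))
            iso_level[i, k] = float(np.mean(clean[i, pe_k + 1:on_k]))

    leads = clean.copy()
    if spec.snr_db is not None:
        rms = float(np.sqrt(np.mean(clean ** 2)))
        sigma = rms * 10.0 ** (-spec.snr_db / 20.0)
    else:
        sigma = spec.noise_white_sigma
    if sigma > 0:
        leads = leads + rng.normal(0.0, sigma, size=leads.shape)
    tt = np.arange(n) / fs
    if spec.baseline_amp:
        for i in range(3):
            phase = rng.uniform(0, 2 * np.pi)
            leads[i] += spec.baseline_amp * np.sin(
                2 * np.pi * spec.baseline_freq_hz * tt + phase)
    if spec.powerline_amp:
        for i in range(3):
            phase = rng.uniform(0, 2 * np.pi)
            leads[i] += spec.powerline_amp * np.sin(
                2 * np.pi * spec.powerline_freq_hz * tt + phase)

    record = VcgRecord(leads=leads, fs=fs,
                       record_id=f"synth-{spec.qrs_class}-{spec.seed}")
    truth = GroundTruth(r=r_true, onset=onset, end=end, p_end=p_end,
                        iso_level=iso_level, qrs_class=spec.qrs_class, fs=fs)
    return record, truth


def truth_to_frame(truth: GroundTruth):
    """Ground truth as a tidy DataFrame (one row per lead and beat)."""
    import pandas as pd
    from .record import LEAD_NAMES
    rows = []
    ms = 1000.0 / truth.fs
    for i in range(3):
        for k in range(truth.n_beats):
            rows.append({
                "lead": LEAD_NAMES[i], "beat": k,
                "r": int(truth.r[i, k]), "r_ms": truth.r[i, k] * ms,
                "onset": int(truth.onset[i, k]),
                "onset_ms": truth.onset[i, k] * ms,
                "end": int(truth.end[i, k]),
                "end_ms": truth.end[i, k] * ms,
                "p_end": int(truth.p_end[i, k]),
                "p_end_ms": truth.p_end[i, k] * ms,
                "iso_level": float(truth.iso_level[i, k]),
                "qrs_class": truth.qrs_class,
            })
    return pd.DataFrame(rows)


def frame_to_truth(df) -> GroundTruth:
    """Inverse of :func:`truth_to_frame`."""
    from .record import LEAD_NAMES
    p = int(df["beat"].max()) + 1
    arrs = {name: np.zeros((3, p), dtype=int)
            for name in ("r", "onset", "end", "p_end")}
    iso = np.zeros((3, p))
    qrs_class = str(df["qrs_class"].iloc[0])
    for _, row in df.iterrows():
        i = LEAD_NAMES.index(row["lead"])
        k = int(row["beat"])
        for name in arrs:
            arrs[name][i, k] = int(row[name])
        iso[i, k] = float(row["iso_level"])
    return GroundTruth(iso_level=iso, qrs_class=qrs_class, **arrs)
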