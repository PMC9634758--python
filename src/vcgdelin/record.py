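"""Record and fiducial containers plus readers/writers.

A :class:`VcgRecord` holds three orthogonal leads (X, Y, Z) in GAIN*mV units
(GAIN = 2000, the native integer scale of PTB-style recordings).  Sample
indices are 0-based throughout the package; on-disk fiducial files carry both
the sample index and its millisecond equivalent, so the convention is
unambiguous to external consumers.

Supported inputs:

* plain CSV, one column per lead, header row, comma separated;
* WFDB-style ``.hea``/``.dat`` pairs restricted to storage format 16
  (interleaved little-endian int16), which covers the PTB layout.

Records not sampled at 1000 Hz are polyphase-resampled to 1000 Hz on
ingestion because every sample-denominated constant of the delineator is
defined at that rate.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

GAIN = 2000.0
WORK_FS = 1000.0

LEAD_NAMES = ("X", "Y", "Z")
#: channel-name aliases recognised when picking X/Y/Z out of a multichannel file
_DEFAULT_ALIASES = {
    "X": ("x", "vx", "lead_x"),
    "Y": ("y", "vy", "lead_y"),
    "Z": ("z", "vz", "lead_z"),
}


@dataclass
class VcgRecord:
    """Three equal-length orthogonal leads, amplitudes in GAIN*mV."""

    leads: np.ndarray          # shape (3, N), float64
    fs: float
    record_id: str = ""

    def __post_init__(self) -> None:
        self.leads = np.asarray(self.leads, dtype=float)
        if self.leads.ndim != 2 or self.leads.shape[0] != 3:
            raise ValueError("leads must have shape (3, N)")
        if self.leads.shape[1] < 1:
            raise ValueError("leads must contain at least one sample")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.leads.shape[1]

    def with_leads(self, leads: np.ndarray) -> "VcgRecord":
        return VcgRecord(leads=leads, fs=self.fs, record_id=self.record_id)

    def resampled(self, fs: float = WORK_FS) -> "VcgRecord":
        """Polyphase-resample to ``fs`` (identity if already there)."""
        if self.fs == fs:
            return self
        frac = Fraction(fs / self.fs).limit_denominator(1000)
        leads = resample_poly(self.leads, frac.numerator, frac.denominator,
                              axis=1)
        return VcgRecord(leads=leads, fs=fs, record_id=self.record_id)


@dataclass
class FiducialTable:
    """Per-lead, per-beat sample indices of the detected fiducials.

    All arrays have shape (3, p) for p detected beats; ``-1`` marks a
    missing value (e.g. a clamped search window).
    """

    r: np.ndarray
    q: np.ndarray
    s: np.ndarray
    pq_begin: np.ndarray
    pq_end: np.ndarray
    fs: float = WORK_FS
    record_id: str = ""

    def __post_init__(self) -> None:
        for name in ("r", "q", "s", "pq_begin", "pq_end"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.ndim != 2 or arr.shape[0] != 3:
                raise ValueError(f"{name} must have shape (3, p)")
            setattr(self, name, arr)
        shapes = {getattr(self, n).shape for n in
                  ("r", "q", "s", "pq_begin", "pq_end")}
        if len(shapes) != 1:
            raise ValueError("all fiducial matrices must share one shape")

    @property
    def n_beats(self) -> int:
        return self.r.shape[1]

    def validate(self, n_samples: Optional[int] = None,
                 stop1: int = 10) -> None:
        """Check the ordering invariants q < r < s and PQ placement."""
        ok = self.r >= 0
        if not np.all(self.q[ok] < self.r[ok]):
            raise ValueError("found q >= r")
        if not np.all(self.r[ok] < self.s[ok]):
            raise ValueError("found r >= s")
        pq_ok = ok & (self.pq_begin >= 0)
        if not np.all(self.pq_begin[pq_ok] < self.pq_end[pq_ok]):
            raise ValueError("found pq_begin >= pq_end")
        if not np.all(self.pq_end[pq_ok] <= self.q[pq_ok] + stop1):
            raise ValueError("found PQ window past q + STOP1")
        if n_samples is not None and np.any(self.s >= n_samples):
            raise ValueError("fiducial outside record")

    def to_frame(self, summary: Optional["LoopSummary"] = None) -> pd.DataFrame:
        ms = 1000.0 / self.fs
        rows = []
        for i in range(3):
            for k in range(self.n_beats):
                row = {"record": self.record_id, "lead": LEAD_NAMES[i],
                       "beat": k}
                for name in ("r", "q", "s", "pq_begin", "pq_end"):
                    v = int(getattr(self, name)[i, k])
                    row[name] = v
                    row[f"{name}_ms"] = v * ms if v >= 0 else float("nan")
                if summary is not None:
                    row["iso"] = float(summary.iso[i, k])
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class LoopSummary:
    """Record-global loop boundaries and per-loop isoelectric coordinates."""

    bound_l: int
    bound_r: int
    iso: np.ndarray            # shape (3, p), GAIN*mV

    def __post_init__(self) -> None:
        self.iso = np.asarray(self.iso, dtype=float)
        if self.bound_l < 0 or self.bound_r < 0:
            raise ValueError("loop boundaries must be non-negative")
        if self.iso.ndim != 2 or self.iso.shape[0] != 3:
            raise ValueError("iso must have shape (3, p)")


@dataclass
class GroundTruth:
    """Exact synthetic-record fiducials used by the evaluation module."""

    r: np.ndarray              # (3, p) true R-peak samples
    onset: np.ndarray          # (3, p) true QRS onsets
    end: np.ndarray            # (3, p) true QRS ends
    p_end: np.ndarray          # (3, p) true P-wave ends
    iso_level: np.ndarray      # (3, p) true isoelectric level, GAIN*mV
    qrs_class: str = "narrow"  # 'narrow' | 'wide'
    fs: float = WORK_FS

    def __post_init__(self) -> None:
        for name in ("r", "onset", "end", "p_end"):
            arr = np.asarray(getattr(self, name), dtype=int)
            setattr(self, name, arr)
        self.iso_level = np.asarray(self.iso_level, dtype=float)
        if np.any(np.diff(self.r, axis=1) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if not (np.all(self.onset < self.r) and np.all(self.r < self.end)):
            raise ValueError("need onset < peak < end")

    @property
    def n_beats(self) -> int:
        return self.r.shape[1]


# --------------------------------------------------------------------------
# readers
# --------------------------------------------------------------------------

def read_record(path: str | Path, fmt: Optional[str] = None,
                fs: Optional[float] = None,
                channels: Optional[Mapping[str, str] | Sequence[str]] = None,
                record_id: Optional[str] = None,
                resample: bool = True) -> VcgRecord:
    """Read a three-lead record from CSV or a WFDB-style header.

    Parameters
    ----------
    path
        ``.csv`` file or ``.hea`` header (a bare stem is tried as header).
    fmt
        ``'csv'`` or ``'wfdb'``; inferred from the suffix when omitted.
    fs
        Sampling rate for CSV input (defaults to 1000 Hz); ignored for
        WFDB-style input, whose header states the rate.
    channels
        Mapping ``{'X': name, 'Y': name, 'Z': name}`` or sequence of three
        column/channel names.  Required when the file holds more than three
        channels and the X/Y/Z names cannot be recognised.
    resample
        Resample to the 1000 Hz working rate (default) after ingestion.
    """
    path = Path(path)
    if fmt is None:
        if path.suffix.lower() == ".csv":
            fmt = "csv"
        elif path.suffix.lower() in (".hea", ""):
            fmt = "wfdb"
        else:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if fmt == "csv":
        rec = _read_csv(path, fs or WORK_FS, channels, record_id)
    elif fmt == "wfdb":
        rec = _read_wfdb(path, channels, record_id)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return rec.resampled() if resample else rec


def _pick_channels(names: Sequence[str],
                   channels: Optional[Mapping[str, str] | Sequence[str]]
                   ) -> list[int]:
    lower = [str(n).strip().lower() for n in names]
    if channels is not None:
        if isinstance(channels, Mapping):
            wanted = [channels[k] for k in LEAD_NAMES]
        else:
            wanted = list(channels)
        if len(wanted) != 3:
            raise ValueError("channel mapping must name exactly three leads")
        idx = []
        for w in wanted:
            try:
                idx.append(lower.index(str(w).strip().lower()))
            except ValueError:
                raise ValueError(f"missing lead: channel {w!r} not found")
        return idx
    if len(names) == 3:
        return [0, 1, 2]
    if len(names) < 3:
        raise ValueError("missing lead: need at least 3 channels")
    idx = []
    for lead in LEAD_NAMES:
        aliases = _DEFAULT_ALIASES[lead]
        hits = [j for j, n in enumerate(lower) if n in aliases]
        if not hits:
            raise ValueError(
                f"missing lead {lead}: >3 channels and no recognisable "
                f"X/Y/Z names; pass an explicit channel mapping")
        idx.append(hits[0])
    return idx


def _read_csv(path: Path, fs: float, channels, record_id) -> VcgRecord:
    df = pd.read_csv(path)
    idx = _pick_channels(list(df.columns), channels)
    leads = df.iloc[:, idx].to_numpy(dtype=float).T
    return VcgRecord(leads=leads, fs=fs,
                     record_id=record_id or path.stem)


def _read_wfdb(path: Path, channels, record_id) -> VcgRecord:
    """Minimal WFDB-style reader (storage format 16 only)."""
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError("unreadable header: expected "
                         "'name nsig fs nsamples' on the first line")
    name, nsig = head[0], int(head[1])
    fs = float(head[2].split("/")[0])
    nsamp = int(head[3])
    sig_lines = lines[1:1 + nsig]
    if len(sig_lines) != nsig:
        raise ValueError("unreadable header: missing signal lines")
    files, fmts, gains, baselines, names = [], [], [], [], []
    for j, ln in enumerate(sig_lines):
        tok = ln.split()
        files.append(tok[0])
        fmts.append(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain = 200.0
        baseline = 0.0
        if len(tok) > 2:
            gtok = tok[2]
            if "(" in gtok:
                gtok, btok = gtok.split("(", 1)
                baseline = float(btok.rstrip(")"))
            gtok = gtok.split("/")[0]
            if gtok:
                gain = float(gtok)
        gains.append(gain if gain != 0 else 200.0)
        baselines.append(baseline)
        names.append(tok[-1] if len(tok) > 4 else f"ch{j}")
    if any(f != "16" for f in fmts):
        raise ValueError("only WFDB storage format 16 is supported")
    if len(set(files)) != 1:
        raise ValueError("multi-file records are not supported")
    dat = hea.with_name(files[0])
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if raw.size % nsig:
        raise ValueError("inconsistent channel lengths in .dat payload")
    frames = raw.size // nsig
    if frames < nsamp:
        raise ValueError("inconsistent channel lengths: "
                         f".dat holds {frames} frames, header says {nsamp}")
    sig = raw.reshape(frames, nsig).T[:, :nsamp].astype(float)
    idx = _pick_channels(names, channels)
    leads = np.empty((3, nsamp))
    for row, j in enumerate(idx):
        mv = (sig[j] - baselines[j]) / gains[j]
        leads[row] = mv * GAIN
    return VcgRecord(leads=leads, fs=fs, record_id=record_id or name)


def write_wfdb(record: VcgRecord, stem: str | Path,
               names: Sequence[str] = ("vx", "vy", "vz"),
               gain: float = 2000.0) -> None:
    """Write a record as a WFDB-style .hea/.dat pair (format 16)."""
    stem = Path(stem)
    mv = record.leads / GAIN
    adc = np.rint(mv * gain).astype("<i2")
    stem.with_suffix(".dat").write_bytes(adc.T.tobytes())
    lines = [f"{stem.name} 3 {record.fs:g} {record.n_samples}"]
    for nm in names:
        lines.append(f"{stem.name}.dat 16 {gain:g} 16 0 0 0 0 {nm}")
    stem.with_suffix(".hea").write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# fiducial output
# --------------------------------------------------------------------------

def write_fiducials(table: FiducialTable, summary: Optional[LoopSummary],
                    path: str | Path) -> None:
    """Write fiducials (and the loop summary) as CSV or JSON.

    CSV output: one row per (lead, beat) with each fiducial given both as a
    0-based sample index and in milliseconds; ``boundL``/``boundR`` ride in
    ``#``-prefixed header comments.  JSON output holds the same content as a
    single object.  An empty table yields a header-only file and a warning.
    """
    path = Path(path)
    if table.n_beats == 0:
        warnings.warn("writing fiducials for an empty table "
                      "(no beats detected)")
    if path.suffix.lower() == ".json":
        obj = {
            "record": table.record_id,
            "fs": table.fs,
            "index_base": 0,
            "fiducials": {name: np.asarray(getattr(table, name)).tolist()
                          for name in ("r", "q", "s", "pq_begin", "pq_end")},
        }
        if summary is not None:
            obj["boundL"] = int(summary.bound_l)
            obj["boundR"] = int(summary.bound_r)
            obj["iso"] = summary.iso.tolist()
        path.write_text(json.dumps(obj, indent=1))
        return
    df = table.to_frame(summary)
    with path.open("w") as fh:
        fh.write(f"# record: {table.record_id}\n")
        fh.write(f"# fs_hz: {table.fs:g}\n")
        fh.write("# index_base: 0\n")
        if summary is not None:
            fh.write(f"# boundL: {summary.bound_l}\n")
            fh.write(f"# boundR: {summary.bound_r}\n")
        if df.empty:
            cols = ["record", "lead", "beat"]
            for name in ("r", "q", "s", "pq_begin", "pq_end"):
                cols += [name, f"{name}_ms"]
            if summary is not None:
                cols.append("iso")
            fh.write(",".join(cols) + "\n")
        else:
            df.to_csv(fh, index=False)


def read_fiducials(path: str | Path
                   ) -> tuple[FiducialTable, Optional[LoopSummary]]:
    """Read back a file written by :func:`write_fiducials`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        fid = {k: np.asarray(v, dtype=int)
               for k, v in obj["fiducials"].items()}
        table = FiducialTable(fs=obj["fs"], record_id=obj.get("record", ""),
                              **fid)
        summary = None
        if "boundL" in obj:
            summary = LoopSummary(obj["boundL"], obj["boundR"],
                                  np.asarray(obj["iso"]))
        return table, summary
    import io
    meta = {}
    lines = path.read_text().splitlines(keepends=True)
    body = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].partition(":")
        meta[key.strip()] = val.strip()
        body += 1
    df = pd.read_csv(io.StringIO("".join(lines[body:])))
    fs = float(meta.get("fs_hz", WORK_FS))
    record_id = meta.get("record", "")
    if df.empty:
        empty = np.zeros((3, 0), dtype=int)
        table = FiducialTable(empty, empty, empty, empty, empty,
                              fs=fs, record_id=record_id)
    else:
        p = int(df["beat"].max()) + 1
        arrs = {name: np.full((3, p), -1, dtype=int)
                for name in ("r", "q", "s", "pq_begin", "pq_end")}
        iso = np.zeros((3, p))
        for _, row in df.iterrows():
            i = LEAD_NAMES.index(row["lead"])
            k = int(row["beat"])
            for name in arrs:
                arrs[name][i, k] = int(row[name])
            if "iso" in row:
                iso[i, k] = float(row["iso"])
        table = FiducialTable(fs=fs, record_id=record_id, **arrs)
    summary = None
    if "boundL" in meta:
        iso_arr = iso if not df.empty else np.zeros((3, 0))
        summary = LoopSummary(int(meta["boundL"]), int(meta["boundR"]),
                              iso_arr)
    return table, summary
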