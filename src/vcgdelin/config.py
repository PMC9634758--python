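"""Pipeline configuration.

All tunable constants of the delineator live in :class:`PipelineConfig`.
Sample-denominated parameters (``ttg``, ``ttls``, ...) are defined at the
working rate of 1000 Hz; records at other rates are resampled on ingestion.
Amplitude-denominated parameters (``thslope``) are in GAIN*mV units with
GAIN = 2000, i.e. the native integer scale of PTB-style records.

The on-disk format is a flat ``key = value`` text file whose dump/load
round-trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple


@dataclass
class PipelineConfig:
    # -- wavelet engine -----------------------------------------------------
    wavelet: str = "bior2.2"
    scales: Tuple[int, ...] = (10, 30, 50, 70, 120)

    # -- preprocessing ------------------------------------------------------
    hp_passband_hz: float = 1.0
    hp_stopband_hz: float = 0.5
    hp_stop_atten_db: float = 61.0
    notch_bw_hz: float = 0.17
    notch_atten_db: float = 60.0
    notch_f0: float = 50.0

    # -- QRS peak detection (scale 30) -------------------------------------
    ratio_o: float = 0.7     # record-global threshold ratio on |W30|
    ratio_a: float = 0.7     # within-beat pruning ratio on |W30|
    ttg: int = 200           # max intra-beat gap / inter-lead cluster radius
    tte: int = 200           # edge exclusion zone
    eps_refine: int = 10     # +-window for amplitude refinement of the R peak

    # -- QRS onset/end on W30 zero crossings --------------------------------
    ttls: int = 150          # zero-crossing search half-window around bpeak
    ratio_ls: float = 0.3    # oscillation-threshold ratio for interval flags
    ttsn: int = 10           # short unsuitable interval forgiven below this
    ttln: int = 25           # single unsuitable interval stops scan above this
    trace_gamma: float = 0.05  # sub-threshold fraction for fine onset tracing

    # -- wide-QRS detection and W70 re-delineation --------------------------
    tt1ls: int = 200         # energy comparison window, onset side
    tt2ls: int = 200         # energy comparison window, end side
    tt3ls: int = 200         # W70 zero-crossing search half-window
    eps1: int = 16           # near-neighbourhood veto zone, onset side
    eps2: int = 24           # near-neighbourhood veto zone, end side
    ttar: int = 50           # padding of the candidate set for the W70 peak
    wide_energy_ratio: float = 2.0       # scale-120 vs scale-70 energy ratio
    wide_energy_near_ratio: float = 0.5  # veto: near-zone energy vs window max

    # -- slope adjustment of onset/end --------------------------------------
    tw: int = 10
    start: int = 30
    stop: int = 0
    delta: int = 2
    thslope: float = 10.0    # GAIN*mV per sample
    slope_trigger_shift: int = 6  # slope exceedance only counts for shift > this

    # -- inter-lead alignment ------------------------------------------------
    ttbs: int = 80

    # -- isoelectric PQ window ----------------------------------------------
    tw1: int = 20
    start1: int = 50
    stop1: int = 10
    delta1: int = 2

    # -- evaluation ----------------------------------------------------------
    match_tol_ms: float = 75.0

    def validate(self) -> None:
        if not self.scales:
            raise ValueError("scales must be non-empty")
        if any(a <= 0 for a in self.scales):
            raise ValueError("scales must be positive")
        for key in ("ratio_o", "ratio_a", "ratio_ls", "trace_gamma"):
            if not 0.0 <= getattr(self, key) <= 1.0:
                raise ValueError(f"{key} must lie in [0, 1]")
        for key in ("ttg", "tte", "ttls", "ttsn", "ttln", "tt1ls", "tt2ls",
                    "tt3ls", "eps1", "eps2", "ttar", "tw", "start", "delta",
                    "ttbs", "tw1", "start1", "stop1", "delta1"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")
        if self.tte < self.eps_refine:
            raise ValueError("tte must be >= eps_refine")
        if self.tw > self.start + self.stop:
            raise ValueError("slope window tw wider than its search range")
        if self.tw1 > self.start1 + self.stop1:
            raise ValueError("PQ window tw1 wider than its search range")

    # ---------------------------------------------------------------- dump/load
    def dump(self, path: str | Path) -> None:
        Path(path).write_text(self.dumps())

    def dumps(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.loads(Path(path).read_text())

    @classmethod
    def loads(cls, text: str) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            typ = fields[key].type
            if typ.startswith("Tuple"):
                kwargs[key] = tuple(int(x) for x in val.split(","))
            elif typ == "int":
                kwargs[key] = int(val)
            elif typ == "float":
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
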