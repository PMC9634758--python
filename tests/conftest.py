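"""Shared fixtures: synthetic records and full pipeline runs.

Everything is generated programmatically and deterministically; the heavier
multi-record suite is session-scoped so the detector-performance tests
share one computation.
"""

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pytest

import vcgdelin as v

PRESETS = ("hc", "mi_low_amp", "bbb_wide")


@pytest.fixture()
def cfg() -> v.PipelineConfig:
    return v.PipelineConfig()


@dataclass
class PipelineCase:
    name: str
    record: v.VcgRecord
    truth: v.GroundTruth
    result: v.PipelineResult
    pairs: np.ndarray          # detected -> truth beat index map (lead X)
    score: v.DetectionScore


def _run_case(name: str, seed: int, duration: float,
              snr_db: float | None) -> PipelineCase:
    spec = v.preset(name, duration_s=duration, seed=seed, snr_db=snr_db,
                    noise_white_sigma=0.0 if snr_db is None else 0.0)
    record, truth = v.generate(spec)
    result = v.run_pipeline(record, notch_enabled=False)
    fid = result.fiducials
    score, pairs = v.match_beats(fid.r[0].astype(float),
                                 truth.r[0].astype(float), 75.0)
    return PipelineCase(name=name, record=record, truth=truth,
                       result=result, pairs=pairs, score=score)


@pytest.fixture(scope="session")
def clean_cases() -> Dict[str, PipelineCase]:
    """One clean (noise-free) 20 s record per preset, fully delineated."""
    return {name: _run_case(name, seed=11, duration=20.0, snr_db=None)
            for name in PRESETS}


@pytest.fixture(scope="session")
def noisy_suite() -> List[PipelineCase]:
    """The mixed-preset 20-record 60 s suite at 20 dB SNR (seeds 1..20)."""
    return [_run_case(PRESETS[j % 3], seed=j + 1, duration=60.0,
                      snr_db=20.0) for j in range(20)]
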