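"""PQ window search, loop boundaries, isoelectric coordinates, loops."""

import numpy as np
import pytest

import vcgdelin as v
from vcgdelin.boundaries import regression_slope


def brute_force_pq(f, q, cfg):
    """Enumerate every candidate window and take the flattest (oracle)."""
    best = None
    for sh in range(0, cfg.start1 + cfg.stop1 - cfg.tw1 + 1, cfg.delta1):
        w0 = q - cfg.start1 + sh
        s = abs(regression_slope(f[w0:w0 + cfg.tw1]))
        if best is None or s < best[0]:
            best = (s, w0)
    return best[1], best[1] + cfg.tw1 - 1


class TestDetectPq:
    def test_flat_region_wins(self, cfg):
        rng = np.random.default_rng(3)
        f = np.cumsum(rng.normal(0, 5, size=400))       # wandering signal
        f[330:361] = f[330]                             # flat plateau
        begin, end = v.detect_pq(f, 380, cfg)
        assert 330 <= begin and end <= 361
        assert (begin, end) == brute_force_pq(f, 380, cfg)

    def test_globally_linear_ties_to_earliest(self, cfg):
        f = 2.0 * np.arange(400)
        begin, end = v.detect_pq(f, 300, cfg)
        assert begin == 300 - cfg.start1

    def test_window_width_is_fixed(self, cfg):
        rng = np.random.default_rng(5)
        f = rng.normal(size=500)
        begin, end = v.detect_pq(f, 400, cfg)
        assert end - begin + 1 == cfg.tw1

    def test_out_of_range_flags_missing(self, cfg):
        with pytest.warns(UserWarning, match="leaves the record"):
            assert v.detect_pq(np.zeros(100), 4, cfg) == (-1, -1)


class TestLoopBoundaries:
    def test_single_beat(self):
        r = np.full((3, 1), 1000)
        pq_begin = r - 120
        s = r + 80
        assert v.loop_boundaries(r, pq_begin, s) == (120, 80)

    def test_median_is_robust_to_outlier(self):
        r = np.array([[1000, 2000, 3000]] * 3)
        pq_begin = r - np.array([[118, 120, 260]] * 3)
        s = r + 80
        bl, br = v.loop_boundaries(r, pq_begin, s)
        assert bl == 120

    def test_even_count_uses_central_mean(self):
        r = np.array([[1000, 2000]] * 3)
        pq_begin = r - np.array([[100, 110]] * 3)
        bl, _ = v.loop_boundaries(r, pq_begin, r + 50)
        assert bl == 105

    def test_incomplete_beats_excluded_with_warning(self):
        r = np.array([[1000, 2000]] * 3)
        pq_begin = r - 100
        pq_begin[1, 1] = -1
        with pytest.warns(UserWarning, match="excluded"):
            bl, _ = v.loop_boundaries(r, pq_begin, r + 50)
        assert bl == 100

    def test_invariant_under_beat_reordering(self, clean_cases):
        fid = clean_cases["hc"].result.fiducials
        perm = np.random.default_rng(0).permutation(fid.n_beats)
        a = v.loop_boundaries(fid.r, fid.pq_begin, fid.s)
        b = v.loop_boundaries(fid.r[:, perm], fid.pq_begin[:, perm],
                              fid.s[:, perm])
        assert a == b


class TestIsoCoordinates:
    def test_constant_level(self):
        f = np.full(100, 7.5)
        assert v.iso_coordinates(f, (20, 39)) == 7.5

    def test_linear_ramp_gives_midpoint(self):
        f = np.arange(100.0)
        assert v.iso_coordinates(f, (10, 30)) == f[20]

    def test_interior_mean(self):
        f = np.array([99.0, 2, 4, 6, 8, 99])
        assert v.iso_coordinates(f, (0, 5)) == 5.0

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            v.iso_coordinates(np.zeros(10), (3, 4))


class TestAlignLoops:
    def test_offset_removed_and_lengths_identical(self, clean_cases):
        case = clean_cases["hc"]
        res = case.result
        length = res.summary.bound_l + res.summary.bound_r + 1
        assert res.loops.shape[1:] == (3, length)
        # the PQ window inside each aligned loop averages to ~zero
        fid = res.fiducials
        for j, k in enumerate(res.kept_beats):
            r1 = fid.r[0, k]
            for i in range(3):
                a = fid.pq_begin[i, k] - (r1 - res.summary.bound_l)
                b = fid.pq_end[i, k] - (r1 - res.summary.bound_l)
                if 0 <= a < b < length:
                    seg = res.loops[j, i, a + 1:b]
                    assert abs(seg.mean()) < 1e-9 * max(
                        1.0, np.abs(res.loops).max())

    def test_identical_beats_give_identical_loops(self):
        n = 8000
        f = np.zeros(n)
        for c in (2000, 4000, 6000):
            t = np.arange(n)
            f += 1000 * np.exp(-0.5 * ((t - c) / 9.0) ** 2)
        rec = v.VcgRecord(leads=np.vstack([f, 0.7 * f, -0.9 * f]),
                          fs=1000.0)
        r = np.array([[2000, 4000, 6000]] * 3)
        table = v.FiducialTable(r=r, q=r - 40, s=r + 40,
                                pq_begin=r - 120, pq_end=r - 101)
        summary = v.summarize_loops(rec, table)
        loops, kept = v.align_loops(rec, table, summary)
        assert len(kept) == 3
        np.testing.assert_allclose(loops[0], loops[1], atol=1e-9)
        np.testing.assert_allclose(loops[0], loops[2], atol=1e-9)
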