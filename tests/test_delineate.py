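"""Onset/end delineation: zero-crossing logic, wide switching, slope
adjustment, and inter-lead alignment."""

import numpy as np
import pytest

import vcgdelin as v
from vcgdelin.delineate import (LEFT, RIGHT, _delineate_on_scale,
                                redelineate_wide, trace_boundary)


class TestZeroCrossings:
    def test_sine_crossings_every_half_period(self):
        b = np.arange(4000)
        w = np.sin(2 * np.pi * (b - 2000) / 100.0 + np.pi / 2)  # crest at 2000
        left = v.find_zero_crossings(w, 2000, LEFT, 150)
        right = v.find_zero_crossings(w, 2000, RIGHT, 150)
        np.testing.assert_array_equal(left, [1975, 1925, 1875])
        np.testing.assert_array_equal(right, [2025, 2075, 2125])

    def test_positive_window_has_no_crossings(self):
        w = np.ones(1000)
        assert v.find_zero_crossings(w, 500, LEFT, 150).size == 0

    def test_interpolated_crossing_rounds_to_sample(self):
        w = np.ones(300)
        w[99], w[100] = -1.0, 3.0          # crossing at 99.25 -> sample 99
        out = v.find_zero_crossings(w, 150, LEFT, 100)
        assert 99 in out


class TestIntervalFlags:
    def test_amplitude_rule(self):
        w = np.zeros(200)
        zeros = np.array([50, 80, 120])
        w[60:70] = 0.5                     # lobe in first interval
        w[90:110] = 0.2
        flags = v.classify_intervals(w, zeros, thls=0.3)
        np.testing.assert_array_equal(flags, [1, 0])

    @pytest.mark.parametrize("flags,lengths,stop", [
        # suitable run then a pair of unsuitable intervals
        ([1, 1, 0, 0, 1], [30, 30, 30, 30, 30], 2),
        # short unsuitable forgiven, stop at the later pair
        ([1, 0, 1, 0, 0], [30, 8, 30, 30, 30], 3),
        # one long unsuitable interval stops the scan by itself
        ([1, 0], [30, 30], 1),
        # published example pattern, left side
        ([1, 0, 0, 0, 0, 1], [30, 15, 15, 15, 15, 30], 1),
        # published example pattern, right side
        ([1, 0, 0, 0, 0, 0, 0], [30, 15, 15, 15, 15, 15, 15], 1),
        # nothing stops the scan
        ([1, 1, 1], [30, 30, 30], 3),
    ])
    def test_stop_rules(self, flags, lengths, stop):
        got = v.select_boundary_zero(np.array(flags), np.array(lengths),
                                     ttsn=10, ttln=25)
        assert got == stop


class TestTrace:
    def test_quiet_interval_extends_to_outer_end(self):
        w = np.zeros(400)
        w[201:] = 1.0          # w is identically zero outward of z_on=200
        q = trace_boundary(w, np.array([200, 150]), 0, 250, LEFT, 150,
                           threshold=0.1)
        assert q == 150

    def test_monotone_ramp_stops_at_threshold_crossing(self):
        w = np.zeros(400)
        w[100:151] = np.linspace(0.0, 1.0, 51)   # rising into the QRS
        q = trace_boundary(w, np.array([150, 100]), 0, 250, LEFT, 150,
                           threshold=0.5)
        assert q == pytest.approx(125, abs=1)

    def test_zero_threshold_keeps_zero_point(self):
        w = np.random.default_rng(0).normal(size=400)
        q = trace_boundary(w, np.array([200, 150]), 0, 250, LEFT, 150,
                           threshold=0.0)
        assert q == 200


class TestWideSwitch:
    def test_double_energy_with_quiet_near_zone(self, cfg):
        n = 600
        ep70 = np.zeros(n)
        ep120 = np.zeros(n)
        ep70[360:380] = 1.0
        ep120[360:380] = 2.1               # double energy at scale 120
        assert v.is_wide_qrs(ep70, ep120, 300, cfg.tt1ls, cfg.eps1, cfg)

    def test_equal_energy_is_narrow(self, cfg):
        n = 600
        ep = np.zeros(n)
        ep[350:380] = 1.0
        assert not v.is_wide_qrs(ep, ep.copy(), 300, cfg.tt1ls, cfg.eps1,
                                 cfg)

    def test_energy_packed_at_boundary_vetoes(self, cfg):
        n = 600
        ep70 = np.zeros(n)
        ep120 = np.zeros(n)
        ep120[295:306] = 2.0               # everything inside the near zone
        ep70[295:306] = 0.5
        assert not v.is_wide_qrs(ep70, ep120, 300, cfg.tt1ls, cfg.eps1,
                                 cfg)

    def test_presets_switch_scales_correctly(self, clean_cases):
        wide = clean_cases["bbb_wide"].result.delineation
        narrow = clean_cases["hc"].result.delineation
        assert np.all(wide.wide_onset | wide.wide_end)
        assert not np.any(narrow.wide_onset | narrow.wide_end)

    def test_wide_redelineation_beats_scale_30(self, clean_cases, cfg):
        """On a wide QRS the scale-70 boundary is closer to the truth."""
        case = clean_cases["bbb_wide"]
        stack = v.cwt_stack(case.result.record, cfg.scales)
        cands = case.result.candidates
        i = 0
        errs30, errs70 = [], []
        for j, k in case.pairs[:5]:
            bp = int(cands.bpeak[i, j])
            q30, _ = _delineate_on_scale(stack.coeff(i, 30), bp, LEFT,
                                         cfg.ttls, cfg)
            q70, _ = redelineate_wide(stack.coeff(i, 70),
                                      cands.groups[i][j], LEFT, cfg)
            truth = case.truth.onset[i, k]
            errs30.append(abs(q30 - truth))
            errs70.append(abs(q70 - truth))
        assert np.mean(errs70) < np.mean(errs30)


class TestSlopeAdjust:
    def test_flat_baseline_leaves_fiducial(self, cfg):
        f = np.zeros(1000)
        assert v.adjust_by_slope(f, 500, LEFT, cfg) == 500

    def test_uniform_steep_ramp_falls_back(self, cfg):
        f = 20.0 * np.arange(1000)
        assert v.adjust_by_slope(f, 500, LEFT, cfg) == 500 - cfg.start

    def test_boundary_between_flat_and_steep(self, cfg):
        # flat until fid-10, then rising at 30 per sample into the QRS
        f = np.zeros(1000, dtype=float)
        f[490:] = 30.0 * np.arange(510)
        got = v.adjust_by_slope(f, 500, LEFT, cfg)
        assert abs(got - 490) <= cfg.delta


class TestAlignment:
    @pytest.mark.parametrize("vals,expected", [
        ((500, 505, 610), (500, 505, 503)),   # farthest moved to mean
        ((500, 505, 560), (500, 505, 560)),   # spread below TTBS
        ((500, 500, 500), (500, 500, 500)),
    ])
    def test_rule(self, vals, expected):
        np.testing.assert_array_equal(v.align_across_leads(vals, 80),
                                      expected)

    def test_post_alignment_spread_bounded(self, noisy_suite, cfg):
        for case in noisy_suite[:6]:
            fid = case.result.fiducials
            for mat in (fid.q, fid.s):
                spread = mat.max(axis=0) - mat.min(axis=0)
                assert np.all(spread <= cfg.ttbs)


class TestOrderingInvariants:
    def test_onset_peak_end_ordering(self, noisy_suite):
        for case in noisy_suite:
            fid = case.result.fiducials
            assert np.all(fid.q < fid.r)
            assert np.all(fid.r < fid.s)

    def test_widening_never_delays_onset(self):
        """Detected onset moves monotonically earlier as the QRS widens."""
        onsets = []
        for sigma in (6, 8, 10, 12, 14, 16, 18, 20):
            waves = dict(v.preset("hc").waves)
            waves["R"] = v.WaveAtom(2200.0, 0.0, float(sigma))
            spec = v.SynthSpec(duration_s=10.0, waves=waves, seed=2)
            rec, _ = v.generate(spec)
            res = v.run_pipeline(rec, notch_enabled=False)
            fid = res.fiducials
            onsets.append(int(fid.q[0, 2] - fid.r[0, 2]))
        assert np.all(np.diff(onsets) <= 0)
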