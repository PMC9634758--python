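"""CWT engine: oracle equivalence, symmetry, scalogram, scale mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vcgdelin as v
from vcgdelin.wavelet import _tabulated_psi, spectral_peak_frequency

SCALES = (10, 30, 50, 70, 120)


def riemann_cwt(signal, a):
    """Direct evaluation of the CWT sum at every translation (oracle)."""
    psi, x = _tabulated_psi("bior2.2", 10)
    n = signal.size
    t = np.arange(n)
    out = np.empty(n)
    for b in range(n):
        out[b] = (signal * np.interp((t - b) / a, x, psi,
                                     left=0.0, right=0.0)).sum()
    return out / np.sqrt(a)


class TestCwt:
    def test_zero_signal(self):
        assert not np.any(v.cwt(np.zeros(300), SCALES))

    def test_linearity_in_signal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        np.testing.assert_allclose(v.cwt(3.5 * x, [30]),
                                   3.5 * v.cwt(x, [30]), rtol=1e-12)

    @pytest.mark.parametrize("a", SCALES)
    def test_matches_direct_riemann_sum(self, a):
        rng = np.random.default_rng(42)
        x = rng.normal(size=400)
        got = v.cwt(x, [a])[0]
        want = riemann_cwt(x, a)
        rel = np.abs(got - want).max() / np.abs(want).max()
        assert rel < 1e-6

    def test_shift_equivariance_away_from_edges(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=1200)
        shift = 100
        w = v.cwt(x, [30])[0]
        ws = v.cwt(np.roll(x, shift), [30])[0]
        margin = 30 * 3 + shift
        np.testing.assert_allclose(ws[margin:-margin],
                                   np.roll(w, shift)[margin:-margin],
                                   atol=1e-9 * np.abs(w).max())

    def test_symmetric_pulse_gives_symmetric_coefficients(self):
        n, b0 = 801, 400
        x = np.exp(-0.5 * ((np.arange(n) - b0) / 20.0) ** 2)
        w = v.cwt(x, [30])[0]
        np.testing.assert_allclose(w[b0 + 1:], w[b0 - 1::-1][:n - b0 - 1],
                                   atol=1e-9 * np.abs(w).max())

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty scale"):
            v.cwt(np.ones(100), [])
        with pytest.raises(ValueError, match="non-finite"):
            v.cwt(np.array([1.0, np.nan, 2.0]), [10])
        with pytest.raises(ValueError, match="positive"):
            v.cwt(np.ones(100), [-3])


class TestCentralFrequency:
    def test_bior22_conventional_value(self):
        assert v.central_frequency("bior2.2") == pytest.approx(1.0008,
                                                               abs=0.01)

    def test_windowed_cosine_recovers_frequency(self):
        x = np.linspace(0.0, 5.0, 4096)
        y = np.cos(2 * np.pi * 2.0 * x)
        assert spectral_peak_frequency(y, x) == pytest.approx(2.0, abs=0.11)

    def test_time_axis_doubling_halves_result(self):
        x = np.linspace(0.0, 5.0, 4096)
        y = np.cos(2 * np.pi * 2.0 * x)
        f1 = spectral_peak_frequency(y, x)
        f2 = spectral_peak_frequency(y, 2 * x)
        assert f2 == pytest.approx(f1 / 2, rel=1e-9)


class TestPseudofrequency:
    @pytest.mark.parametrize("a,printed", [(10, 100.0), (30, 33.4),
                                           (50, 20.0), (70, 14.3),
                                           (120, 8.3)])
    def test_published_scale_mapping(self, a, printed):
        fa = v.pseudofrequency(a, fcentral=1.0008, delta=0.001)
        decimals = 1 if printed != int(printed) or printed < 100 else 0
        assert round(fa, 1 if a > 10 else 0) == pytest.approx(printed)

    def test_unit_scale(self):
        assert v.pseudofrequency(1, fcentral=1.0008, delta=0.001) \
            == pytest.approx(1000.8)

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            v.pseudofrequency(0.0, fcentral=1.0, delta=0.001)


class TestScalogram:
    def test_single_nonzero_cell(self):
        c = np.zeros((2, 5))
        c[1, 3] = 7.0
        ep = v.scalogram_energy(c)
        assert ep[1, 3] == 100.0 and ep.sum() == 100.0

    def test_two_equal_cells(self):
        c = np.zeros((1, 4))
        c[0, 0], c[0, 2] = 3.0, -3.0
        ep = v.scalogram_energy(c)
        assert ep[0, 0] == ep[0, 2] == 50.0

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero energy"):
            v.scalogram_energy(np.zeros((3, 10)))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_cells_sum_to_hundred(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.normal(size=(5, 200)) * rng.lognormal(0, 3)
        assert v.scalogram_energy(c).sum() == pytest.approx(100.0,
                                                            abs=1e-9)
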