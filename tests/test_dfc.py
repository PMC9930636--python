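"""Phase extraction and dFC estimators against closed forms and oracles."""

import numpy as np
import pytest

from tempostab import (
    BoldTimeSeries,
    hilbert_phase,
    phase_coherence_dfc,
    sliding_window_dfc,
)
from tempostab.dfc import PhaseSeries


def _analytic_phase_oracle(x):
    """Analytic-signal phase by zeroing negative frequencies in the DFT."""
    n = len(x)
    spec = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    return np.angle(np.fft.ifft(spec * h))


class TestHilbertPhase:
    def test_cosine_phase_advances_linearly(self):
        # cos(2 pi 0.05 t), TR = 2 s: phase increment 2 pi * 0.05 * 2 per sample
        tr, f, t = 2.0, 0.05, 200
        sig = np.cos(2 * np.pi * f * tr * np.arange(t))
        ts = BoldTimeSeries(np.vstack([sig, np.roll(sig, 1)]), tr_seconds=tr)
        ph = hilbert_phase(ts).phases[0]
        inc = np.diff(np.unwrap(ph))[20:-20]
        np.testing.assert_allclose(inc, 2 * np.pi * f * tr, atol=1e-6)

    def test_quadrature_pair_lags_by_half_pi(self):
        tr, f, t = 1.0, 0.1, 250  # exactly 25 cycles: no spectral leakage
        arg = 2 * np.pi * f * tr * np.arange(t)
        ts = BoldTimeSeries(np.vstack([np.cos(arg), np.sin(arg)]), tr_seconds=tr)
        ph = hilbert_phase(ts).phases
        lag = np.angle(np.exp(1j * (ph[0] - ph[1])))[20:-20]
        np.testing.assert_allclose(lag, np.pi / 2, atol=1e-6)

    def test_matches_frequency_domain_oracle(self, rng):
        x = rng.normal(size=(4, 120))
        ts = BoldTimeSeries(x, tr_seconds=2.0)
        got = hilbert_phase(ts).phases
        for r in range(4):
            want = _analytic_phase_oracle(x[r] - x[r].mean())
            np.testing.assert_allclose(got[r], want, atol=1e-10)

    def test_phases_in_half_open_interval(self, rng):
        ts = BoldTimeSeries(rng.normal(size=(5, 64)), tr_seconds=2.0)
        ph = hilbert_phase(ts).phases
        assert np.all(ph > -np.pi) and np.all(ph <= np.pi)

    def test_constant_region_rejected(self):
        x = np.vstack([np.ones(32), np.sin(np.arange(32))])
        ts = BoldTimeSeries(x, tr_seconds=2.0)
        with pytest.raises(ValueError, match="ROI001"):
            hilbert_phase(ts)

    def test_bandpass_edges_validated(self, rng):
        ts = BoldTimeSeries(rng.normal(size=(3, 64)), tr_seconds=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            hilbert_phase(ts, bandpass=(0.01, 0.3))  # Nyquist is 0.25 Hz
        hilbert_phase(ts, bandpass=(0.01, 0.2))  # valid band passes

    def test_edge_trim_shortens_series(self, rng):
        ts = BoldTimeSeries(rng.normal(size=(3, 64)), tr_seconds=2.0)
        assert hilbert_phase(ts, edge_trim=5).n_timepoints == 54


class TestPhaseCoherence:
    def test_unit_diagonal_everywhere(self, rng):
        ph = PhaseSeries(rng.uniform(-np.pi + 1e-6, np.pi, size=(6, 30)), 2.0)
        dfc = phase_coherence_dfc(ph)
        diag = dfc.values[np.arange(6), np.arange(6), :]
        assert np.all(diag == 1.0)

    def test_antiphase_gives_minus_one(self):
        theta = np.zeros((2, 10))
        theta[1, :] = np.pi
        dfc = phase_coherence_dfc(PhaseSeries(theta, 2.0))
        np.testing.assert_allclose(dfc.values[0, 1, :], -1.0, atol=1e-12)

    def test_scalar_value_is_cosine_of_difference(self):
        theta = np.zeros((2, 10))
        theta[0, 3], theta[1, 3] = 0.3, 1.0
        dfc = phase_coherence_dfc(PhaseSeries(theta, 2.0))
        np.testing.assert_allclose(dfc.values[0, 1, 3], np.cos(-0.7), atol=1e-12)

    def test_symmetry_and_range(self, rng):
        ph = PhaseSeries(rng.uniform(-np.pi + 1e-6, np.pi, size=(8, 40)), 2.0)
        v = phase_coherence_dfc(ph).values
        np.testing.assert_allclose(v, np.swapaxes(v, 0, 1), atol=1e-14)
        assert v.min() >= -1.0 and v.max() <= 1.0

    def test_each_slice_is_rank_two(self, rng):
        """cos(a-b) slices are cc^T + ss^T: the third eigenvalue vanishes."""
        ph = PhaseSeries(rng.uniform(-np.pi + 1e-6, np.pi, size=(10, 25)), 2.0)
        v = phase_coherence_dfc(ph).values
        for t in range(25):
            lam = np.sort(np.abs(np.linalg.eigvalsh(v[:, :, t])))[::-1]
            assert lam[2] <= 1e-8 * lam[0]

    def test_amplitude_scaling_invariance(self, rng):
        x = rng.normal(size=(5, 80))
        ts = BoldTimeSeries(x, tr_seconds=2.0)
        scaled = BoldTimeSeries(x * rng.uniform(0.5, 20, size=(5, 1)), tr_seconds=2.0)
        a = phase_coherence_dfc(hilbert_phase(ts)).values
        b = phase_coherence_dfc(hilbert_phase(scaled)).values
        np.testing.assert_allclose(a, b, atol=1e-10)


def _weighted_corr_oracle(seg, w):
    """Longhand weighted Pearson correlation of rows of seg."""
    n = seg.shape[0]
    w = w / w.sum()
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            mi = np.sum(w * seg[i])
            mj = np.sum(w * seg[j])
            cij = np.sum(w * (seg[i] - mi) * (seg[j] - mj))
            cii = np.sum(w * (seg[i] - mi) ** 2)
            cjj = np.sum(w * (seg[j] - mj) ** 2)
            out[i, j] = cij / np.sqrt(cii * cjj)
    return out


class TestSlidingWindow:
    def test_identical_regions_correlate_fully(self, rng):
        base = rng.normal(size=60)
        ts = BoldTimeSeries(np.vstack([base, base, rng.normal(size=60)]), 2.0)
        v = sliding_window_dfc(ts, window_length=20).values
        np.testing.assert_allclose(v[0, 1, :], 1.0, atol=1e-12)

    def test_negated_region_anticorrelates(self, rng):
        base = rng.normal(size=60)
        ts = BoldTimeSeries(np.vstack([base, -base, rng.normal(size=60)]), 2.0)
        v = sliding_window_dfc(ts, window_length=20).values
        np.testing.assert_allclose(v[0, 1, :], -1.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=(5, 60))
        ts = BoldTimeSeries(x, tr_seconds=2.0)
        dfc = sliding_window_dfc(ts, window_length=20)
        assert dfc.n_slices == 3
        from tempostab.dfc import _gaussian_taper

        w = _gaussian_taper(20)
        for i in range(3):
            want = _weighted_corr_oracle(x[:, 20 * i : 20 * (i + 1)], w)
            np.testing.assert_allclose(dfc.values[:, :, i], want, atol=1e-10)

    def test_window_validation(self, rng):
        ts = BoldTimeSeries(rng.normal(size=(3, 60)), 2.0)
        with pytest.raises(ValueError, match=">= 4"):
            sliding_window_dfc(ts, window_length=3)
        with pytest.raises(ValueError, match="2 windows"):
            sliding_window_dfc(ts, window_length=40)
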