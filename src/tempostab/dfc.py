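"""Instantaneous phase-coherence dFC and the windowed-correlation alternative.

The primary estimator is window-free: each region's BOLD series is turned
into an analytic signal z(t) = s(t) + j·H[s(t)] via the Hilbert transform,
its angle gives the instantaneous phase theta(n, t), and the connectivity of
regions n and p at time t is the phase coherence

    dFC(n, p, t) = cos(theta(n, t) - theta(p, t)).

Because cos(a - b) = cos a cos b + sin a sin b, every phase-coherence slice
equals c c^T + s s^T with c = cos(theta(:, t)), s = sin(theta(:, t)); each
slice therefore has rank at most 2, which is what makes a k=3 dominant
subspace capture essentially all of its variance downstream.

A nonoverlapping Gaussian-tapered windowed Pearson correlation is provided
as the conventional sliding-window reference estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import BoldTimeSeries

__all__ = [
    "PhaseSeries",
    "DfcTensor",
    "hilbert_phase",
    "phase_coherence_dfc",
    "sliding_window_dfc",
]


@dataclass
class PhaseSeries:
    """Instantaneous phases, radians in (-pi, pi], one row per region."""

    phases: np.ndarray
    tr_seconds: float
    source: BoldTimeSeries | None = None

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases contain non-finite entries")
        if np.any(self.phases > np.pi) or np.any(self.phases <= -np.pi):
            raise ValueError("phases must lie in (-pi, pi]")

    @property
    def n_regions(self) -> int:
        return self.phases.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.phases.shape[1]


@dataclass
class DfcTensor:
    """Time-resolved connectivity, one symmetric N x N slice per timepoint.

    ``values`` has shape (N, N, T'). For the phase-coherence estimator
    T' equals the input length and every slice has a unit diagonal; for
    the windowed estimator T' = floor(T / window_length).
    """

    values: np.ndarray
    estimator: str
    tr_seconds: float
    window_length: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"expected (N, N, T') array, got {self.values.shape}")
        if self.estimator not in ("phase_coherence", "sliding_window"):
            raise ValueError(f"unknown estimator {self.estimator!r}")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_slices(self) -> int:
        return self.values.shape[2]

    def slice(self, t: int) -> np.ndarray:
        return self.values[:, :, t]


def hilbert_phase(
    ts: BoldTimeSeries,
    detrend: bool = False,
    bandpass: tuple[float, float] | None = None,
    edge_trim: int = 0,
) -> PhaseSeries:
    """Instantaneous phase of each region via the analytic signal.

    The per-region temporal mean is always removed (the arctan phase of the
    analytic signal presumes a zero-mean oscillation); ``detrend`` removes a
    linear trend as well. ``bandpass`` optionally applies a zero-phase
    second-order Butterworth filter with the given (low, high) corner
    frequencies in Hz before the transform; the default is no filtering.
    ``edge_trim`` drops that many samples at each end after the transform —
    the discrete analytic signal is distorted near the series edges — and
    defaults to 0 (all timepoints kept).
    """
    x = np.asarray(ts.values, dtype=float)
    if detrend:
        x = sps.detrend(x, axis=1, type="linear")
    x = x - x.mean(axis=1, keepdims=True)
    if bandpass is not None:
        low, high = bandpass
        nyq = 0.5 * ts.sampling_rate_hz
        if not (0.0 < low < high < nyq):
            raise ValueError(
                f"bandpass edges must satisfy 0 < low < high < Nyquist "
                f"({nyq:.4g} Hz); got ({low}, {high})"
            )
        sos = sps.butter(2, [low, high], btype="bandpass", fs=ts.sampling_rate_hz, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1)
        x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(
            f"region {ts.region_labels[bad]!r} (index {bad + 1}) is constant "
            "after preprocessing; cannot define a phase"
        )
    analytic = sps.hilbert(x, axis=1)
    phases = np.angle(analytic)
    # np.angle returns [-pi, pi]; fold the closed lower edge onto +pi
    phases[phases <= -np.pi] = np.pi
    if edge_trim:
        if 2 * edge_trim >= phases.shape[1] - 2:
            raise ValueError(
                f"edge_trim={edge_trim} leaves fewer than 2 timepoints"
            )
        phases = phases[:, edge_trim:-edge_trim]
    return PhaseSeries(phases=phases, tr_seconds=ts.tr_seconds, source=ts)


def phase_coherence_dfc(phases: PhaseSeries) -> DfcTensor:
    """Assemble the phase-coherence tensor cos(theta_n - theta_p) per timepoint."""
    theta = phases.phases
    c = np.cos(theta)  # (N, T)
    s = np.sin(theta)
    # cos(theta_n - theta_p) = c_n c_p + s_n s_p, all t at once
    values = np.einsum("nt,pt->npt", c, c) + np.einsum("nt,pt->npt", s, s)
    n = values.shape[0]
    values[np.arange(n), np.arange(n), :] = 1.0
    np.clip(values, -1.0, 1.0, out=values)
    return DfcTensor(values=values, estimator="phase_coherence", tr_seconds=phases.tr_seconds)


def _gaussian_taper(window_length: int) -> np.ndarray:
    # sigma = L/4, centered in the window, truncated to the window
    center = (window_length - 1) / 2.0
    sigma = window_length / 4.0
    t = np.arange(window_length)
    w = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return w / w.sum()


def sliding_window_dfc(ts: BoldTimeSeries, window_length: int = 20) -> DfcTensor:
    """Nonoverlapping Gaussian-tapered windowed Pearson correlation.

    The series is tiled into floor(T / L) consecutive windows; within each,
    correlations are computed with Gaussian weights (sigma = L/4) centered in
    the window. Used as a reliability check against the phase-coherence path.
    """
    if window_length < 4:
        raise ValueError(
            f"window_length must be >= 4 for a stable correlation, got {window_length}"
        )
    n, t = ts.values.shape
    if t < 2 * window_length:
        raise ValueError(
            f"need at least 2 windows: T={t} < 2 x window_length={window_length}"
        )
    n_windows = t // window_length
    w = _gaussian_taper(window_length)
    out = np.empty((n, n, n_windows))
    for i in range(n_windows):
        seg = ts.values[:, i * window_length : (i + 1) * window_length]
        mu = seg @ w
        dev = seg - mu[:, None]
        cov = (dev * w) @ dev.T
        sd = np.sqrt(np.diag(cov))
        if np.any(sd == 0):
            bad = int(np.argmax(sd == 0))
            raise ValueError(
                f"region {ts.region_labels[bad]!r} constant within window {i + 1}"
            )
        corr = cov / np.outer(sd, sd)
        np.clip(corr, -1.0, 1.0, out=corr)
        np.fill_diagonal(corr, 1.0)
        out[:, :, i] = corr
    return DfcTensor(
        values=out,
        estimator="sliding_window",
        tr_seconds=ts.tr_seconds,
        window_length=window_length,
    )
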