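"""Model/Results front end for the temporal-stability analysis.

`TemporalStabilityModel` holds one subject's parcellated BOLD series plus
the estimator configuration; `fit()` runs phases -> dFC -> dominant
subspaces -> stability matrices -> entropy (and optionally the AR order
selection of the stability time course) and returns a
`TemporalStabilityResults` carrying every intermediate along with a
`summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ar as ar_mod
from .complexity import EntropyResult, stability_entropy
from .dfc import DfcTensor, PhaseSeries, hilbert_phase, phase_coherence_dfc, sliding_window_dfc
from .io import BoldTimeSeries, read_timeseries
from .stability import (
    StabilityMatrix,
    angle_stability_matrix,
    mahalanobis_stability_matrix,
)
from .subspace import DominantSubspace, subspace_trajectory

__all__ = ["TemporalStabilityModel", "TemporalStabilityResults"]


class TemporalStabilityModel:
    """Temporal-stability analysis of one parcellated BOLD run.

    Parameters
    ----------
    ts : BoldTimeSeries
        Regions x time input signal.
    estimator : {"phase_coherence", "sliding_window"}
        Instantaneous phase-coherence dFC (default) or the nonoverlapping
        Gaussian-tapered windowed correlation.
    window_length : int, optional
        Window length in samples for the windowed estimator.
    k : int
        Dominant-subspace dimension (default 3; for phase-coherence input
        the slices are rank-2, so k=3 captures all variance).
    detrend, bandpass
        Preprocessing options forwarded to the phase extraction.
    scaling : {"sqrt_eigenvalue", "unit"}
        Eigenvector scaling of the dominant components.

    Examples
    --------
    >>> from tempostab import simulate
    >>> spec = simulate.RegimeSpec.random(20, dwell_mean=10,
    ...                                   rng=np.random.default_rng(0))
    >>> ts, _ = simulate.generate_regime_bold(spec, n_timepoints=120, seed=0)
    >>> res = TemporalStabilityModel(ts).fit()
    >>> 0 <= res.entropy["angle"].entropy_bits <= 8
    True
    """

    def __init__(
        self,
        ts: BoldTimeSeries,
        estimator: str = "phase_coherence",
        window_length: int | None = None,
        k: int = 3,
        detrend: bool = False,
        bandpass: tuple[float, float] | None = None,
        edge_trim: int = 0,
        scaling: str = "sqrt_eigenvalue",
    ) -> None:
        if estimator not in ("phase_coherence", "sliding_window"):
            raise ValueError(f"unknown estimator {estimator!r}")
        if estimator == "sliding_window" and not window_length:
            raise ValueError("sliding_window estimator requires window_length")
        self.ts = ts
        self.estimator = estimator
        self.window_length = window_length
        self.k = k
        self.detrend = detrend
        self.bandpass = bandpass
        self.edge_trim = edge_trim
        self.scaling = scaling

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        layout: str = "regions_by_time",
        tr_seconds: float = 2.0,
        **kwargs,
    ) -> "TemporalStabilityModel":
        return cls(read_timeseries(path, layout=layout, tr_seconds=tr_seconds), **kwargs)

    def fit(
        self,
        metrics: tuple[str, ...] | list[str] = ("angle",),
        mahalanobis_mode: str = "rowpair",
        epsilon_scale: float = 1e-8,
        bins: int = 256,
        compute_ar: bool = False,
        ar_max_order: int = 20,
        ar_lag: int = 1,
        ar_rule: str = "first_local_min",
    ) -> "TemporalStabilityResults":
        for m in metrics:
            if m not in ("angle", "mahalanobis"):
                raise ValueError(f"unknown metric {m!r}")
        phases = None
        if self.estimator == "phase_coherence":
            phases = hilbert_phase(
                self.ts, detrend=self.detrend, bandpass=self.bandpass,
                edge_trim=self.edge_trim,
            )
            dfc = phase_coherence_dfc(phases)
        else:
            dfc = sliding_window_dfc(self.ts, window_length=self.window_length)
        trajectory = subspace_trajectory(dfc, k=self.k, scaling=self.scaling)
        variance_fractions = np.array([d.variance_fraction for d in trajectory])
        stability: dict[str, StabilityMatrix] = {}
        entropy: dict[str, EntropyResult] = {}
        timecourse = {}
        ar_selection = {}
        for m in metrics:
            if m == "angle":
                mat = angle_stability_matrix(trajectory, tr_seconds=self.ts.tr_seconds)
            else:
                mat = mahalanobis_stability_matrix(
                    trajectory, mode=mahalanobis_mode, epsilon_scale=epsilon_scale,
                    tr_seconds=self.ts.tr_seconds,
                )
            stability[m] = mat
            entropy[m] = stability_entropy(mat, bins=bins)
            tc = ar_mod.stability_timecourse(mat, lag=ar_lag)
            timecourse[m] = tc
            if compute_ar:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")  # max_order capping on short runs
                    ar_selection[m] = ar_mod.select_order(
                        tc, max_order=ar_max_order, rule=ar_rule
                    )
        return TemporalStabilityResults(
            model=self,
            phases=phases,
            dfc=dfc,
            trajectory=trajectory,
            variance_fractions=variance_fractions,
            stability=stability,
            entropy=entropy,
            timecourse=timecourse,
            ar_selection=ar_selection,
        )


@dataclass
class TemporalStabilityResults:
    """Fitted temporal-stability quantities for one run."""

    model: TemporalStabilityModel
    phases: PhaseSeries | None
    dfc: DfcTensor
    trajectory: list[DominantSubspace]
    variance_fractions: np.ndarray
    stability: dict[str, StabilityMatrix]
    entropy: dict[str, EntropyResult]
    timecourse: dict = field(default_factory=dict)
    ar_selection: dict = field(default_factory=dict)

    def summary(self) -> str:
        ts = self.model.ts
        lines = [
            "Temporal Stability Results",
            "=" * 54,
            f"subject:            {ts.subject_id}  ({ts.condition})",
            f"regions x time:     {ts.n_regions} x {ts.n_timepoints}   TR = {ts.tr_seconds:g} s",
            f"estimator:          {self.dfc.estimator}"
            + (f" (window {self.dfc.window_length})" if self.dfc.window_length else ""),
            f"subspace dimension: k = {self.model.k}",
            f"variance fraction:  min {self.variance_fractions.min():.6f}, "
            f"mean {self.variance_fractions.mean():.6f}",
            "-" * 54,
        ]
        for m, mat in self.stability.items():
            v = mat.values
            off = v[~np.eye(v.shape[0], dtype=bool)]
            lines.append(
                f"{m:>12s}: range [{off.min():.4f}, {off.max():.4f}], "
                f"median {np.median(off):.4f}"
            )
            lines.append(
                f"{'':>12s}  entropy = {self.entropy[m].entropy_bits:.4f} bits "
                f"({self.entropy[m].range_policy}, {self.entropy[m].bins} bins)"
            )
            if m in self.ar_selection:
                sel = self.ar_selection[m]
                tag = " (global-min fallback)" if sel.used_fallback else ""
                lines.append(
                    f"{'':>12s}  AR order (first local AIC min) = "
                    f"{sel.selected_order}{tag}"
                )
        return "\n".join(lines)

    def plot_stability(self, metric: str = "angle", ax=None):
        """Heat map of the T' x T' stability matrix."""
        import matplotlib.pyplot as plt

        mat = self.stability[metric]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        vmax = np.pi / 2 if metric == "angle" else None
        im = ax.imshow(mat.values, origin="lower", cmap="viridis", vmin=0, vmax=vmax)
        ax.set_xlabel("timepoint")
        ax.set_ylabel("timepoint")
        ax.set_title(f"{metric} temporal stability ({self.model.ts.subject_id})")
        ax.figure.colorbar(im, ax=ax, label=metric)
        return ax

    def plot_aic(self, metric: str = "angle", ax=None):
        """AIC curve over candidate AR orders with the selected order marked."""
        import matplotlib.pyplot as plt

        if metric not in self.ar_selection:
            raise ValueError(f"AR selection was not computed for metric {metric!r}")
        sel = self.ar_selection[metric]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        ax.plot(np.arange(len(sel.aic_curve)), sel.aic_curve, marker="o", ms=3)
        ax.axvline(sel.selected_order, color="crimson", ls="--",
                   label=f"selected order {sel.selected_order}")
        ax.set_xlabel(r"AR order $\rho$")
        ax.set_ylabel("AIC")
        ax.legend()
        return ax
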