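"""Autoregressive characterization of the stability time course.

The lag-L superdiagonal of a stability matrix gives the distance between
dominant subspaces L steps apart — by default the successive-timepoint
series phi(t) or M(t). That series is modeled as an AR(rho) process

    X_t = c + sum_{i=1..rho} phi_i X_{t-i} + eps_t,

estimated by conditional least squares. To keep AIC values comparable, all
candidate orders are fitted on the common sample that conditions out the
first ``max_order`` points. The Gaussian log-likelihood is computed from
the residual mean squared error and AIC(rho) = -2 L + 2 rho; the selected
order is the first local minimum of the AIC curve (falling back to the
global minimum when the curve has none). Order 0 is white noise; order 1 a
Markov process; order > 1 indicates longer temporal memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stability import StabilityMatrix

__all__ = [
    "StabilityTimecourse",
    "ARModelFit",
    "OrderSelection",
    "stability_timecourse",
    "fit_ar",
    "select_order",
]


@dataclass
class StabilityTimecourse:
    """Distance between subspaces ``lag`` steps apart, as a function of time."""

    values: np.ndarray
    metric: str
    lag: int


@dataclass
class ARModelFit:
    order: int
    constant: float
    coefficients: np.ndarray
    residual_variance: float
    loglik: float
    aic: float
    n_effective: int


@dataclass
class OrderSelection:
    aic_curve: np.ndarray  # index rho = 0 .. max_order
    selected_order: int
    rule: str
    used_fallback: bool = False
    fits: list[ARModelFit] = field(default_factory=list)

    @property
    def best_fit(self) -> ARModelFit:
        return self.fits[self.selected_order]


def stability_timecourse(mat: StabilityMatrix, lag: int = 1) -> StabilityTimecourse:
    """Extract the lag-offset superdiagonal of a stability matrix."""
    t = mat.n_timepoints
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    if lag >= t:
        raise ValueError(f"lag {lag} must be smaller than T'={t}")
    return StabilityTimecourse(
        values=np.diagonal(mat.values, offset=lag).copy(), metric=mat.metric, lag=lag
    )


def _lag_matrix(x: np.ndarray, order: int, hold_out: int) -> tuple[np.ndarray, np.ndarray]:
    y = x[hold_out:]
    cols = [np.ones_like(y)]
    for i in range(1, order + 1):
        cols.append(x[hold_out - i : len(x) - i])
    return np.column_stack(cols), y


def fit_ar(
    series: np.ndarray | StabilityTimecourse,
    order: int,
    hold_out: int | None = None,
) -> ARModelFit:
    """Conditional least-squares AR(order) fit with Gaussian likelihood.

    ``hold_out`` fixes how many initial points are conditioned out (defaults
    to ``order``); passing a common value across orders makes their AIC
    values directly comparable.
    """
    x = series.values if isinstance(series, StabilityTimecourse) else np.asarray(series, float)
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    hold_out = order if hold_out is None else hold_out
    if hold_out < order:
        raise ValueError(f"hold_out ({hold_out}) must be >= order ({order})")
    if len(x) < order + 10:
        raise ValueError(
            f"series of length {len(x)} too short for AR({order}); need >= {order + 10}"
        )
    design, y = _lag_matrix(x, order, hold_out)
    n_eff = len(y)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError(
            f"lag matrix is rank-deficient at order {order}; "
            "the series may be too regular — try a lower order"
        )
    resid = y - design @ coef
    sigma2 = float(resid @ resid) / n_eff
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    loglik = -0.5 * n_eff * (np.log(2 * np.pi * sigma2) + 1.0)
    aic = -2.0 * loglik + 2.0 * order
    return ARModelFit(
        order=order,
        constant=float(coef[0]),
        coefficients=coef[1:].copy(),
        residual_variance=sigma2,
        loglik=float(loglik),
        aic=float(aic),
        n_effective=n_eff,
    )


def select_order(
    series: np.ndarray | StabilityTimecourse,
    max_order: int = 100,
    rule: str = "first_local_min",
) -> OrderSelection:
    """AIC curve over orders 0..max_order and the selected order.

    ``first_local_min`` picks the smallest rho with AIC(rho) < AIC(rho-1)
    and AIC(rho) <= AIC(rho+1) (rho = 0 qualifies when AIC(0) <= AIC(1));
    if the curve has no local minimum it falls back to the global minimum
    and flags ``used_fallback``. ``max_order`` is capped at a third of the
    series length to avoid degenerate fits on short series.
    """
    if rule not in ("first_local_min", "global_min"):
        raise ValueError(f"unknown rule {rule!r}")
    x = series.values if isinstance(series, StabilityTimecourse) else np.asarray(series, float)
    n = len(x)
    cap = max(min(max_order, n // 3, n - 11), 0)
    if cap < max_order:
        warnings.warn(
            f"max_order capped from {max_order} to {cap} for a series of length {n}",
            stacklevel=2,
        )
    fits = [fit_ar(x, rho, hold_out=cap) for rho in range(cap + 1)]
    aic = np.array([f.aic for f in fits])
    used_fallback = False
    if rule == "global_min" or len(aic) == 1:
        selected = int(np.argmin(aic))
    else:
        selected = -1
        for rho in range(len(aic) - 1):
            left_ok = rho == 0 or aic[rho] < aic[rho - 1]
            right_ok = aic[rho] <= aic[rho + 1]
            if left_ok and right_ok:
                selected = rho
                break
        if selected < 0:
            selected = int(np.argmin(aic))
            used_fallback = True
    return OrderSelection(
        aic_curve=aic, selected_order=selected, rule=rule,
        used_fallback=used_fallback, fits=fits,
    )
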