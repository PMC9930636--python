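"""Scalar summaries of stability matrices: histogram entropy and Frobenius distance.

Entropy follows the image-histogram convention: matrix entries are mapped to
[0, 1], binned into 256 equal-width bins, normalized to a probability vector
p, and summarized as E = -sum p log2 p (bits). Angle matrices use the fixed
theoretical range [0, pi/2] so entropies are comparable across subjects;
Mahalanobis matrices, which have no finite theoretical bound, default to
per-matrix min-max mapping. High entropy means the matrix mixes many
distance levels (short-lived, varied stability patterns); low entropy means
few levels (uniform or strongly block-like stability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stability import StabilityMatrix

__all__ = ["EntropyResult", "FrobeniusResult", "stability_entropy", "frobenius_distance"]


@dataclass
class EntropyResult:
    entropy_bits: float
    histogram: np.ndarray  # normalized, sums to 1
    bins: int
    range_policy: str

    @property
    def max_entropy_bits(self) -> float:
        return float(np.log2(self.bins))


@dataclass
class FrobeniusResult:
    distance: float
    shapes_compared: tuple[int, int]
    truncated_to: int


def stability_entropy(
    mat: StabilityMatrix | np.ndarray,
    bins: int = 256,
    range_policy: str | None = None,
) -> EntropyResult:
    """Shannon entropy (bits) of the binned entries of a stability matrix.

    ``range_policy='fixed_theoretical'`` divides angle entries by pi/2;
    ``'minmax'`` rescales by the observed range. When unspecified, angle
    matrices use the fixed range and Mahalanobis matrices min-max. The full
    matrix, diagonal included, is histogrammed.
    """
    if isinstance(mat, StabilityMatrix):
        values = mat.values
        if range_policy is None:
            range_policy = "fixed_theoretical" if mat.metric == "angle" else "minmax"
        metric = mat.metric
    else:
        values = np.asarray(mat, dtype=float)
        if range_policy is None:
            range_policy = "minmax"
        metric = None
    if range_policy not in ("fixed_theoretical", "minmax"):
        raise ValueError(f"unknown range_policy {range_policy!r}")
    if not np.all(np.isfinite(values)):
        raise ValueError("stability matrix contains non-finite entries")
    flat = values.ravel()
    if range_policy == "fixed_theoretical":
        if metric == "mahalanobis":
            raise ValueError(
                "fixed_theoretical range is undefined for the Mahalanobis "
                "metric (no finite upper bound); use range_policy='minmax'"
            )
        mapped = flat / (np.pi / 2)
    else:
        lo, hi = float(flat.min()), float(flat.max())
        if hi == lo:
            warnings.warn(
                "constant matrix under minmax range: single-bin histogram, entropy 0",
                stacklevel=2,
            )
            p = np.zeros(bins)
            p[0] = 1.0
            return EntropyResult(0.0, p, bins, range_policy)
        mapped = (flat - lo) / (hi - lo)
    counts, _ = np.histogram(np.clip(mapped, 0.0, 1.0), bins=bins, range=(0.0, 1.0))
    p = counts / counts.sum()
    nz = p[p > 0]
    e = float(-np.sum(nz * np.log2(nz)))
    return EntropyResult(e, p, bins, range_policy)


def frobenius_distance(
    a: StabilityMatrix | np.ndarray, b: StabilityMatrix | np.ndarray
) -> FrobeniusResult:
    """Frobenius distance sqrt(sum |a_ij - b_ij|^2) between stability matrices.

    Matrices from conditions of unequal length (e.g. a 261-point rest run vs
    a 193-point movie run) are truncated to the leading common T x T block
    before the elementwise computation; ``truncated_to`` records the size.
    """
    if isinstance(a, StabilityMatrix) and isinstance(b, StabilityMatrix):
        if a.metric != b.metric:
            raise ValueError(
                f"cannot compare stability matrices of different metrics: "
                f"{a.metric} vs {b.metric}"
            )
    av = a.values if isinstance(a, StabilityMatrix) else np.asarray(a, float)
    bv = b.values if isinstance(b, StabilityMatrix) else np.asarray(b, float)
    ta, tb = av.shape[0], bv.shape[0]
    t = min(ta, tb)
    d = av[:t, :t] - bv[:t, :t]
    return FrobeniusResult(
        distance=float(np.sqrt(np.sum(np.abs(d) ** 2))),
        shapes_compared=(ta, tb),
        truncated_to=t,
    )
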