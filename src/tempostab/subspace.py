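"""Per-timepoint eigendecomposition of dFC(t) and the dominant subspace D_t.

Each connectivity slice dFC_t = V S V^T is decomposed into orthonormal
eigenvectors sorted by descending eigenvalue. The dominant subspace keeps
the k leading components; with the default sqrt-eigenvalue scaling,
D_t D_t^T is the best rank-k reconstruction of the slice, so D_t preserves
both the span (for principal angles) and the pattern (for reconstruction).

Phase-coherence slices have rank at most 2, so k = 3 captures the full
variance up to floating point. The third column is then numerically null;
it is retained (the span of the leading eigenvectors is still well defined)
and the affected columns are flagged for downstream covariance handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .dfc import DfcTensor

__all__ = [
    "EigenDecomposition",
    "DominantSubspace",
    "eigendecompose",
    "dominant_subspace",
    "subspace_trajectory",
]

SYMMETRY_TOL = 1e-10
NULL_EIGENVALUE_REL = 1e-12


@dataclass
class EigenDecomposition:
    """Full spectrum of a symmetric matrix, eigenvalues descending."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # orthonormal columns, column i pairs eigenvalues[i]


@dataclass
class DominantSubspace:
    """N x k matrix of scaled leading eigenvectors of one dFC slice.

    ``variance_fraction`` is sum(|lambda_i|, i <= k) / sum(|lambda_i|), the
    share of total (absolute) spectral mass the k leading components carry.
    """

    components: np.ndarray
    eigenvalues_k: np.ndarray
    variance_fraction: float
    k: int
    timepoint: int = 0
    scaling: str = "sqrt_eigenvalue"
    null_columns: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def n_regions(self) -> int:
        return self.components.shape[0]


def eigendecompose(dfc_slice: np.ndarray) -> EigenDecomposition:
    """Eigendecompose a symmetric slice, sorted by descending eigenvalue."""
    a = np.asarray(dfc_slice, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    asym = np.max(np.abs(a - a.T))
    scale = max(np.max(np.abs(a)), 1.0)
    if asym > SYMMETRY_TOL * scale:
        raise ValueError(
            f"matrix is asymmetric beyond tolerance: max |A - A^T| = {asym:.3g}"
        )
    a = 0.5 * (a + a.T)
    w, v = sla.eigh(a)
    order = np.argsort(w)[::-1]
    return EigenDecomposition(eigenvalues=w[order], eigenvectors=v[:, order])


def _fix_signs(v: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return v * signs


def dominant_subspace(
    dfc_slice: np.ndarray,
    k: int = 3,
    scaling: str = "sqrt_eigenvalue",
    timepoint: int = 0,
) -> DominantSubspace:
    """Top-k eigenvector matrix of one slice, sign-fixed and scaled.

    ``scaling='sqrt_eigenvalue'`` multiplies eigenvector i by sqrt(|lambda_i|)
    so that components @ components.T reproduces the best rank-k
    reconstruction; ``scaling='unit'`` keeps unit-norm columns. Both span the
    same subspace.
    """
    if scaling not in ("sqrt_eigenvalue", "unit"):
        raise ValueError(f"unknown scaling {scaling!r}")
    dec = eigendecompose(dfc_slice)
    n = dec.eigenvectors.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    lam = dec.eigenvalues[:k]
    v = _fix_signs(dec.eigenvectors[:, :k].copy())
    total = np.sum(np.abs(dec.eigenvalues))
    frac = float(np.sum(np.abs(lam)) / total) if total > 0 else 1.0
    null_cols = np.abs(lam) < NULL_EIGENVALUE_REL * max(np.abs(lam[0]), 1e-300)
    if scaling == "sqrt_eigenvalue":
        comp = v * np.sqrt(np.abs(lam))[None, :]
    else:
        comp = v
    return DominantSubspace(
        components=comp,
        eigenvalues_k=lam,
        variance_fraction=frac,
        k=k,
        timepoint=timepoint,
        scaling=scaling,
        null_columns=null_cols,
    )


def subspace_trajectory(
    dfc: DfcTensor, k: int = 3, scaling: str = "sqrt_eigenvalue"
) -> list[DominantSubspace]:
    """Dominant subspace of every slice, in temporal order.

    Timepoints are tagged 1-based. Per-timepoint variance fractions are on
    each element for QC (`[d.variance_fraction for d in traj]`).
    """
    return [
        dominant_subspace(dfc.values[:, :, t], k=k, scaling=scaling, timepoint=t + 1)
        for t in range(dfc.n_slices)
    ]
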