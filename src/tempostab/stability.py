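"""Temporal-stability matrices: principal angles and Mahalanobis distances.

Two distances between the dominant subspaces D_a, D_b of different
timepoints:

* Angular distance: the largest principal angle between span(D_a) and
  span(D_b), from the SVD of the cross-Gram matrix Q_a^T Q_b of orthonormal
  bases. Ranges 0 (identical subspaces) to pi/2 (orthogonal).
* Mahalanobis distance: treating the N rows of D (one k-vector per region)
  as a point cloud, either the covariance-normalized distance between
  matched rows of D_a and D_b (``rowpair``) or of each row of D_b from the
  row distribution of D_a (``distribution``). The covariance is estimated
  from the rows of D_a and ridge-regularized, because rank-deficient slices
  (phase coherence is exactly rank 2) make the raw covariance singular.

Assembling either distance over all timepoint pairs gives the T' x T'
temporal-stability matrix whose block structure exposes dwell epochs of the
connectivity pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .subspace import DominantSubspace

__all__ = [
    "StabilityMatrix",
    "SubspacePointCloud",
    "SpatialStabilityProfile",
    "principal_angle",
    "angle_stability_matrix",
    "mahalanobis_profile",
    "mahalanobis_stability_matrix",
    "short_long_range_profiles",
]

DEFAULT_EPSILON = 1e-8


@dataclass
class StabilityMatrix:
    """Symmetric T' x T' matrix of pairwise subspace distances."""

    values: np.ndarray
    metric: str  # "angle" | "mahalanobis"
    tr_seconds: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"expected square matrix, got {self.values.shape}")
        if self.metric not in ("angle", "mahalanobis"):
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def theoretical_range(self) -> tuple[float, float]:
        return (0.0, np.pi / 2) if self.metric == "angle" else (0.0, np.inf)


@dataclass
class SubspacePointCloud:
    """Rows of a dominant subspace seen as N points in R^k."""

    points: np.ndarray
    mean: np.ndarray
    covariance: np.ndarray  # regularized, invertible
    regularization_epsilon: float


@dataclass
class SpatialStabilityProfile:
    """Per-region Mahalanobis distance for one timepoint pair."""

    per_roi_distance: np.ndarray
    timepoint_pair: tuple[int, int]
    mode: str


RANK_RTOL = 1e-6  # sqrt of the 1e-12 eigenvalue-nullity threshold


def _effective_components(d: DominantSubspace | np.ndarray) -> np.ndarray:
    """Component matrix with numerically-null flagged columns removed.

    A rank-deficient slice (phase coherence is exactly rank 2) carries
    arbitrary null-space directions in its trailing eigenvectors; including
    them would randomize the largest principal angle, so they are excluded
    from the span.
    """
    if isinstance(d, DominantSubspace):
        comp = d.components
        if d.null_columns.size and d.null_columns.any() and (~d.null_columns).any():
            comp = comp[:, ~d.null_columns]
        return comp
    return np.asarray(d, dtype=float)


def _orthonormal_basis(components: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the numerically significant column span.

    Singular directions below RANK_RTOL of the leading singular value are
    treated as null (they correspond to eigenvalues below ~1e-12 of the
    leading one in a sqrt-eigenvalue-scaled component matrix).
    """
    u, s, _ = np.linalg.svd(components, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise ValueError("degenerate subspace: all columns numerically zero")
    rank = int(np.sum(s > RANK_RTOL * s[0]))
    if rank == 0:
        raise ValueError("degenerate subspace: all columns numerically zero")
    return u[:, :rank]


def _principal_angles_from_bases(qa: np.ndarray, qb: np.ndarray) -> np.ndarray:
    """All principal angles (ascending, radians) from two orthonormal bases."""
    sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
    # singular values descending, so arccos yields angles ascending
    return np.arccos(np.clip(sv, -1.0, 1.0))


def principal_angle(
    da: DominantSubspace | np.ndarray,
    db: DominantSubspace | np.ndarray,
    which: str = "largest",
) -> float | np.ndarray:
    """Principal angle(s) between two dominant subspaces, in radians.

    Both component matrices are orthonormalized (rank-revealing, so scaling
    and basis choice are irrelevant); the cosines of the principal angles are
    the singular values of the cross-Gram matrix. ``which`` selects the
    ``largest`` (default — the scalar used in the stability matrix),
    ``smallest``, or ``all`` angles (ascending).
    """
    a = _effective_components(da)
    b = _effective_components(db)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"subspaces live in different spaces: {a.shape[0]} vs {b.shape[0]} rows")
    angles = _principal_angles_from_bases(_orthonormal_basis(a), _orthonormal_basis(b))
    if which == "all":
        return angles
    if which == "largest":
        return float(angles[-1])
    if which == "smallest":
        return float(angles[0])
    raise ValueError(f"unknown which={which!r}")


def angle_stability_matrix(
    trajectory: list[DominantSubspace], tr_seconds: float | None = None
) -> StabilityMatrix:
    """T' x T' matrix of largest principal angles between all timepoint pairs."""
    t = len(trajectory)
    if t < 2:
        raise ValueError("need a trajectory of at least 2 subspaces")
    bases = [_orthonormal_basis(_effective_components(d)) for d in trajectory]
    ranks = {b.shape[1] for b in bases}
    out = np.zeros((t, t))
    if len(ranks) == 1:
        # common rank: batch the cross-Gram SVDs
        q = np.stack(bases)  # (T, N, r)
        gram = np.einsum("ank,bnl->abkl", q, q)
        sv = np.linalg.svd(gram, compute_uv=False)  # (T, T, r), descending
        out = np.arccos(np.clip(sv[..., -1], -1.0, 1.0))
    else:
        for i in range(t):
            for j in range(i + 1, t):
                out[i, j] = out[j, i] = _principal_angles_from_bases(bases[i], bases[j])[-1]
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    np.clip(out, 0.0, np.pi / 2, out=out)
    return StabilityMatrix(values=out, metric="angle", tr_seconds=tr_seconds)


def _point_cloud(
    d: DominantSubspace | np.ndarray, epsilon_scale: float
) -> SubspacePointCloud:
    pts = d.components if isinstance(d, DominantSubspace) else np.asarray(d, float)
    mu = pts.mean(axis=0)
    dev = pts - mu
    c = dev.T @ dev / max(pts.shape[0] - 1, 1)
    tr = float(np.trace(c))
    if tr <= 0:
        raise ValueError(
            "covariance is identically zero (all subspace rows identical); "
            "Mahalanobis distance is undefined"
        )
    k = c.shape[0]
    c_reg = c + epsilon_scale * (tr / k) * np.eye(k)
    return SubspacePointCloud(
        points=pts, mean=mu, covariance=c_reg, regularization_epsilon=epsilon_scale
    )


def mahalanobis_profile(
    da: DominantSubspace | np.ndarray,
    db: DominantSubspace | np.ndarray,
    mode: str = "rowpair",
    epsilon_scale: float = DEFAULT_EPSILON,
) -> SpatialStabilityProfile:
    """Per-region Mahalanobis distance between two dominant subspaces.

    The covariance C is estimated from the mean-centered rows of ``da`` and
    regularized as C + eps * tr(C)/k * I. ``rowpair`` measures matched-row
    differences sqrt((d_a,p - d_b,p)^T C^-1 (d_a,p - d_b,p)); ``distribution``
    measures each row of ``db`` against the row distribution of ``da``:
    sqrt((d_b,p - mu_a)^T C^-1 (d_b,p - mu_a)).
    """
    if mode not in ("rowpair", "distribution"):
        raise ValueError(f"unknown mode {mode!r}")
    a = da.components if isinstance(da, DominantSubspace) else np.asarray(da, float)
    b = db.components if isinstance(db, DominantSubspace) else np.asarray(db, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    cloud = _point_cloud(a, epsilon_scale)
    diff = (a - b) if mode == "rowpair" else (b - cloud.mean[None, :])
    cf = sla.cho_factor(cloud.covariance, lower=True)
    sol = sla.cho_solve(cf, diff.T)  # (k, N)
    d2 = np.einsum("nk,kn->n", diff, sol)
    ta = da.timepoint if isinstance(da, DominantSubspace) else 0
    tb = db.timepoint if isinstance(db, DominantSubspace) else 0
    return SpatialStabilityProfile(
        per_roi_distance=np.sqrt(np.maximum(d2, 0.0)),
        timepoint_pair=(ta, tb),
        mode=mode,
    )


def mahalanobis_stability_matrix(
    trajectory: list[DominantSubspace],
    mode: str = "rowpair",
    epsilon_scale: float = DEFAULT_EPSILON,
    tr_seconds: float | None = None,
) -> StabilityMatrix:
    """T' x T' matrix of region-averaged Mahalanobis distances.

    Entry (a, b) is the mean over regions of the per-region profile; because
    the covariance is estimated from one side, the raw quantity is
    asymmetric and the matrix is symmetrized as (M(a,b) + M(b,a)) / 2.
    """
    t = len(trajectory)
    if t < 2:
        raise ValueError("need a trajectory of at least 2 subspaces")
    comps = np.stack([d.components for d in trajectory])  # (T, N, k)
    n, k = comps.shape[1], comps.shape[2]
    mus = comps.mean(axis=1)  # (T, k)
    dev = comps - mus[:, None, :]
    covs = np.einsum("tnk,tnl->tkl", dev, dev) / max(n - 1, 1)
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        bad = int(np.argmax(traces <= 0))
        raise ValueError(
            f"covariance identically zero at timepoint {bad + 1}; "
            "Mahalanobis distance is undefined"
        )
    covs = covs + (epsilon_scale * traces / k)[:, None, None] * np.eye(k)[None]
    inv = np.linalg.inv(covs)  # (T, k, k)
    raw = np.zeros((t, t))
    for a in range(t):
        diff = (comps[a][None] - comps) if mode == "rowpair" else (comps - mus[a][None, None, :])
        # mean over regions of sqrt(diff C_a^-1 diff)
        d2 = np.einsum("bnk,kl,bnl->bn", diff, inv[a], diff)
        raw[a, :] = np.sqrt(np.maximum(d2, 0.0)).mean(axis=1)
    out = 0.5 * (raw + raw.T)
    np.fill_diagonal(out, np.diag(raw) if mode == "distribution" else 0.0)
    if mode == "rowpair":
        np.fill_diagonal(out, 0.0)
    return StabilityMatrix(values=out, metric="mahalanobis", tr_seconds=tr_seconds)


def short_long_range_profiles(
    trajectory: list[DominantSubspace],
    near_pair: tuple[int, int] = (15, 20),
    far_pair: tuple[int, int] = (15, 150),
    mode: str = "rowpair",
    epsilon_scale: float = DEFAULT_EPSILON,
) -> tuple[SpatialStabilityProfile, SpatialStabilityProfile]:
    """Spatial stability profiles at a short and a long temporal separation.

    Timepoints are 1-based. Defaults compare pairs 5 and 135 samples apart,
    probing how per-region stability decays with temporal distance.
    """
    t = len(trajectory)
    profiles = []
    for pair in (near_pair, far_pair):
        for tp in pair:
            if not 1 <= tp <= t:
                raise ValueError(f"timepoint {tp} outside [1, {t}]")
        prof = mahalanobis_profile(
            trajectory[pair[0] - 1], trajectory[pair[1] - 1],
            mode=mode, epsilon_scale=epsilon_scale,
        )
        profiles.append(
            SpatialStabilityProfile(
                per_roi_distance=prof.per_roi_distance, timepoint_pair=pair, mode=mode
            )
        )
    return profiles[0], profiles[1]
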