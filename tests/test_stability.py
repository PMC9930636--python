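"""Principal-angle and Mahalanobis stability against oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import subspace_angles

from tempostab import (
    angle_stability_matrix,
    mahalanobis_profile,
    mahalanobis_stability_matrix,
    principal_angle,
    short_long_range_profiles,
)
from tempostab.subspace import DominantSubspace, dominant_subspace


def _sub(components, timepoint=0):
    components = np.asarray(components, float)
    return DominantSubspace(
        components=components,
        eigenvalues_k=np.ones(components.shape[1]),
        variance_fraction=1.0,
        k=components.shape[1],
        timepoint=timepoint,
        null_columns=np.zeros(components.shape[1], dtype=bool),
    )


def _planted_pair(alpha, dim=6):
    e = np.eye(dim)
    a = e[:, :2]
    b = np.column_stack([e[:, 0], np.cos(alpha) * e[:, 1] + np.sin(alpha) * e[:, 2]])
    return a, b


class TestPrincipalAngle:
    def test_identical_subspaces(self, rng):
        a = rng.normal(size=(8, 3))
        assert principal_angle(a, a) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_spans(self):
        e = np.eye(7)
        assert principal_angle(e[:, :3], e[:, 3:6]) == pytest.approx(np.pi / 2)

    @pytest.mark.parametrize("alpha", [0.0, 0.4, np.pi / 2])
    def test_planted_plane_pair(self, alpha):
        a, b = _planted_pair(alpha)
        assert principal_angle(a, b) == pytest.approx(alpha, abs=1e-12)
        if alpha > 0:
            np.testing.assert_allclose(
                principal_angle(a, b, which="all"), [0.0, alpha], atol=1e-12
            )

    def test_matches_scipy_oracle(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=(2, 9, 3))
            want = np.max(subspace_angles(a, b))
            assert principal_angle(a, b) == pytest.approx(want, abs=1e-10)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_basis_change(self, seed):
        """Right-multiplying by any invertible k x k matrix keeps the span."""
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 7, 3))
        g = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # comfortably invertible
        assert principal_angle(a @ g, b) == pytest.approx(
            principal_angle(a, b), abs=1e-8
        )

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            principal_angle(np.zeros((5, 2)), np.eye(5)[:, :2])


class TestAngleMatrix:
    def test_constant_trajectory_is_zero(self, rng):
        d = _sub(rng.normal(size=(8, 3)))
        mat = angle_stability_matrix([d] * 10)
        # arccos near 1 resolves angles only to ~sqrt(machine eps)
        np.testing.assert_allclose(mat.values, 0.0, atol=1e-7)

    def test_bounds_symmetry_zero_diagonal(self, two_regime_trajectory):
        traj, _ = two_regime_trajectory
        mat = angle_stability_matrix(traj)
        v = mat.values
        np.testing.assert_array_equal(v, v.T)
        np.testing.assert_array_equal(np.diag(v), 0.0)
        assert v.max() <= np.pi / 2 and v.min() >= 0.0

    def test_two_regime_block_structure(self, two_regime_trajectory):
        traj, states = two_regime_trajectory
        v = angle_stability_matrix(traj).values
        same = np.equal.outer(states, states)
        off = ~np.eye(len(states), dtype=bool)
        assert np.median(v[same & off]) < np.median(v[~same])

    def test_matrix_agrees_with_scalar_operation(self, two_regime_trajectory):
        traj, _ = two_regime_trajectory
        v = angle_stability_matrix(traj).values
        for i, j in [(3, 77), (15, 149), (60, 61)]:
            assert v[i, j] == pytest.approx(
                principal_angle(traj[i], traj[j]), abs=1e-10
            )


def _mahal_oracle(da, db, mode="rowpair", eps=1e-8):
    """Longhand oracle: explicit covariance inverse and per-row quadratic form."""
    mu = da.mean(axis=0)
    dev = da - mu
    c = dev.T @ dev / (da.shape[0] - 1)
    c = c + eps * np.trace(c) / c.shape[0] * np.eye(c.shape[0])
    cinv = np.linalg.inv(c)
    out = np.empty(da.shape[0])
    for p in range(da.shape[0]):
        d = (da[p] - db[p]) if mode == "rowpair" else (db[p] - mu)
        out[p] = np.sqrt(d @ cinv @ d)
    return out


class TestMahalanobis:
    def test_identical_rowpair_is_zero(self, rng):
        a = rng.normal(size=(6, 2))
        prof = mahalanobis_profile(_sub(a), _sub(a), mode="rowpair")
        np.testing.assert_allclose(prof.per_roi_distance, 0.0, atol=1e-12)

    def test_whitened_rows_reduce_to_euclidean(self, rng):
        a = rng.normal(size=(12, 3))
        dev = a - a.mean(axis=0)
        c = dev.T @ dev / (len(a) - 1)
        w = np.linalg.inv(np.linalg.cholesky(c)).T
        aw = a.mean(axis=0) + dev @ w  # sample covariance exactly identity
        b = aw + rng.normal(size=aw.shape)
        prof = mahalanobis_profile(aw, b, mode="rowpair")
        np.testing.assert_allclose(
            prof.per_roi_distance, np.linalg.norm(aw - b, axis=1), rtol=1e-6
        )

    @pytest.mark.parametrize("mode", ["rowpair", "distribution"])
    def test_matches_longhand_oracle(self, rng, mode):
        a, b = rng.normal(size=(2, 6, 2))
        prof = mahalanobis_profile(a, b, mode=mode)
        np.testing.assert_allclose(
            prof.per_roi_distance, _mahal_oracle(a, b, mode), rtol=1e-8
        )

    def test_distribution_mode_affine_invariance(self, rng):
        """A common invertible map of both row clouds leaves distances unchanged."""
        from scipy.stats import ortho_group

        a, b = rng.normal(size=(2, 10, 3))
        # well-conditioned map: rotation times anisotropic scaling
        g = ortho_group.rvs(3, random_state=1) @ np.diag([0.5, 1.3, 2.0])
        d0 = mahalanobis_profile(a, b, mode="distribution").per_roi_distance
        d1 = mahalanobis_profile(a @ g, b @ g, mode="distribution").per_roi_distance
        np.testing.assert_allclose(d0, d1, atol=1e-6)

    def test_identical_rows_rejected(self):
        a = np.ones((6, 2))
        with pytest.raises(ValueError, match="identical"):
            mahalanobis_profile(a, a + 1.0)


class TestMahalanobisMatrix:
    def test_constant_trajectory_zero(self, rng):
        d = _sub(rng.normal(size=(8, 3)))
        mat = mahalanobis_stability_matrix([d] * 6, mode="rowpair")
        np.testing.assert_allclose(mat.values, 0.0, atol=1e-10)

    def test_entry_is_symmetrized_profile_mean(self, two_regime_trajectory):
        traj, _ = two_regime_trajectory
        mat = mahalanobis_stability_matrix(traj, mode="rowpair")
        i, j = 15, 150
        ab = mahalanobis_profile(traj[i], traj[j], mode="rowpair").per_roi_distance
        ba = mahalanobis_profile(traj[j], traj[i], mode="rowpair").per_roi_distance
        want = 0.5 * (ab.mean() + ba.mean())
        assert mat.values[i, j] == pytest.approx(want, rel=1e-10)
        np.testing.assert_allclose(mat.values, mat.values.T, atol=1e-12)
        assert mat.values.min() >= 0.0

    def test_two_regime_block_structure(self, two_regime_trajectory):
        traj, states = two_regime_trajectory
        v = mahalanobis_stability_matrix(traj, mode="rowpair").values
        same = np.equal.outer(states, states)
        off = ~np.eye(len(states), dtype=bool)
        assert np.mean(v[same & off]) < np.mean(v[~same])


class TestShortLongRange:
    def test_constant_trajectory_all_zero(self, rng):
        d = _sub(rng.normal(size=(8, 3)))
        near, far = short_long_range_profiles([d] * 160)
        np.testing.assert_allclose(near.per_roi_distance, 0.0, atol=1e-12)
        np.testing.assert_allclose(far.per_roi_distance, 0.0, atol=1e-12)

    def test_default_pairs_probe_5_and_135_offsets(self, two_regime_trajectory):
        traj, _ = two_regime_trajectory
        near, far = short_long_range_profiles(traj)
        assert near.timepoint_pair == (15, 20)
        assert far.timepoint_pair == (15, 150)
        assert far.timepoint_pair[1] - far.timepoint_pair[0] == 135

    def test_far_pair_across_switch_exceeds_near(self):
        # fixed dwell 50: t=15 and t=20 share a regime; t=80 is past a switch.
        # moderate noise so the planted structure dominates eigenvector jitter
        from tempostab import generate_regime_bold, hilbert_phase, phase_coherence_dfc
        from tempostab.simulate import RegimeSpec
        from tempostab.subspace import subspace_trajectory

        spec = RegimeSpec.random(
            20, n_regimes=2, n_communities=3, dwell_mean=50,
            dwell_distribution="fixed", rng=np.random.default_rng(7),
        )
        ts, states = generate_regime_bold(spec, n_timepoints=200, noise_sd=0.05, seed=7)
        traj = subspace_trajectory(phase_coherence_dfc(hilbert_phase(ts)), k=3)
        assert states[14] == states[19] and states[14] != states[79]
        near, far = short_long_range_profiles(traj, near_pair=(15, 20), far_pair=(15, 80))
        assert far.per_roi_distance.mean() > near.per_roi_distance.mean()

    def test_out_of_range_timepoint(self, two_regime_trajectory):
        traj, _ = two_regime_trajectory
        with pytest.raises(ValueError, match="outside"):
            short_long_range_profiles(traj, far_pair=(15, 500))
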