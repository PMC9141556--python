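import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
import scipy.linalg
from scipy.spatial.distance import squareform

from nbens.constants import KB_KCAL
from nbens.cv_landscape import (
    CollectiveVariable,
    TorsionFeatures,
    average_linkage_cluster,
    eval_cv,
    featurize,
    free_energy_surface,
    pairwise_rmsd_matrix,
    tica_fit,
    tica_transform,
)
from nbens.structure_io import Trajectory
from nbens.synthetic_data import TwoStateLoopParams, gen_two_state_loop
from .conftest import make_peptide, rigid_move


def torsion_traj(angles, dt=1.0):
    angles = np.atleast_2d(np.asarray(angles, float))
    return Trajectory(frames=angles, dt=dt, kind="torsion",
                      labels=[(i + 1, "psi") for i in range(angles.shape[1])])


# ---------------------------------------------------------------------------
# featurize
# ---------------------------------------------------------------------------


class TestFeaturize:
    def test_ninety_degrees(self):
        f = featurize(torsion_traj([[90.0]] * 3))
        np.testing.assert_allclose(f.matrix, [[1.0, 0.0]] * 3, atol=1e-12)

    def test_zero_degrees(self):
        f = featurize(torsion_traj([[0.0]]))
        np.testing.assert_allclose(f.matrix, [[0.0, 1.0]], atol=1e-12)

    def test_full_turn_invariance(self):
        rng = np.random.default_rng(1)
        angles = rng.uniform(-180, 180, (50, 3))
        f1 = featurize(torsion_traj(angles))
        f2 = featurize(torsion_traj(angles + 360.0))
        np.testing.assert_allclose(f1.matrix, f2.matrix, atol=1e-12)

    def test_sin_cos_identity(self):
        rng = np.random.default_rng(2)
        f = featurize(torsion_traj(rng.uniform(-180, 180, (100, 4))))
        s2c2 = f.matrix[:, 0::2] ** 2 + f.matrix[:, 1::2] ** 2
        np.testing.assert_allclose(s2c2, 1.0, atol=1e-12)

    def test_undefined_torsion_rejected(self):
        angles = np.array([[10.0, np.nan], [20.0, 30.0]])
        with pytest.raises(ValueError, match="undefined"):
            featurize(torsion_traj(angles))

    def test_selection_order(self):
        angles = np.array([[0.0, 90.0]])
        f = featurize(torsion_traj(angles), torsion_selection=[(2, "psi"),
                                                               (1, "psi")])
        np.testing.assert_allclose(f.matrix, [[1.0, 0.0, 0.0, 1.0]],
                                   atol=1e-12)


# ---------------------------------------------------------------------------
# eval_cv
# ---------------------------------------------------------------------------


class TestEvalCV:
    def test_unit_sin_weights_at_ninety(self):
        k = 5
        cv = CollectiveVariable(sin_weights=np.ones(k),
                                cos_weights=np.zeros(k))
        vals = eval_cv(torsion_traj([[90.0] * k] * 3), cv)
        np.testing.assert_allclose(vals, k, atol=1e-12)

    def test_zero_weights(self):
        cv = CollectiveVariable(sin_weights=np.zeros(4),
                                cos_weights=np.zeros(4))
        vals = eval_cv(torsion_traj(np.random.default_rng(0).uniform(
            -180, 180, (10, 4))), cv)
        np.testing.assert_allclose(vals, 0.0, atol=1e-12)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(3)
        k, n = 6, 40
        angles = rng.uniform(-180, 180, (n, k))
        a = rng.normal(size=k)
        b = rng.normal(size=k)
        cv = CollectiveVariable(sin_weights=a, cos_weights=b)
        got = eval_cv(torsion_traj(angles), cv)
        rad = np.radians(angles)
        expected = np.array([
            sum(a[i] * np.sin(rad[t, i]) + b[i] * np.cos(rad[t, i])
                for i in range(k))
            for t in range(n)
        ])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_features_and_angles_agree(self):
        rng = np.random.default_rng(4)
        angles = rng.uniform(-180, 180, (20, 3))
        cv = CollectiveVariable(sin_weights=rng.normal(size=3),
                                cos_weights=rng.normal(size=3))
        traj = torsion_traj(angles)
        np.testing.assert_allclose(eval_cv(traj, cv),
                                   eval_cv(featurize(traj), cv), atol=1e-12)

    def test_length_mismatch(self):
        cv = CollectiveVariable(sin_weights=np.ones(2),
                                cos_weights=np.ones(2))
        with pytest.raises(ValueError):
            eval_cv(torsion_traj([[0.0, 0.0, 0.0]]), cv)


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------


def ar1(rho, n, rng, d=1):
    x = np.zeros((n, d))
    noise = rng.normal(size=(n, d))
    for t in range(1, n):
        x[t] = rho * x[t - 1] + noise[t]
    return x


class TestTica:
    def test_ar1_eigenvalue(self):
        rho, lag = 0.9, 5
        rng = np.random.default_rng(0)
        estimates = [
            tica_fit(ar1(rho, 20_000, rng), lag=lag).eigenvalues[0]
            for _ in range(10)
        ]
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - rho**lag) < 3 * max(se, 1e-3)

    def test_constant_features_degenerate(self):
        with pytest.raises(ValueError):
            tica_fit(np.ones((100, 2)), lag=2)

    def test_matches_dense_eigensolver_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(400, 5)) @ rng.normal(size=(5, 5))
        x = np.cumsum(x, axis=0) * 0.05 + x  # give it time correlation
        lag = 3
        eps = 1e-6
        model = tica_fit(x, lag=lag, epsilon=eps)
        # independent dense route: explicitly build both covariances and
        # solve with eig on inv(C0) @ Ctau
        x0, xt = x[:-lag], x[lag:]
        mean = np.concatenate([x0, xt]).mean(axis=0)
        a, b = x0 - mean, xt - mean
        n = a.shape[0]
        c0 = (a.T @ a + b.T @ b) / (2 * n) + eps * np.eye(5)
        ctau = (a.T @ b + b.T @ a) / (2 * n)
        w = np.linalg.eigvals(np.linalg.inv(c0) @ ctau)
        np.testing.assert_allclose(model.eigenvalues,
                                   np.sort(w.real)[::-1], atol=1e-8)

    def test_components_c0_orthonormal(self):
        rng = np.random.default_rng(6)
        x = ar1(0.8, 5000, rng, d=4)
        model = tica_fit(x, lag=2, epsilon=1e-10)
        gram = model.components.T @ model.c0 @ model.components
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-6)

    def test_eigenvalues_bounded(self):
        rng = np.random.default_rng(7)
        model = tica_fit(ar1(0.7, 5000, rng, d=3), lag=1)
        assert np.all(np.abs(model.eigenvalues) <= 1.0 + 1e-6)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_rescaling_leaves_eigenvalues(self):
        rng = np.random.default_rng(8)
        x = ar1(0.85, 8000, rng, d=3)
        scale = np.array([2.0, 0.5, 3.0])
        m1 = tica_fit(x, lag=2, epsilon=1e-12)
        m2 = tica_fit(x * scale, lag=2, epsilon=1e-12)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-8)

    def test_lag_too_long(self):
        with pytest.raises(ValueError):
            tica_fit(np.random.default_rng(0).normal(size=(10, 2)), lag=20)

    def test_transform_of_mean_is_origin(self):
        rng = np.random.default_rng(9)
        x = ar1(0.8, 3000, rng, d=3)
        model = tica_fit(x, lag=2)
        np.testing.assert_allclose(tica_transform(model, model.mean), 0.0,
                                   atol=1e-12)

    def test_two_state_separable_on_tic1(self):
        params = TwoStateLoopParams(
            n_residues=3,
            state_centers=([-60.0, -45.0, 150.0], [60.0, 45.0, -150.0]),
            hop_probability=0.01, angular_noise_sd=15.0,
            n_frames=20_000, seed=10)
        traj, labels = gen_two_state_loop(params)
        feats = featurize(traj)
        model = tica_fit(feats, lag=1.0)
        tic1 = tica_transform(model, feats)[:, 0]
        thr = np.median(tic1)
        pred = (tic1 > thr).astype(int)
        err = min(np.mean(pred != labels), np.mean(pred != 1 - labels))
        assert err < 0.05

    def test_out_of_sample_matches_in_sample(self):
        rng = np.random.default_rng(11)
        x = ar1(0.9, 4000, rng, d=3)
        model = tica_fit(x, lag=2)
        proj_all = tica_transform(model, x)
        proj_single = tica_transform(model, x[123])
        np.testing.assert_allclose(proj_single, proj_all[123], atol=1e-12)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(12)
        model = tica_fit(ar1(0.8, 1000, rng, d=3), lag=1)
        with pytest.raises(ValueError):
            tica_transform(model, np.zeros((5, 4)))


# ---------------------------------------------------------------------------
# Free-energy surface
# ---------------------------------------------------------------------------


class TestFreeEnergySurface:
    def test_uniform_points_flat(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, (200_000, 2))
        fes = free_energy_surface(pts, bins=5, temperature=300.0)
        assert np.nanmax(fes.delta_g) < 0.05  # kcal/mol of counting noise

    def test_counts_conserved_and_min_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5000, 2))
        fes = free_energy_surface(pts, bins=20)
        assert fes.counts.sum() == 5000
        assert np.nanmin(fes.delta_g) == 0.0

    def test_two_equal_blobs_equal_depth(self):
        rng = np.random.default_rng(2)
        blob = rng.normal(0, 0.1, (20_000, 2))
        pts = np.vstack([blob + [-1, 0], blob + [1, 0]])
        fes = free_energy_surface(pts, bins=24)
        half = fes.delta_g.shape[0] // 2
        left = np.nanmin(fes.delta_g[:half])
        right = np.nanmin(fes.delta_g[half:])
        assert abs(left - right) < 0.02

    def test_ten_to_one_gives_kt_ln10(self):
        rng = np.random.default_rng(3)
        n = 100_000
        blob_a = rng.normal(0, 0.05, (n, 2)) + [-1, 0]
        blob_b = rng.normal(0, 0.05, (n // 10, 2)) + [1, 0]
        fes = free_energy_surface(np.vstack([blob_a, blob_b]), bins=30,
                                  temperature=300.0)
        half = fes.delta_g.shape[0] // 2
        ddg = np.nanmin(fes.delta_g[half:]) - np.nanmin(fes.delta_g[:half])
        expected = KB_KCAL * 300.0 * np.log(10)  # 1.37 kcal/mol
        assert ddg == pytest.approx(expected, abs=0.08)

    def test_single_point_valid(self):
        fes = free_energy_surface(np.zeros((1, 2)), bins=4)
        assert fes.counts.sum() == 1
        assert np.nanmin(fes.delta_g) == 0.0

    def test_unsampled_bins_are_nan(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        fes = free_energy_surface(pts, bins=4)
        assert np.isnan(fes.delta_g[~fes.occupied]).all()
        assert np.isfinite(fes.delta_g[fes.occupied]).all()


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def conformer_trajectory(n_a=4, n_b=3, spread=0.05, seed=0):
    """Frames drawn around two rigid conformers separated by a large RMSD."""
    rng = np.random.default_rng(seed)
    base_a = np.array([[0.0, 0, 0], [3, 0, 0], [3, 3, 0], [0, 3, 0],
                       [0, 0, 3]])
    base_b = base_a.copy()
    base_b[4] = [5.0, 5.0, 8.0]  # very different fifth atom
    frames = []
    labels = []
    for k in range(n_a + n_b):
        base = base_a if k < n_a else base_b
        frames.append(base + rng.normal(0, spread, base.shape))
        labels.append(0 if k < n_a else 1)
    return Trajectory(frames=np.array(frames)), np.array(labels)


class TestClustering:
    def test_identical_frames_single_cluster(self):
        base = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        traj = Trajectory(frames=np.repeat(base[None], 5, axis=0))
        res = average_linkage_cluster(traj, selection=None, cutoff=1.2)
        assert res.n_clusters == 1
        assert res.representatives[0] in range(5)

    def test_two_conformers_recovered(self):
        traj, labels = conformer_trajectory()
        res = average_linkage_cluster(traj, selection=None, cutoff=1.2)
        assert res.n_clusters == 2
        # mapping may flip, but partition must match exactly
        assert (np.all(res.assignments == labels)
                or np.all(res.assignments == 1 - labels))
        for cid, rep in enumerate(res.representatives):
            assert res.assignments[rep] == cid

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(4)
        traj = Trajectory(frames=rng.normal(0, 2, (6, 4, 3)))
        dist = pairwise_rmsd_matrix(traj, selection=None)
        cutoff = np.median(dist)
        res = average_linkage_cluster(traj, selection=None, cutoff=cutoff)
        z = sch.linkage(squareform(dist, checks=False), method="average")
        expected = sch.fcluster(z, t=cutoff, criterion="distance")
        # compare partitions up to relabeling
        def canon(a):
            first = {}
            out = []
            for v in a:
                first.setdefault(v, len(first))
                out.append(first[v])
            return out
        assert canon(res.assignments) == canon(expected)
        # merge distances below the cutoff agree with scipy's dendrogram
        ours = sorted(h[2] for h in res.merge_history)
        theirs = sorted(d for d in z[:, 2] if d <= cutoff)
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_permutation_invariant_partition(self):
        traj, _ = conformer_trajectory(seed=5)
        res1 = average_linkage_cluster(traj, selection=None, cutoff=1.2)
        perm = np.random.default_rng(6).permutation(traj.n_frames)
        traj2 = Trajectory(frames=traj.frames[perm])
        res2 = average_linkage_cluster(traj2, selection=None, cutoff=1.2)
        # clusters as frozensets of original frame ids must coincide
        def partition(assign, mapping=None):
            groups = {}
            for frame, cid in enumerate(assign):
                orig = frame if mapping is None else mapping[frame]
                groups.setdefault(cid, set()).add(orig)
            return {frozenset(v) for v in groups.values()}
        assert partition(res1.assignments) == partition(res2.assignments, perm)

    def test_empty_selection_rejected(self):
        traj, _ = conformer_trajectory()
        with pytest.raises(Exception):
            average_linkage_cluster(traj, selection=[], cutoff=1.0)
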