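"""Superposition, RMSF, essential-dynamics PCA, RMSIP and LDA consistency."""

import numpy as np
import pytest

from camryr import synthetic
from camryr.ensemble import (
    Ensemble,
    EssentialSubspace,
    ParticleLabel,
    pca,
    project,
    replica_consistency,
    rmsf,
    rmsip,
    superpose,
)


def labels(n):
    return tuple(ParticleLabel("A", i + 1) for i in range(n))


def random_subspace(rng, dim, s):
    q, _ = np.linalg.qr(rng.normal(size=(dim, s)))
    vals = np.sort(rng.random(s))[::-1]
    return EssentialSubspace(eigenvectors=q, eigenvalues=vals,
                             mean=np.zeros(dim))


class TestSuperpose:
    def test_identical_frames_unmoved(self):
        base = synthetic._helix_backbone(10)
        ens = Ensemble(labels(10), np.stack([base] * 5))
        sup = superpose(ens)
        assert np.allclose(sup.frames, sup.frames[0], atol=1e-10)

    def test_rigid_motion_removed(self):
        ens, _ = synthetic.gen_ensemble(seed=1, n_frames=20, jitter_sd=0.0,
                                        mode_variances=(0.0,),
                                        rigid_nuisance=True)
        sup = superpose(ens)
        # all frames identical up to the removed rigid motion
        rmsd = np.sqrt(((sup.frames - sup.frames[0]) ** 2).sum(-1).mean(-1))
        assert np.all(rmsd < 1e-8)

    def test_refinement_is_monotone(self):
        ens, _ = synthetic.gen_ensemble(seed=2, n_frames=50, jitter_sd=0.5,
                                        rigid_nuisance=True)

        def mean_rmsd(e):
            ref = e.frames.mean(axis=0)
            return np.sqrt(((e.frames - ref) ** 2).sum(-1).mean())

        vals = [mean_rmsd(superpose(ens, n_rounds=r)) for r in range(3)]
        assert vals[0] >= vals[1] - 1e-12
        assert vals[1] >= vals[2] - 1e-12

    def test_too_few_particles_rejected(self):
        ens = Ensemble(labels(2), np.zeros((3, 2, 3)) + np.arange(2)[None, :, None])
        with pytest.raises(ValueError):
            superpose(ens, selection="all")


class TestRMSF:
    def test_static_frames_zero(self):
        base = synthetic._helix_backbone(8)
        ens = Ensemble(labels(8), np.stack([base] * 4), superposed=True)
        assert np.allclose(rmsf(ens).rmsf, 0.0)

    def test_two_state_oscillation_closed_form(self):
        # one particle alternating ±a along x: RMSF = a
        a = 0.7
        base = synthetic._helix_backbone(5)
        frames = np.stack([base] * 10)
        frames[::2, 2, 0] += a
        frames[1::2, 2, 0] -= a
        ens = Ensemble(labels(5), frames, superposed=True)
        profile = rmsf(ens)
        assert profile.rmsf[2] == pytest.approx(a)
        assert np.allclose(np.delete(profile.rmsf, 2), 0.0)

    def test_requires_superposition(self):
        ens, _ = synthetic.gen_ensemble(seed=0, rigid_nuisance=True)
        with pytest.raises(RuntimeError):
            rmsf(ens)

    def test_invariant_under_global_rigid_motion(self):
        ens, _ = synthetic.gen_ensemble(seed=3, n_frames=100, jitter_sd=0.3)
        ref_profile = rmsf(superpose(ens, n_rounds=10)).rmsf
        # rotate and translate every frame before superposing again
        rng = np.random.default_rng(99)
        frames = ens.frames.copy()
        for f in range(frames.shape[0]):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ])
            frames[f] = frames[f] @ rot.T + rng.normal(0.0, 8.0, size=3)
        moved = Ensemble(ens.particle_labels, frames)
        # iterative refinement converges to the same fixed point from
        # either starting orientation
        recovered = rmsf(superpose(moved, n_rounds=10)).rmsf
        assert np.allclose(recovered, ref_profile, atol=1e-8)


class TestPCA:
    def test_planted_single_mode_recovered(self):
        ens, truth = synthetic.gen_ensemble(seed=4, n_frames=400,
                                            mode_variances=(4.0,),
                                            jitter_sd=0.0)
        sub = pca(ens)
        dot = abs(sub.eigenvectors[:, 0] @ truth["mode_vectors"][:, 0])
        assert dot > 0.999
        assert np.all(sub.eigenvalues[1:] < 1e-10)

    def test_trace_identity(self):
        ens, _ = synthetic.gen_ensemble(seed=5, n_frames=800, jitter_sd=0.3)
        sub = pca(ens)
        flat = ens.frames.reshape(ens.n_frames, -1)
        total_var = flat.var(axis=0).sum()
        assert sub.eigenvalues.sum() == pytest.approx(total_var, rel=1e-6)

    def test_planted_variance_ratio(self):
        ens, _ = synthetic.gen_ensemble(seed=6, n_frames=5000,
                                        mode_variances=(4.0, 1.0),
                                        jitter_sd=0.0)
        sub = pca(ens)
        ratio = sub.eigenvalues[0] / sub.eigenvalues[1]
        assert ratio == pytest.approx(4.0, rel=0.15)


class TestProjection:
    def test_average_structure_maps_to_origin(self):
        ens, _ = synthetic.gen_ensemble(seed=7, n_frames=200, jitter_sd=0.2)
        sub = pca(ens)
        scores = project(ens, sub, k=2)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-9)

    def test_score_variance_equals_eigenvalue(self):
        ens, _ = synthetic.gen_ensemble(seed=8, n_frames=500, jitter_sd=0.2)
        sub = pca(ens)
        scores = project(ens, sub, k=3)
        assert np.allclose(scores.var(axis=0), sub.eigenvalues[:3], rtol=1e-8)

    def test_full_rank_reconstruction(self):
        ens, _ = synthetic.gen_ensemble(seed=9, n_particles=6, n_frames=100,
                                        jitter_sd=0.2)
        sub = pca(ens)
        flat = ens.frames.reshape(ens.n_frames, -1)
        scores = project(ens, sub, k=sub.n_components)
        rebuilt = sub.mean + scores @ sub.eigenvectors.T
        assert np.allclose(rebuilt, flat, atol=1e-8)


class TestRMSIP:
    def test_self_overlap_is_one(self):
        sub = random_subspace(np.random.default_rng(0), 120, 25)
        assert rmsip(sub, sub, 20) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_subspaces_zero(self):
        dim, s = 80, 20
        eye = np.eye(dim)
        a = EssentialSubspace(eye[:, :s], np.ones(s), np.zeros(dim))
        b = EssentialSubspace(eye[:, s:2 * s], np.ones(s), np.zeros(dim))
        assert rmsip(a, b, s) == 0.0

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = random_subspace(rng, 90, 20)
            b = random_subspace(rng, 90, 20)
            ab, ba = rmsip(a, b, 20), rmsip(b, a, 20)
            assert ab == pytest.approx(ba, abs=1e-12)
            assert 0.0 <= ab <= 1.0


class TestReplicaConsistency:
    def test_same_distribution_near_chance(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(4000, 2))
        rep = replica_consistency(scores, np.repeat([0, 1], 2000))
        assert rep["accuracy"] <= rep["chance"] + 0.1
        assert rep["overlap"][("0", "1")] > 0.9

    def test_separated_clusters(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 0.3, size=(500, 2))
        b = rng.normal(10.0, 0.3, size=(500, 2))
        rep = replica_consistency(np.vstack([a, b]), np.repeat(["r1", "r2"], 500))
        assert rep["accuracy"] > 0.999
        assert rep["overlap"][("r1", "r2")] < 0.01

    def test_duplicated_replica_full_overlap(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(300, 2))
        rep = replica_consistency(np.vstack([a, a]), np.repeat(["a", "b"], 300))
        assert rep["overlap"][("a", "b")] == pytest.approx(1.0, abs=1e-9)

    def test_single_replica_rejected(self):
        with pytest.raises(ValueError):
            replica_consistency(np.zeros((10, 2)), np.zeros(10))
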