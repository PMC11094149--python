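"""Overlap, weight change, deviation angles, RDMs, congruence, decay fits."""

import numpy as np
import pytest

from motoradapt import adaptation_metrics as am
from motoradapt import tasks


class TestManifoldOverlap:
    def test_identical_activity_ratio_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(60, 15)) * np.linspace(3, 0.1, 15)
        ratio, b1, b2 = am.manifold_overlap(a, a, k=5)
        assert ratio == pytest.approx(1.0, abs=1e-12)
        assert b1 == b2

    def test_orthogonal_complement_ratio_zero(self):
        rng = np.random.default_rng(1)
        # A1 spans the first 4 axes, A2 the last 4 of a 12-d space
        a1 = np.zeros((40, 12))
        a1[:, :4] = rng.normal(size=(40, 4)) * [4, 3, 2, 1]
        a2 = np.zeros((40, 12))
        a2[:, -4:] = rng.normal(size=(40, 4))
        ratio, _, b2 = am.manifold_overlap(a1, a2, k=4)
        assert b2 == pytest.approx(0.0, abs=1e-10)
        assert ratio == pytest.approx(0.0, abs=1e-10)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        a1 = rng.normal(size=(50, 8)) * np.linspace(2, 0.2, 8)
        a2 = rng.normal(size=(50, 8))
        ratio, _, _ = am.manifold_overlap(a1, a2, k=3)
        perm = rng.permutation(50)
        ratio_p, _, _ = am.manifold_overlap(a1, a2[perm], k=3)
        assert ratio_p == pytest.approx(ratio, rel=1e-10)

    def test_matches_explicit_projection_oracle(self):
        """Trace formula vs explicitly projecting activity onto the axes."""
        rng = np.random.default_rng(3)
        for trial in range(5):
            a1 = rng.normal(size=(30, 9)) * rng.uniform(0.1, 3, size=9)
            a2 = rng.normal(size=(25, 9)) * rng.uniform(0.1, 3, size=9)
            k = 4
            ratio, b1, b2 = am.manifold_overlap(a1, a2, k=k)
            from motoradapt.geometry import fit_manifold

            v1 = fit_manifold(a1, k=k).components
            for a, beta in ((a1, b1), (a2, b2)):
                centered = a - a.mean(axis=0)
                proj = centered @ v1.T
                explained = np.sum(proj.var(axis=0, ddof=1))
                total = np.sum(centered.var(axis=0, ddof=1))
                assert beta == pytest.approx(explained / total, abs=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            am.manifold_overlap(np.ones((10, 4)), np.ones((10, 4)), k=2)


class TestRelativeWeightChange:
    def test_no_change(self):
        j = np.random.default_rng(0).normal(size=(5, 5))
        med, n_exc = am.relative_weight_change(j, j)
        assert med == 0.0 and n_exc == 0

    def test_doubling_gives_one(self):
        j = np.random.default_rng(1).normal(size=(5, 5))
        med, _ = am.relative_weight_change(j, 2 * j)
        assert med == pytest.approx(1.0)

    def test_hand_enumerated_toy(self):
        before = np.array([[1.0, 2.0], [4.0, 8.0]])
        after = np.array([[2.0, 1.0], [8.0, 4.0]])
        med, _ = am.relative_weight_change(before, after)
        # |dJ/J| entries: {1, 0.5, 1, 0.5} -> median 0.75
        assert med == pytest.approx(0.75)

    def test_zero_entries_excluded(self):
        before = np.array([[0.0, 1.0], [2.0, 4.0]])
        after = np.array([[5.0, 2.0], [2.0, 2.0]])
        med, n_exc = am.relative_weight_change(before, after)
        assert n_exc == 1
        assert med == pytest.approx(0.5)  # median of {1, 0, 0.5}


class TestDeviationAngles:
    def test_parallel_adaptation_zero_degrees(self):
        rng = np.random.default_rng(4)
        x1 = rng.normal(size=(30, 10))
        x2 = x1 + rng.normal(size=(30, 10))
        x1p = x1 + 0.3 * (x2 - x1)  # moved exactly toward movement 2
        dev = am.deviation_angles(x1, x2, x1p)
        # arccos loses precision near cos = 1; 1e-3 deg is still "parallel"
        np.testing.assert_allclose(dev.angles_deg, 0.0, atol=1e-3)

    def test_orthogonal_adaptation_ninety_degrees(self):
        T = 20
        x1 = np.zeros((T, 4))
        x2 = np.zeros((T, 4))
        x2[:, 0] = 1.0  # adjacent vector along axis 0
        x1p = np.zeros((T, 4))
        x1p[:, 1] = 2.0  # adaptation along axis 1
        dev = am.deviation_angles(x1, x2, x1p)
        np.testing.assert_allclose(dev.angles_deg, 90.0, atol=1e-10)

    def test_random_vectors_concentrate_near_ninety(self):
        """Shuffled-control behaviour: independent random directions in
        k = 10 dimensions are nearly orthogonal on average."""
        rng = np.random.default_rng(5)
        x1 = np.zeros((4000, 10))
        dev = am.deviation_angles(
            x1, rng.normal(size=(4000, 10)), rng.normal(size=(4000, 10))
        )
        assert abs(np.median(dev.angles_deg) - 90.0) < 3.0
        assert dev.angles_deg.min() >= 0.0 and dev.angles_deg.max() <= 180.0

    def test_zero_vectors_dropped(self):
        x1 = np.zeros((5, 3))
        x2 = np.zeros((5, 3))
        x2[2:, 0] = 1.0
        x1p = np.ones((5, 3))
        dev = am.deviation_angles(x1, x2, x1p)
        assert dev.n_dropped == 2
        assert len(dev.angles_deg) == 3


class TestRDMs:
    def test_input_rdm_identical_vectors_zero(self):
        cfg = tasks.center_out_config(3, "angular")
        rdm = am.input_rdm(cfg)
        assert np.all(np.diag(rdm.values) == 0)
        assert np.all(rdm.values >= 0)
        np.testing.assert_allclose(rdm.values, rdm.values.T)

    def test_distinct_onehot_cues_dissimilarity_one(self):
        cfg = tasks.center_out_config(4, "categorical")
        rdm = am.input_rdm(cfg)
        off_diag = rdm.values[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off_diag, 1.0, atol=1e-12)

    def test_angular_cues_cosine_identity(self):
        cfg = tasks.center_out_config(4, "angular")
        rdm = am.input_rdm(cfg)
        angles = [m.angle_deg for m in cfg.movements]
        for i in range(4):
            for j in range(4):
                expected = 1 - np.cos(np.deg2rad(angles[i] - angles[j]))
                assert rdm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_neural_rdm_translation(self):
        rng = np.random.default_rng(6)
        x1 = np.cumsum(rng.normal(size=(20, 5)), axis=0)
        offset = np.array([3.0, 0, 0, 0, 0])
        rdm = am.neural_rdm([x1, x1 + offset, x1.copy()])
        steps = np.linalg.norm(np.diff(x1, axis=0), axis=1)
        denom = np.median(np.concatenate([steps] * 3))
        assert rdm.values[0, 1] == pytest.approx(3.0 / denom, rel=1e-10)
        assert rdm.values[0, 2] == 0.0

    def test_neural_rdm_straight_line_hand_case(self):
        # trajectories along x at speed 1/step; traj2 shifted by 2 in y
        t = np.arange(5, dtype=float)
        x1 = np.column_stack([t, np.zeros(5)])
        x2 = np.column_stack([t, np.full(5, 2.0)])
        rdm = am.neural_rdm([x1, x2])
        # step lengths all 1 -> denominator 1; D = 2
        assert rdm.values[0, 1] == pytest.approx(2.0)

    def test_single_point_trajectory_rejected(self):
        with pytest.raises(ValueError):
            am.neural_rdm([np.zeros((1, 3)), np.zeros((1, 3))])


class TestCongruence:
    def _rdm(self, values):
        v = np.asarray(values, dtype=float)
        return am.RDM(values=v, kind="neural_distance",
                      movement_ids=tuple(range(v.shape[0])))

    def test_identical_rdms_r_one(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(size=(4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        assert am.congruence(self._rdm(m), self._rdm(m)) == pytest.approx(1.0)

    def test_positive_affine_invariance(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(size=(4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        m2 = 2.5 * m + 0.3
        np.fill_diagonal(m2, 0)
        assert am.congruence(self._rdm(m), self._rdm(m2)) == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        ua = np.array([1.0, 2, 3, 4, 5, 6])
        ub = ua[::-1].copy()
        iu = np.triu_indices(4, k=1)
        a[iu], b[iu] = ua, ub
        a, b = a + a.T, b + b.T
        r = am.congruence(self._rdm(a), self._rdm(b))
        expected = np.corrcoef(ua, ub)[0, 1]  # = -1 for reversed order
        assert r == pytest.approx(expected, abs=1e-12)

    def test_two_movements_rejected(self):
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            am.congruence(self._rdm(m), self._rdm(m))


class TestDecayFit:
    def test_noise_free_recovery(self):
        n = np.arange(100)
        curve = 1.0 * np.exp(-n / 20.0) + 0.05
        fit = am.fit_decay_constant(curve, smooth=False)
        assert fit.success
        assert fit.tau_trials == pytest.approx(20.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-6)
        assert fit.offset == pytest.approx(0.05, abs=1e-8)

    def test_noisy_recovery_within_fifteen_percent(self):
        """Monte-Carlo: tau recovered within 15% on noisy exponentials."""
        rng = np.random.default_rng(9)
        n = np.arange(100)
        errs = []
        for _ in range(100):
            curve = 1.0 * np.exp(-n / 20.0) + 0.05 + rng.normal(0, 0.01, 100)
            fit = am.fit_decay_constant(curve, smooth=True)
            assert fit.success
            errs.append(abs(fit.tau_trials - 20.0) / 20.0)
        assert np.median(errs) < 0.15
        assert np.mean(errs) < 0.15

    def test_constant_curve_flagged(self):
        fit = am.fit_decay_constant(np.full(50, 0.3))
        assert not fit.success

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            am.fit_decay_constant(np.array([1.0, np.nan, 0.5]))
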