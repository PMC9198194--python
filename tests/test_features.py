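import math

import numpy as np
import pytest

from vectex import (MEASURE_NAMES, N_FEATURES, ROIMask, VTI, compute_vcm_stack,
                    feature_vector, normalize_vcm, texture_measures)
from vectex.features import DegenerateMatrixError


def oracle_measures(counts):
    """Direct per-formula summation over all cells; independent of the
    vectorized implementation."""
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    p = counts / counts.sum()

    def log2(x):
        return math.log2(x) if x > 0 else 0.0

    px = [sum(p[i, j] for j in range(n)) for i in range(n)]
    py = [sum(p[i, j] for i in range(n)) for j in range(n)]
    psum = [0.0] * (2 * n - 1)
    pdiff = [0.0] * n
    for i in range(n):
        for j in range(n):
            psum[i + j] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(n))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(n))

    out = {}
    out["energy"] = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    out["contrast"] = sum((i - j) ** 2 * p[i, j]
                          for i in range(n) for j in range(n))
    if var_x > 0 and var_y > 0:
        out["correlation"] = sum((i - mu_x) * (j - mu_y) * p[i, j]
                                 for i in range(n) for j in range(n)) \
            / math.sqrt(var_x * var_y)
    else:
        out["correlation"] = 0.0
    out["sum_of_squares_variance"] = var_x
    out["inverse_difference_moment"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    sa = sum(k * psum[k] for k in range(len(psum)))
    out["sum_average"] = sa
    out["sum_variance"] = sum((k - sa) ** 2 * psum[k] for k in range(len(psum)))
    out["sum_entropy"] = -sum(psum[k] * log2(psum[k]) for k in range(len(psum)))
    hxy = -sum(p[i, j] * log2(p[i, j]) for i in range(n) for j in range(n))
    out["entropy"] = hxy
    da = sum(k * pdiff[k] for k in range(n))
    out["difference_variance"] = sum((k - da) ** 2 * pdiff[k] for k in range(n))
    out["difference_entropy"] = -sum(pdiff[k] * log2(pdiff[k]) for k in range(n))
    hx = -sum(px[i] * log2(px[i]) for i in range(n))
    hy = -sum(py[j] * log2(py[j]) for j in range(n))
    hxy1 = -sum(p[i, j] * log2(px[i] * py[j])
                for i in range(n) for j in range(n))
    hxy2 = -sum(px[i] * py[j] * log2(px[i] * py[j])
                for i in range(n) for j in range(n))
    out["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    support = [i for i in range(n) if px[i] > 0]
    if len(support) >= 2:
        q = np.zeros((len(support), len(support)))
        for a, i in enumerate(support):
            for b, j in enumerate(support):
                q[a, b] = sum(p[i, k] * p[j, k] / (px[i] * py[k])
                              for k in support)
        eig = sorted(np.real(np.linalg.eigvals(q)), reverse=True)
        second = eig[1] if len(eig) > 1 else 0.0
        out["max_correlation_coeff"] = math.sqrt(min(max(second, 0.0), 1.0))
    else:
        out["max_correlation_coeff"] = 0.0
    out["autocorrelation"] = sum(i * j * p[i, j]
                                 for i in range(n) for j in range(n))
    for power, name in ((4, "cluster_prominence"), (3, "cluster_shade"),
                        (2, "cluster_tendency")):
        out[name] = sum((i + j - mu_x - mu_y) ** power * p[i, j]
                        for i in range(n) for j in range(n))
    out["dissimilarity"] = sum(abs(i - j) * p[i, j]
                               for i in range(n) for j in range(n))
    out["maximum_probability"] = max(p[i, j]
                                     for i in range(n) for j in range(n))
    out["inverse_difference"] = sum(p[i, j] / (1 + abs(i - j))
                                    for i in range(n) for j in range(n))
    out["inverse_difference_normalized"] = sum(
        p[i, j] / (1 + abs(i - j) / n) for i in range(n) for j in range(n))
    out["inverse_difference_moment_normalized"] = sum(
        p[i, j] / (1 + (i - j) ** 2 / n ** 2)
        for i in range(n) for j in range(n))
    out["joint_average"] = mu_x
    out["joint_variance"] = var_x
    out["inverse_variance"] = sum(p[i, j] / (i - j) ** 2
                                  for i in range(n) for j in range(n) if i != j)
    out["difference_average"] = da
    out["marginal_entropy_sum"] = hx + hy
    return out


class TestNormalize:
    def test_single_count(self):
        counts = np.zeros((3, 3))
        counts[1, 2] = 4
        pm = normalize_vcm(counts)
        assert pm.p[1, 2] == 1.0
        assert pm.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform(self):
        pm = normalize_vcm(np.ones((5, 5)))
        np.testing.assert_allclose(pm.p, 1 / 25)
        np.testing.assert_allclose(pm.p_x, 1 / 5)

    def test_marginals_consistent(self, rng):
        counts = rng.integers(0, 20, size=(6, 6))
        counts = counts + counts.T
        pm = normalize_vcm(counts)
        np.testing.assert_allclose(pm.p_x, pm.p.sum(axis=1))
        np.testing.assert_allclose(pm.p_sum.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(pm.p_diff.sum(), 1.0, atol=1e-12)

    def test_zero_total_raises(self):
        with pytest.raises(DegenerateMatrixError):
            normalize_vcm(np.zeros((4, 4)))


class TestTextureMeasures:
    def test_order_and_count(self):
        assert len(MEASURE_NAMES) == 28
        values = texture_measures(normalize_vcm(np.ones((4, 4))))
        assert [name for name, _ in values] == list(MEASURE_NAMES)

    def test_degenerate_single_entry(self):
        counts = np.zeros((4, 4))
        counts[2, 2] = 7
        tm = dict(texture_measures(normalize_vcm(counts)))
        assert tm["energy"] == pytest.approx(1.0)
        assert tm["entropy"] == pytest.approx(0.0, abs=1e-12)
        assert tm["contrast"] == pytest.approx(0.0)

    def test_uniform_matrix(self):
        k = 5
        tm = dict(texture_measures(normalize_vcm(np.ones((k, k)))))
        assert tm["energy"] == pytest.approx(1 / k ** 2)
        assert tm["entropy"] == pytest.approx(math.log2(k ** 2))

    @pytest.mark.parametrize("size", [4, 7, 16])
    def test_matches_direct_summation_oracle(self, rng, size):
        counts = rng.integers(0, 30, size=(size, size))
        counts = counts + counts.T  # symmetric, as produced upstream
        got = dict(texture_measures(normalize_vcm(counts)))
        want = oracle_measures(counts)
        assert set(got) == set(want)
        for name in want:
            assert got[name] == pytest.approx(want[name], abs=1e-10), name

    def test_hand_set_4x4_oracle(self):
        counts = np.array([[4, 2, 1, 0], [2, 6, 3, 1],
                           [1, 3, 2, 2], [0, 1, 2, 8]], dtype=float)
        got = dict(texture_measures(normalize_vcm(counts)))
        want = oracle_measures(counts)
        for name in want:
            assert got[name] == pytest.approx(want[name], abs=1e-10), name

    def test_basic_ranges(self, rng):
        for _ in range(5):
            counts = rng.integers(0, 50, size=(6, 6))
            counts[0, 0] += 1  # non-degenerate
            counts = counts + counts.T
            tm = dict(texture_measures(normalize_vcm(counts)))
            assert 0 < tm["energy"] <= 1
            assert tm["entropy"] >= 0
            assert tm["contrast"] >= 0
            assert 0 < tm["maximum_probability"] <= 1
            assert -1 <= tm["correlation"] <= 1

    def test_label_permutation_invariance(self, rng):
        counts = rng.integers(0, 30, size=(8, 8))
        counts = counts + counts.T
        perm = rng.permutation(8)
        permuted = counts[np.ix_(perm, perm)]
        a = dict(texture_measures(normalize_vcm(counts)))
        b = dict(texture_measures(normalize_vcm(permuted)))
        for name in ("entropy", "energy", "maximum_probability"):
            assert a[name] == pytest.approx(b[name], abs=1e-12)

    def test_count_scaling_invariance(self, rng):
        counts = rng.integers(0, 30, size=(6, 6))
        counts = counts + counts.T + np.eye(6, dtype=int)
        a = dict(texture_measures(normalize_vcm(counts)))
        b = dict(texture_measures(normalize_vcm(counts * 7)))
        for name in MEASURE_NAMES:
            assert a[name] == pytest.approx(b[name], abs=1e-10), name


class TestFeatureVector:
    def _stack(self, rng, shape=(6, 6, 6)):
        ch0 = rng.integers(0, 2, size=shape)
        ch1 = rng.integers(0, 3, size=shape)
        vti = VTI(kind="GAV", channels=[ch0, ch1], levels=[2, 3])
        roi = ROIMask(np.ones(shape, dtype=bool))
        return vti, roi, compute_vcm_stack(vti, roi)

    def test_length_and_unique_names(self, rng):
        _, _, stack = self._stack(rng)
        fv = feature_vector(stack, "lesion_a", label=1)
        assert fv.values.size == N_FEATURES == 364
        assert len(set(fv.names)) == 364

    def test_deterministic(self, rng):
        vti, roi, _ = self._stack(rng)
        a = feature_vector(compute_vcm_stack(vti, roi), "x")
        b = feature_vector(compute_vcm_stack(vti, roi), "x")
        np.testing.assert_array_equal(a.values, b.values)

    def test_invariant_under_triple_axis_flip(self, rng):
        vti, roi, stack = self._stack(rng)
        flipped = VTI(kind="GAV",
                      channels=[ch[::-1, ::-1, ::-1] for ch in vti.channels],
                      levels=vti.levels)
        stack_f = compute_vcm_stack(flipped, roi)
        a = feature_vector(stack, "x")
        b = feature_vector(stack_f, "x")
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_degenerate_direction_gets_sentinels(self):
        # a 3x3x1 slab has no slice-direction pairs: direction (0,0,1)
        # (and every offset with a z-component) yields zero sentinels
        vti = VTI(kind="GAV",
                  channels=[np.zeros((3, 3, 1), dtype=int)] * 2,
                  levels=[1, 1])
        roi = ROIMask(np.ones((3, 3, 1), dtype=bool))
        with pytest.warns(RuntimeWarning):
            stack = compute_vcm_stack(vti, roi)
            fv = feature_vector(stack, "slab")
        z_feats = [v for n, v in zip(fv.names, fv.values)
                   if n.startswith("d0_0_1__")]
        assert all(v == 0.0 for v in z_feats)
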