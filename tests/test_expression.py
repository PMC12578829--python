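import numpy as np
import pytest
from scipy import stats

from selnc import expression_analytics as ea
from selnc.formats_io import ExpressionMatrix


# ---------------------------------------------------------------------------
# Nearest-centroid subtyping
# ---------------------------------------------------------------------------

@pytest.fixture
def centroids(rng):
    genes = [f"g{i}" for i in range(20)]
    values = rng.normal(size=(20, 3))
    return ea.SubtypeCentroids(genes, ["Basal", "Her2", "LumA"], values,
                               min_corr=0.1)


class TestClassifySubtype:
    def test_exact_match(self, centroids):
        sample = {g: centroids.values[i, 0] for i, g in enumerate(centroids.gene_ids)}
        label, r = ea.classify_subtype(sample, centroids)
        assert label == "Basal" and r == pytest.approx(1.0)

    def test_unknown_below_threshold(self, rng):
        genes = [f"g{i}" for i in range(20)]
        cents = ea.SubtypeCentroids(genes, ["A", "B"], rng.normal(size=(20, 2)),
                                    min_corr=0.99)
        sample = {g: rng.normal() for g in genes}
        label, _ = ea.classify_subtype(sample, cents)
        assert label == "Unknown"

    def test_tie_lexicographic(self):
        genes = ["g1", "g2", "g3", "g4"]
        col = np.array([1.0, 2.0, 3.0, 4.0])
        cents = ea.SubtypeCentroids(genes, ["Zeta", "Alpha"],
                                    np.column_stack([col, col]), min_corr=0.0)
        label, _ = ea.classify_subtype(dict(zip(genes, col)), cents)
        assert label == "Alpha"

    def test_insufficient_coverage(self, centroids):
        with pytest.raises(ValueError, match="covers only"):
            ea.classify_subtype({"g0": 1.0, "g1": 2.0, "g2": 0.5}, centroids)

    def test_too_few_shared(self, centroids):
        with pytest.raises(ValueError):
            ea.classify_subtype({"g0": 1.0}, centroids)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

class TestLDA:
    def test_separable_training_accuracy(self, rng):
        x = np.r_[rng.normal(-1, 0.1, 20), rng.normal(1, 0.1, 20)][:, None]
        labels = ["a"] * 20 + ["b"] * 20
        model = ea.lda_fit(x, labels, ridge=1e-9)
        assert ea.lda_classify(model, x) == labels

    def test_identical_classes_no_separation(self, rng):
        x = rng.normal(size=(40, 2))
        labels = ["a"] * 20 + ["b"] * 20
        sep = ea.lda_fit(np.r_[x[:20] - 3, x[20:] + 3], labels, ridge=1e-9)
        same = ea.lda_fit(np.r_[x[:20], x[:20]], labels, ridge=1e-6)
        assert same.eigenvalues[0] < 1e-3 * sep.eigenvalues[0]

    def test_axis_matches_grid_search_oracle(self, rng):
        # brute-force Fisher ratio over 3600 angles in 2-D
        x1 = rng.multivariate_normal([0, 0], [[2, 1.2], [1.2, 1]], 200)
        x2 = rng.multivariate_normal([2, 1], [[2, 1.2], [1.2, 1]], 200)
        X = np.r_[x1, x2]
        labels = np.r_[np.zeros(200), np.ones(200)]
        model = ea.lda_fit(X, labels, ridge=1e-9)
        w = model.axes[:, 0]

        def fisher(theta):
            v = np.array([np.cos(theta), np.sin(theta)])
            p1, p2 = x1 @ v, x2 @ v
            between = (p1.mean() - p2.mean()) ** 2
            within = ((p1 - p1.mean()) ** 2).sum() + ((p2 - p2.mean()) ** 2).sum()
            return between / within

        grid = np.linspace(0, np.pi, 3600, endpoint=False)
        best = grid[int(np.argmax([fisher(t) for t in grid]))]
        got = np.arctan2(w[1], w[0]) % np.pi
        diff = min(abs(got - best), np.pi - abs(got - best))
        assert diff < np.deg2rad(0.5)

    def test_small_class_rejected(self, rng):
        with pytest.raises(ValueError):
            ea.lda_fit(rng.normal(size=(3, 2)), ["a", "a", "b"])

    def test_ridge_required_high_dim(self, rng):
        with pytest.raises(ValueError):
            ea.lda_fit(rng.normal(size=(6, 10)), ["a"] * 3 + ["b"] * 3, ridge=0.0)


# ---------------------------------------------------------------------------
# Moderated t / BH
# ---------------------------------------------------------------------------

class TestModeratedT:
    def test_equal_means_moderation_off(self):
        x = np.array([[1.0, 2.0, 1.0, 2.0]])
        mask = np.array([True, True, False, False])
        res = ea.moderated_ttest(x, mask, moderation=False)
        assert res[0].t_mod == 0.0 and res[0].p == 1.0

    def test_moderation_off_equals_pooled_t(self, rng):
        X = rng.normal(size=(30, 8))
        mask = np.zeros(8, bool)
        mask[:4] = True
        res = ea.moderated_ttest(X, mask, moderation=False)
        for i, r in enumerate(res):
            t_ref, p_ref = stats.ttest_ind(X[i, mask], X[i, ~mask], equal_var=True)
            assert r.t_mod == pytest.approx(t_ref, abs=1e-12)
            assert r.p == pytest.approx(p_ref, abs=1e-12)

    def test_hand_computed_toy(self):
        # groups (1, 3) vs (2, 6): diff=-2, s2=((2)+(8))/2=5, se=sqrt(5*1)= sqrt(5)
        x = np.array([[1.0, 3.0, 2.0, 6.0]])
        mask = np.array([True, True, False, False])
        r = ea.moderated_ttest(x, mask, moderation=False)[0]
        assert r.log2fc == pytest.approx(-2.0)
        assert r.t_mod == pytest.approx(-2.0 / np.sqrt(5.0))

    def test_null_calibration(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(2000, 20))
        mask = np.zeros(20, bool)
        mask[:10] = True
        res = ea.moderated_ttest(X, mask, moderation=True)
        rejection = np.mean([r.p < 0.05 for r in res])
        assert abs(rejection - 0.05) <= 0.01

    def test_small_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            ea.moderated_ttest(rng.normal(size=(5, 3)),
                               np.array([True, False, False]))

    def test_all_zero_variance_error(self):
        X = np.ones((4, 6))
        mask = np.array([True] * 3 + [False] * 3)
        with pytest.raises(ValueError):
            ea.moderated_ttest(X, mask, moderation=True)


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(ea.bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(ea.bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single(self):
        np.testing.assert_allclose(ea.bh_fdr([0.2]), [0.2])

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ea.bh_fdr([0.5, 1.5])

    def test_matches_brute_force_definition(self, rng):
        def brute(p):
            p = np.asarray(p)
            m = len(p)
            q = np.empty(m)
            for i in range(m):
                # q_i = min over all thresholds t >= p_i of p_t * m / rank(t)
                candidates = []
                for j in range(m):
                    if p[j] >= p[i]:
                        rank = (p <= p[j]).sum()
                        candidates.append(p[j] * m / rank)
                q[i] = min(min(candidates), 1.0)
            return q

        for _ in range(100):
            p = rng.random(int(rng.integers(1, 30)))
            np.testing.assert_allclose(ea.bh_fdr(p), brute(p), atol=1e-12)


class TestSubtypeDE:
    # one-vs-rest: a shift of 4 in one subtype of four leaks 4/3 into the
    # other subtypes' fold changes, so lfc_min=2 separates planted from leak
    def make_matrix(self, rng, shifts):
        features = [f"f{i}" for i in range(40)]
        labels = [s for s in "ABCD" for _ in range(10)]
        values = rng.normal(0, 0.3, size=(40, 40)) + 5.0
        for (feat, sub), delta in shifts.items():
            cols = [j for j, s in enumerate(labels) if s == sub]
            values[feat, cols] += delta
        return ExpressionMatrix(features, [f"s{j}" for j in range(40)],
                                values, "log2"), labels

    def test_planted_features_recovered(self, rng):
        shifts = {(i, "A"): 4.0 for i in range(10)}
        matrix, labels = self.make_matrix(rng, shifts)
        out = ea.subtype_de_summary(matrix, labels, alpha=0.05, lfc_min=2.0)
        assert out["de_sets"]["A"] == {f"f{i}" for i in range(10)}
        assert out["de_sets"]["C"] == set()

    def test_alpha_zero_empty(self, rng):
        matrix, labels = self.make_matrix(rng, {(0, "A"): 4.0})
        out = ea.subtype_de_summary(matrix, labels, alpha=0.0)
        assert all(not s for s in out["de_sets"].values())

    def test_shared_features_intersection(self, rng):
        shifts = {}
        for i in range(3):          # shared between A and B
            shifts[(i, "A")] = 4.0
            shifts[(i, "B")] = 4.0
        for i in range(3, 6):
            shifts[(i, "A")] = 4.0
        matrix, labels = self.make_matrix(rng, shifts)
        out = ea.subtype_de_summary(matrix, labels, alpha=0.05, lfc_min=2.0)
        assert out["pairwise"][("A", "B")] == {f"f{i}" for i in range(3)}


# ---------------------------------------------------------------------------
# qPCR helpers
# ---------------------------------------------------------------------------

class TestDdct:
    def test_all_equal(self):
        assert ea.ddct(20, 20, 20, 20) == 1.0

    def test_one_cycle_up(self):
        assert ea.ddct(21, 20, 20, 20) == 0.5

    def test_one_cycle_down(self):
        assert ea.ddct(19, 20, 20, 20) == 2.0

    def test_constant_shift_invariance(self, rng):
        base = rng.normal(25, 2, size=4)
        shifted = base + 3.7
        assert ea.ddct(*base) == pytest.approx(ea.ddct(*shifted))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ea.ddct(np.nan, 20, 20, 20)


class TestHalfLife:
    def test_exact_halving(self):
        times = [0, 2, 4, 6, 8]
        expr = [1.0, 0.5, 0.25, 0.125, 0.0625]
        assert ea.estimate_half_life(times, expr) == pytest.approx(2.0)

    def test_constant_series_infinite(self):
        with pytest.warns(UserWarning):
            assert ea.estimate_half_life([0, 2, 4], [1.0, 1.0, 1.0]) == np.inf

    def test_noisy_recovery(self):
        rng = np.random.default_rng(5)
        times = np.array([0.0, 1, 2, 4, 6, 8, 12])
        true = np.exp(-np.log(2) / 4.0 * times)
        noisy = true * np.exp(rng.normal(0, 0.05, size=len(times)))
        est = ea.estimate_half_life(times, noisy)
        assert 3.5 <= est <= 4.5

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ea.estimate_half_life([0, 1, 2], [1.0, 0.0, 0.5])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ea.estimate_half_life([0, 1], [1.0, 0.5])
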