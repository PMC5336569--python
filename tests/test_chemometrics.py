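"""Chemometrics: PCA/SVD equivalence, target rotation recovery against a
grid-search oracle, OPLS properties and NIPALS-PLS equivalence, grouped Q2
behavior, OPLS-DA separation, and Ward linkage against brute force."""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as SkPCA

from acclimet.chemometrics import (OPLS, OPLSDA, PCAModel, cross_val_accuracy,
                                   fit_pca, grouped_q2, hca_ward,
                                   rotate_to_target)
from acclimet.errors import ValidationError

RNG = np.random.default_rng(20161207)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def test_rank_one_matrix_has_unit_first_component(self):
        x = np.outer(np.arange(1.0, 6.0), np.linspace(1, 2, 8))
        p = PCAModel(n_components=2, center=False).fit(x)
        assert p.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction_and_sklearn_agreement(self):
        for _ in range(10):
            x = RNG.normal(size=(20, 50))
            k = 19
            p = PCAModel(n_components=k, center=True).fit(x)
            xc = x - x.mean(axis=0)
            np.testing.assert_allclose(p.scores_ @ p.loadings_, xc, atol=1e-8)
            oracle = SkPCA(n_components=k, svd_solver="full").fit(xc)
            cos = np.abs(np.sum(p.loadings_ * oracle.components_, axis=1))
            np.testing.assert_allclose(cos, 1.0, atol=1e-8)

    def test_centered_scores_have_zero_mean(self):
        p = PCAModel(n_components=3).fit(RNG.normal(size=(15, 9)))
        np.testing.assert_allclose(p.scores_.mean(axis=0), 0.0, atol=1e-10)

    def test_loadings_orthonormal(self):
        p = PCAModel(n_components=5).fit(RNG.normal(size=(30, 12)))
        np.testing.assert_allclose(p.loadings_ @ p.loadings_.T, np.eye(5),
                                   atol=1e-8)

    def test_excess_components_error_names_rank(self):
        with pytest.raises(ValidationError, match="rank 4"):
            PCAModel(n_components=5).fit(RNG.normal(size=(5, 50)))


# ---------------------------------------------------------------------------
# target rotation
# ---------------------------------------------------------------------------

def _fake_pca(scores: np.ndarray) -> PCAModel:
    p = PCAModel(n_components=scores.shape[1])
    p.scores_ = scores
    q, _ = np.linalg.qr(RNG.normal(size=(40, scores.shape[1])))
    p.loadings_ = q.T
    p.mean_ = None
    return p


def _grid_oracle(S: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    """0.01-degree grid search for the in-plane direction maximizing
    |Pearson r| with the target."""
    best = (-1.0, 0.0)
    for deg in np.arange(0.0, 180.0, 0.01):
        a = np.radians(deg)
        s = S @ np.array([np.cos(a), np.sin(a)])
        r = abs(stats.pearsonr(s, t)[0])
        if r > best[0]:
            best = (r, deg)
    return best[1], best[0]


class TestRotation:
    def test_identity_when_pc1_is_the_target(self):
        t = np.repeat([12, 15.5, 18, 20, 22, 25, 27, 29.5, 31, 32], 3)
        s1 = (t - t.mean()) * 2.0
        s2 = RNG.normal(size=t.size)
        s2 -= s2 @ s1 / (s1 @ s1) * s1  # orthogonalize
        rot = rotate_to_target(_fake_pca(np.column_stack([s1, s2])), t)
        assert abs(rot.angle) % np.pi == pytest.approx(0.0, abs=1e-6)
        assert rot.r_linear == pytest.approx(1.0)

    def test_planted_30_degree_mixture_recovered_against_grid_oracle(self):
        t = np.repeat([12, 15.5, 18, 20, 22, 25, 27, 29.5, 31, 32], 5)
        lin = t - t.mean()
        quad = (t - 22.0) ** 2
        quad = quad - quad.mean()
        latent = np.column_stack([lin / lin.std(), quad / quad.std()])
        a = np.radians(30.0)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        S = latent @ R.T
        rot = rotate_to_target(_fake_pca(S), t)
        grid_deg, grid_r = _grid_oracle(S, t)
        found = np.degrees(rot.angle) % 180.0
        assert min(abs(found - grid_deg), 180 - abs(found - grid_deg)) <= 0.5
        assert rot.r_linear >= 0.999 * grid_r and rot.r_linear >= 0.999

    def test_rotated_correlation_dominates_both_components(self):
        for _ in range(100):
            S = RNG.normal(size=(24, 2))
            t = RNG.normal(size=24)
            rot = rotate_to_target(_fake_pca(S), t)
            r1 = abs(stats.pearsonr(S[:, 0], t)[0])
            r2 = abs(stats.pearsonr(S[:, 1], t)[0])
            assert rot.r_linear + 1e-10 >= max(r1, r2)

    def test_rotated_loadings_stay_orthonormal(self):
        rot = rotate_to_target(_fake_pca(RNG.normal(size=(30, 2))),
                               RNG.normal(size=30))
        G = np.vstack([rot.linear_loadings, rot.ushape_loadings])
        np.testing.assert_allclose(G @ G.T, np.eye(2), atol=1e-10)

    def test_zero_variance_target_rejected(self):
        with pytest.raises(ValidationError):
            rotate_to_target(_fake_pca(RNG.normal(size=(10, 2))), np.ones(10))


# ---------------------------------------------------------------------------
# OPLS
# ---------------------------------------------------------------------------

class TestOPLS:
    def test_noiseless_latent_response_fully_explained(self):
        y = RNG.normal(size=30)
        v = RNG.normal(size=10)
        x = np.outer(y, v)  # y spans the only X variation
        m = OPLS(n_orthogonal=0).fit(x, y)
        assert m.R2Y_ >= 0.999

    def test_zero_orthogonal_matches_single_component_pls_scores(self):
        for _ in range(5):
            x = RNG.normal(size=(25, 40))
            y = x @ RNG.normal(size=40) + RNG.normal(size=25)
            m = OPLS(n_orthogonal=0).fit(x, y)
            oracle = PLSRegression(n_components=1, scale=False).fit(x, y)
            a = m.scores_ / np.linalg.norm(m.scores_)
            b = oracle.x_scores_.ravel()
            b /= np.linalg.norm(b)
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_orthogonal_scores_uncorrelated_with_y(self):
        x = RNG.normal(size=(40, 60))
        y = x @ RNG.normal(size=60) + RNG.normal(size=40)
        m = OPLS(n_orthogonal=3).fit(x, y)
        yc = y - y.mean()
        for t_o in m.orth_scores_:
            assert abs(stats.pearsonr(t_o, yc)[0]) < 1e-8

    def test_orthogonal_filtering_never_reduces_r2y(self):
        x = RNG.normal(size=(30, 50))
        y = x @ RNG.normal(size=50) + RNG.normal(size=30) * 3
        base = OPLS(n_orthogonal=0).fit(x, y).R2Y_
        for k in (1, 2, 3):
            assert OPLS(n_orthogonal=k).fit(x, y).R2Y_ >= base - 1e-10

    def test_component_notation_and_rank_guard(self):
        x = RNG.normal(size=(12, 30))
        y = x @ RNG.normal(size=30)
        assert OPLS(n_orthogonal=2).fit(x, y).A_ == "1+2"
        with pytest.raises(ValidationError):
            OPLS(n_orthogonal=11).fit(x, y)


class TestGroupedQ2:
    def test_noiseless_limit_close_to_one(self):
        y = RNG.normal(size=40) * 3
        x = np.outer(y, RNG.normal(size=20)) + 0.01 * RNG.normal(size=(40, 20))
        groups = np.repeat(np.arange(8), 5)
        assert grouped_q2(x, y, groups, n_orth=0) >= 0.99

    def test_invariant_to_group_relabeling_and_sample_order(self):
        x = RNG.normal(size=(30, 15))
        y = x @ RNG.normal(size=15) + RNG.normal(size=30)
        groups = np.repeat(np.arange(6), 5)
        q = grouped_q2(x, y, groups, n_orth=1)
        relabeled = np.array([f"g{v}" for v in groups])
        assert grouped_q2(x, y, relabeled, n_orth=1) == pytest.approx(q)
        perm = RNG.permutation(30)
        assert grouped_q2(x[perm], y[perm], groups[perm], n_orth=1) == \
            pytest.approx(q, abs=1e-10)

    def test_degenerate_grouping_rejected(self):
        x = RNG.normal(size=(10, 5))
        y = x[:, 0]
        with pytest.raises(ValidationError):
            grouped_q2(x, y, np.repeat([1, 2], 5))


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

class TestOPLSDA:
    def test_spiked_column_separates_two_classes(self):
        x = RNG.normal(size=(30, 20))
        classes = np.array(["a"] * 15 + ["b"] * 15)
        x[:15, 7] += 8.0
        m = OPLSDA(n_predictive=1, n_orthogonal=0).fit(x, classes)
        s = m.scores_[:, 0]
        assert max(s[:15].min(), s[15:].min()) > min(s[:15].max(), s[15:].max()) \
            or s[:15].max() < s[15:].min() or s[15:].max() < s[:15].min()

    def test_indicator_shape_and_condition_means(self, default_bundle):
        # default design: 20 sex x temperature classes over 100 samples
        assert len(default_bundle.dendrogram_labels) == 20

    def test_small_class_rejected(self):
        x = RNG.normal(size=(5, 4))
        with pytest.raises(ValidationError, match="< 2 samples"):
            OPLSDA().fit(x, np.array(["a", "a", "a", "a", "b"]))

    def test_shuffled_labels_predict_at_chance(self):
        x = RNG.normal(size=(40, 30))
        x[:20, 3] += 5.0
        accs = []
        for rep in range(20):
            labels = np.array(["a", "b", "c", "d"] * 10)
            shuffled = RNG.permutation(labels)
            accs.append(cross_val_accuracy(x, shuffled, n_pred=2, n_orth=0,
                                           n_splits=4, seed=rep))
        assert abs(np.mean(accs) - 0.25) < 0.12  # chance = 1/4


# ---------------------------------------------------------------------------
# Ward linkage vs brute force
# ---------------------------------------------------------------------------

def brute_force_ward(points: np.ndarray):
    """Greedy Ward agglomeration by explicit centroid bookkeeping."""
    clusters = {i: [i] for i in range(len(points))}
    merges = []
    nxt = len(points)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pa, pb = points[clusters[a]], points[clusters[b]]
            na, nb = len(pa), len(pb)
            d2 = 2.0 * na * nb / (na + nb) * \
                float(np.sum((pa.mean(0) - pb.mean(0)) ** 2))
            if best is None or d2 < best[0]:
                best = (d2, a, b)
        d2, a, b = best
        merges.append((frozenset(clusters[a]) | frozenset(clusters[b]),
                       np.sqrt(d2)))
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        nxt += 1
    return merges


class TestWard:
    def test_identical_points_merge_at_zero_height(self):
        d = hca_ward(np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]]),
                     ["a", "b", "c"])
        assert d.merges[0, 2] == pytest.approx(0.0)

    def test_three_point_merge_order(self):
        d = hca_ward(np.array([[0.0], [1.0], [10.0]]), ["x", "y", "z"])
        first = {d.labels[int(d.merges[0, 0])], d.labels[int(d.merges[0, 1])]}
        assert first == {"x", "y"}

    def test_matches_brute_force_on_small_point_sets(self):
        for trial in range(10):
            n = int(RNG.integers(4, 9))
            pts = RNG.normal(size=(n, 3))
            labels = [f"p{i}" for i in range(n)]
            d = hca_ward(pts, labels)
            oracle = brute_force_ward(pts)
            # reconstruct merged leaf sets from the linkage matrix
            members = {i: frozenset([i]) for i in range(n)}
            for row_idx, row in enumerate(d.merges):
                a, b = int(row[0]), int(row[1])
                merged = members[a] | members[b]
                members[n + row_idx] = merged
                exp_set, exp_h = oracle[row_idx]
                assert merged == exp_set
                assert row[2] == pytest.approx(exp_h, rel=1e-8)

    def test_heights_monotone_nondecreasing(self):
        d = hca_ward(RNG.normal(size=(12, 4)), [f"p{i}" for i in range(12)])
        assert np.all(np.diff(d.merges[:, 2]) >= -1e-12)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError):
            hca_ward(np.zeros((2, 2)), ["a", "a"])

    def test_newick_roundtrip(self):
        import io as _io

        from Bio import Phylo

        d = hca_ward(RNG.normal(size=(6, 2)), list("abcdef"))
        tree = Phylo.read(_io.StringIO(d.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == list("abcdef")
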