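"""Chemometrics: PCA/HCA/PLSR against independent oracles, merit algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volatilo import chemometrics as chem
from volatilo import preprocess as pp
from volatilo import synthetic_data as sd


# --------------------------------------------------------------------------
# independent oracles

def ward_naive(points):
    """O(n^3) Ward agglomeration via the Lance-Williams update.

    Returns the sorted merge heights (scipy convention: Euclidean merge
    distance).  Ties are broken by the lowest cluster-index pair.
    """
    pts = [np.asarray(p, dtype=float) for p in points]
    n = len(pts)
    sizes = {i: 1 for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(np.linalg.norm(pts[i] - pts[j]))
    active = set(range(n))
    next_id = n
    heights = []
    while len(active) > 1:
        (i, j) = min(d, key=lambda k: (d[k], k))
        h = d[(i, j)]
        heights.append(h)
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in sorted(active - {i, j}):
            nk = sizes[k]
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            dij = h
            val = np.sqrt(((ni + nk) * dik**2 + (nj + nk) * djk**2
                           - nk * dij**2) / (ni + nj + nk))
            d[(k, new)] = float(val)
        for key in list(d):
            if i in key or j in key:
                del d[key]
        active -= {i, j}
        active.add(new)
        sizes[new] = ni + nj
    return np.array(heights)


# --------------------------------------------------------------------------
# alpha groups

class TestAlphaGroups:
    @pytest.mark.parametrize("alpha,label", [
        (2.0, "low"), (6.9, "low"), (6.94, "low"),
        (6.96, "middle"), (7.0, "middle"), (10.0, "middle"),
        (10.1, "high"), (15.0, "high"), (18.1, "high"),
    ])
    def test_thresholds(self, alpha, label):
        assert chem.assign_alpha_group(alpha) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chem.assign_alpha_group(-0.1)


# --------------------------------------------------------------------------
# PCA

class TestPCA:
    def test_rank_one_matrix_explained_by_single_component(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([0.5, -1.0, 2.0])
        model = chem.pca_fit(np.outer(u, v), n_components=2)
        assert model.explained_variance_pct[0] == pytest.approx(100.0)

    @pytest.mark.parametrize("n,p,seed", [(3, 3, 0), (8, 5, 1), (20, 50, 2),
                                          (12, 4, 3)])
    def test_matches_eigendecomposition_oracle(self, n, p, seed):
        X = np.random.default_rng(seed).normal(size=(n, p))
        k = min(n - 1, p, 3)
        model = chem.pca_fit(X, n_components=k)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (n - 1))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for c in range(k):
            dot = abs(model.loadings[c] @ evecs[:, c])
            assert dot == pytest.approx(1.0, abs=1e-8)
        ev_pct = evals[:k] / evals.sum() * 100
        np.testing.assert_allclose(model.explained_variance_pct, ev_pct,
                                   rtol=1e-8)

    def test_scores_are_uncorrelated(self):
        X = np.random.default_rng(7).normal(size=(15, 6))
        model = chem.pca_fit(X, n_components=4)
        cov = np.cov(model.scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            chem.pca_fit(np.ones((4, 3)), n_components=4)


# --------------------------------------------------------------------------
# Ward HCA

class TestWardHCA:
    def test_identical_points_merge_at_zero_height(self):
        S = np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        res = chem.hca_ward(S, k=None)
        assert res.merges[0, 2] == pytest.approx(0.0)

    def test_two_tight_triads_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.01, (3, 2))
        b = rng.normal(5, 0.01, (3, 2)) + [5, 0]
        res = chem.hca_ward(np.vstack([a, b]), k=None)
        labels = res.cut(n_clusters=2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    @pytest.mark.parametrize("n,seed", [(4, 0), (6, 1), (8, 2), (8, 3), (7, 4)])
    def test_merge_heights_match_naive_agglomeration(self, n, seed):
        pts = np.random.default_rng(seed).normal(size=(n, 3))
        res = chem.hca_ward(pts, k=None)
        np.testing.assert_allclose(np.sort(res.merges[:, 2]),
                                   np.sort(ward_naive(pts)), rtol=1e-9)

    def test_heights_non_decreasing(self):
        pts = np.random.default_rng(9).normal(size=(12, 4))
        res = chem.hca_ward(pts, k=None)
        assert np.all(np.diff(res.merges[:, 2]) >= -1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            chem.hca_ward(np.ones((1, 3)))


# --------------------------------------------------------------------------
# train/test split

class TestSplit:
    def test_paper_sized_split(self):
        y = np.linspace(1, 18.1, 65)
        train, test = chem.split_train_test(y, n_test=10, seed=0)
        assert len(train) == 55 and len(test) == 10
        assert not set(train) & set(test)

    def test_extremes_stay_in_training(self):
        y = np.random.default_rng(1).uniform(1, 18, 40)
        train, test = chem.split_train_test(y, n_test=8, seed=3)
        assert np.argmin(y) in train and np.argmax(y) in train
        assert y[test].min() > y.min() and y[test].max() < y.max()

    def test_test_set_covers_range(self):
        y = np.linspace(0, 1, 65)
        _, test = chem.split_train_test(y, n_test=10, seed=0)
        assert y[test].min() < 0.2 and y[test].max() > 0.8

    def test_deterministic_under_seed(self):
        y = np.random.default_rng(2).uniform(size=30)
        assert np.array_equal(chem.split_train_test(y, 5, seed=7)[1],
                              chem.split_train_test(y, 5, seed=7)[1])

    def test_oversized_test_rejected(self):
        with pytest.raises(ValueError):
            chem.split_train_test(np.arange(5.0), n_test=5)


# --------------------------------------------------------------------------
# PLSR

class TestPLSR:
    def test_single_latent_variable_recovers_univariate_relation(self):
        """With orthogonal feature columns and y proportional to one of
        them, the first weight vector aligns with that column and one
        latent variable reproduces y exactly."""
        rng = np.random.default_rng(0)
        M = rng.normal(size=(12, 5))
        M -= M.mean(axis=0)
        X, _ = np.linalg.qr(M)  # orthonormal, zero-mean columns
        y = 2.0 * X[:, 3] + 1.0
        model = chem.plsr_fit(X, y, n_lv=1)
        assert np.abs(y - model.predict(X)).max() < 1e-8

    def test_full_rank_pls_equals_ordinary_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = chem.plsr_fit(X, y, n_lv=4)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        pred_ols = Xc @ beta + y.mean()
        np.testing.assert_allclose(model.predict(X), pred_ols, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_pls_implementation(self, seed):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        for n_lv in (1, 2, 3):
            mine = chem.plsr_fit(X, y, n_lv)
            ref = PLSRegression(n_components=n_lv, scale=False).fit(X, y)
            np.testing.assert_allclose(mine.coef, ref.coef_.ravel(), atol=1e-6)

    def test_excess_latent_variables_raise_rank_error(self):
        X = np.random.default_rng(2).normal(size=(5, 3))
        y = np.random.default_rng(3).normal(size=5)
        with pytest.raises(chem.RankError):
            chem.plsr_fit(X, y, n_lv=5)

    def test_pareto_parameters_stored_with_model(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 6))
        y = X @ rng.normal(size=6)
        model = chem.plsr_fit(X, y, n_lv=3, pareto=True)
        assert model.scaler.pareto
        # prediction on the training matrix reproduces fitted values
        np.testing.assert_allclose(model.predict(X), model.predict(X.copy()))


class TestSelectLV:
    def test_noise_free_rank_two_relation_chooses_two(self):
        rng = np.random.default_rng(0)
        T = rng.normal(size=(40, 2))
        P = rng.normal(size=(2, 10))
        X = T @ P
        y = T @ np.array([1.0, -2.0])
        sel = chem.select_lv(X[:30], y[:30], X[30:], y[30:], lv_max=6)
        assert sel.n_lv == 2

    def test_pure_noise_warns_and_returns_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 8))
        y = rng.normal(size=40)
        with pytest.warns(UserWarning):
            sel = chem.select_lv(X[:30], y[:30], X[30:], y[30:], lv_max=5)
        assert sel.flat_flag
        assert sel.n_lv == 1

    def test_calibration_error_non_increasing(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + rng.normal(0, 0.5, 30)
        sel = chem.select_lv(X[:22], y[:22], X[22:], y[22:], lv_max=8)
        assert np.all(np.diff(sel.rmsec) <= 1e-9)


# --------------------------------------------------------------------------
# figures of merit

class TestFiguresOfMerit:
    def test_hand_worked_vector_example(self):
        """y = (1,2,3), pred = (1.5,2,2.5): RMSEP = sqrt(1/6), Bias = 0,
        SEP = 0.5, RE = 100 sqrt(0.5/14)."""
        rep = chem.figures_of_merit([1, 2, 3], [1, 2, 3],
                                    [1, 2, 3], [1.5, 2.0, 2.5])
        assert rep.rmsep == pytest.approx(np.sqrt(1 / 6), rel=1e-12)
        assert rep.bias == pytest.approx(0.0, abs=1e-12)
        assert rep.sep == pytest.approx(0.5, rel=1e-12)
        assert rep.re_pct == pytest.approx(100 * np.sqrt(0.5 / 14), rel=1e-12)

    def test_perfect_prediction_gives_zero_errors(self):
        y = np.array([2.0, 4.0, 8.0])
        rep = chem.figures_of_merit(y, y, y, y)
        assert rep.r2 == 1.0
        assert rep.rmsec == rep.rmsep == rep.bias == rep.sep == rep.re_pct == 0.0

    def test_constant_shift_is_pure_bias(self):
        y = np.array([1.0, 2.0, 5.0, 7.0])
        rep = chem.figures_of_merit(y, y, y, y + 0.4)
        assert rep.bias == pytest.approx(-0.4)
        assert rep.sep == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(2, 30), st.integers(0, 10_000))
    def test_error_decomposition_identity(self, n, seed):
        """rmsep^2 = bias^2 + sep^2 (n-1)/n for any residual vector."""
        rng = np.random.default_rng(seed)
        y = rng.normal(5, 2, n)
        pred = y + rng.normal(0, 1, n)
        rep = chem.figures_of_merit(y, y, y, pred)
        assert rep.rmsep**2 == pytest.approx(
            rep.bias**2 + rep.sep**2 * (n - 1) / n, abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chem.figures_of_merit([1, 2], [1], [1, 2], [1, 2])

    def test_single_test_sample_rejected(self):
        with pytest.raises(ValueError):
            chem.figures_of_merit([1, 2], [1, 2], [1], [1])


# --------------------------------------------------------------------------
# Mahalanobis ellipses

class TestMahalanobisEllipse:
    def test_chi_square_threshold_at_97_5_percent(self):
        pts = np.random.default_rng(0).normal(size=(30, 2))
        ell = chem.mahalanobis_ellipse(pts, level=0.975)
        assert ell.threshold == pytest.approx(-2 * np.log(0.025), rel=1e-9)
        assert ell.threshold == pytest.approx(7.378, abs=1e-3)

    def test_isotropic_group_gives_circle_of_known_radius(self):
        base = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        pts = base / np.sqrt(np.cov(base, rowvar=False)[0, 0])  # unit cov
        ell = chem.mahalanobis_ellipse(pts, level=0.975)
        r = np.sqrt(-2 * np.log(0.025))
        assert ell.semi_axes[0] == pytest.approx(r, rel=1e-9)
        assert ell.semi_axes[1] == pytest.approx(r, rel=1e-9)

    def test_center_point_has_zero_distance(self):
        pts = np.random.default_rng(1).normal(size=(10, 2))
        assert chem.squared_mahalanobis(pts, pts.mean(axis=0)) == pytest.approx(0.0)

    def test_degenerate_group_rejected(self):
        line = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(np.linalg.LinAlgError):
            chem.mahalanobis_ellipse(line)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            chem.mahalanobis_ellipse(np.ones((2, 2)))


# --------------------------------------------------------------------------
# loading refolding

class TestRefold:
    def test_refold_matches_matrix_backmap(self):
        x = np.random.default_rng(0).random((6, 4))
        cube = pp.IMSCube(intensities=x, rt_axis=np.arange(6.0),
                          dt_axis=1.0 + 0.1 * np.arange(4.0), sample_id="S")
        m = pp.unfold([cube])
        np.testing.assert_array_equal(chem.refold_loadings(m.X[0], m), x)

    def test_regression_weights_localise_on_the_varying_compound(self):
        """When only myrcene tracks the response, the top PLSR weights sit
        inside myrcene's peak footprints."""
        myrcene = next(c for c in sd.DEFAULT_COMPOUNDS if c.name == "beta-myrcene")
        marker = next(c for c in sd.DEFAULT_COMPOUNDS if c.class_tag == "marker")
        lib = [myrcene, marker]
        cfg = sd.SimConfig(n_samples=10, n_replicates=1, rt_step=0.04, n_dt=128,
                           noise_sd_additive=0.01, noise_sd_multiplicative=0,
                           rt_jitter_sd=0, dt_jitter_sd=0, seed=2)
        samples = sd.make_sample_table(10, seed=2)
        alpha = np.array([s.alpha_acid for s in samples])
        conc = {s.sample_id: {"beta-myrcene":
                              sd.expected_concentration(s.alpha_acid, myrcene)}
                for s in samples}
        cubes = sd.simulate_ims_cube(samples, conc, cfg, lib)
        m = pp.unfold(pp.average_by_sample(pp.preprocess_ims(cubes)))
        model = chem.plsr_fit(m.X, alpha, n_lv=1)
        tops = chem.top_features(model.coef, m, n_top=10)
        for rt, dt, _ in tops:
            assert abs(rt - myrcene.rt_true) < 0.3
            assert min(abs(dt - d) for d in (1.0, *myrcene.dt_rel_species)) < 0.03

    def test_top_features_gain_library_annotations(self):
        """A weight map peaked at the alpha-humulene reference coordinates
        is annotated with that compound's name."""
        rt = np.arange(12.0, 13.6, 0.02)
        dt = np.linspace(1.0, 2.0, 101)
        w = np.outer(np.exp(-0.5 * ((rt - 12.82) / 0.05) ** 2),
                     np.exp(-0.5 * ((dt - 1.552) / 0.01) ** 2))
        cube = pp.IMSCube(intensities=w, rt_axis=rt, dt_axis=dt,
                          sample_id="S", dt_normalized=True)
        m = pp.unfold([cube])
        out = chem.annotate_top_features(m.X[0], m, n_top=3)
        assert out[0][3] == "alpha-humulene"

    def test_mismatched_vector_rejected(self):
        cube = pp.IMSCube(intensities=np.ones((3, 3)), rt_axis=np.arange(3.0),
                          dt_axis=1.0 + 0.1 * np.arange(3.0), sample_id="S")
        m = pp.unfold([cube])
        with pytest.raises(ValueError):
            chem.refold_loadings(np.ones(5), m)
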