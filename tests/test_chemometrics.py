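import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as SkPCA
from sklearn.metrics import silhouette_score

import ucnmr as u
from ucnmr.processing import BucketTable


def _scale(X):
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / np.sqrt(sd)


def _toy_problem(n=32, p=40, effect=3.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["ctrl"] * (n // 2) + ["case"] * (n - n // 2))
    X = rng.normal(size=(n, p))
    X[:, 5] += np.where(y == "case", effect, 0.0)
    return _scale(X), y


class TestPCA:
    def test_rank_one_matrix_fully_explained_by_first_component(self):
        t = np.linspace(-1, 1, 20)[:, None]
        v = np.array([[1.0, 2.0, -1.0, 0.5]])
        model = u.fit_pca(t @ v, n_components=2)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 12))
        ours = u.fit_pca(X, n_components=4)
        oracle = SkPCA(n_components=4).fit(X)
        for j in range(4):
            a = ours.loadings[:, j]
            b = oracle.components_[j]
            sign = np.sign(a @ b)
            assert np.allclose(a, sign * b, atol=1e-6)
        assert np.allclose(
            ours.explained_variance_fraction, oracle.explained_variance_ratio_, atol=1e-6
        )

    def test_seeded_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 20 + [1] * 20)
        X = rng.normal(size=(40, 30))
        X[:, 0] += y * 8.0
        model = u.fit_pca(_scale(X), n_components=2)
        assert silhouette_score(model.scores[:, :1], y) > 0.5

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            u.fit_pca(np.random.default_rng(0).normal(size=(5, 10)), n_components=5)


class TestOPLSDA:
    def test_perfect_predictor_column_dominates(self):
        Xs, y = _toy_problem(effect=8.0)
        model = u.fit_oplsda(Xs, y, rng=np.random.default_rng(0))
        assert np.argmax(np.abs(model.w)) == 5
        _, calls, _ = u.predict_oplsda(model, Xs)
        assert np.all(calls == y)
        assert abs(np.linalg.norm(model.w) - 1.0) < 1e-12

    def test_zero_ortho_equals_pls1_oracle(self):
        Xs, y = _toy_problem(effect=2.0, seed=7)
        y01 = (y == "case").astype(float)  # "case" < "ctrl" alphabetically
        model = u.fit_oplsda(Xs, y, n_ortho=0, positive_class="case",
                             rng=np.random.default_rng(0))
        yhat, _, _ = u.predict_oplsda(model, Xs)
        oracle = PLSRegression(n_components=1, scale=False).fit(Xs, y01)
        assert np.allclose(yhat, oracle.predict(Xs).ravel(), atol=1e-8)

    def test_orthogonal_structure_detected_and_helpful(self):
        # construction in the spirit of the original O-PLS papers: a strong
        # structured component orthogonal to y inflates PLS1 error; the
        # orthogonal filter should absorb it and improve internal Q2
        rng = np.random.default_rng(11)
        n, p = 48, 60
        y = np.array(["a"] * 24 + ["b"] * 24)
        y01 = (y == "b").astype(float)
        yc = y01 - y01.mean()
        signal_dir = np.zeros(p); signal_dir[0] = 1.0
        ortho_dir = np.zeros(p); ortho_dir[1:6] = 1.0
        t_ortho = rng.normal(size=n) * 4.0
        t_ortho -= (t_ortho @ yc) / (yc @ yc) * yc  # orthogonal to the response
        X = np.outer(yc, signal_dir) * 2.0 + np.outer(t_ortho, ortho_dir)
        X += rng.normal(size=(n, p)) * 0.3
        Xs = _scale(X)
        model = u.fit_oplsda(Xs, y, rng=np.random.default_rng(1))
        assert model.n_ortho >= 1
        assert model.q2_trace[model.n_ortho] >= model.q2_trace[0]

    def test_predictions_invariant_along_removed_directions(self):
        Xs, y = _toy_problem(effect=4.0, seed=2)
        model = u.fit_oplsda(Xs, y, n_ortho=2, rng=np.random.default_rng(0))
        if model.n_ortho == 0:
            pytest.skip("no orthogonal component extracted from this draw")
        base, _, _ = u.predict_oplsda(model, Xs)
        perturbed = Xs + 3.7 * np.outer(np.ones(len(Xs)), model.P_o[:, 0])
        moved, _, _ = u.predict_oplsda(model, perturbed)
        assert np.allclose(base, moved, atol=1e-8)

    def test_sample_at_threshold_is_borderline(self):
        Xs, y = _toy_problem(effect=6.0)
        model = u.fit_oplsda(Xs, y, rng=np.random.default_rng(0))
        # construct a row whose prediction lands exactly on the threshold
        direction = model.w * model.c
        x = direction * (model.decision_threshold - model.y_mean) / (direction @ direction)
        _, _, borderline = u.predict_oplsda(model, x[None, :])
        assert borderline[0]

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        with pytest.raises(ValueError):
            u.fit_oplsda(X, ["a"] * 10, rng=np.random.default_rng(0))

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            u.fit_oplsda(np.zeros((10, 5)), ["a"] * 5 + ["b"] * 5,
                         n_ortho=0, rng=np.random.default_rng(0))

    def test_dimension_mismatch_rejected(self):
        Xs, y = _toy_problem()
        model = u.fit_oplsda(Xs, y, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="dimension"):
            u.predict_oplsda(model, Xs[:, :10])


class TestVIP:
    def test_informative_column_has_max_vip_and_normalization(self):
        Xs, y = _toy_problem(effect=6.0)
        model = u.fit_oplsda(Xs, y, rng=np.random.default_rng(0))
        vip = u.compute_vip(model)
        assert np.argmax(vip) == 5
        assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-6)
        assert np.all(vip >= 0)

    def test_permutation_equivariance(self):
        Xs, y = _toy_problem(seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(Xs.shape[1])
        m1 = u.fit_oplsda(Xs, y, n_ortho=0, rng=np.random.default_rng(1))
        m2 = u.fit_oplsda(Xs[:, perm], y, n_ortho=0, rng=np.random.default_rng(1))
        assert np.allclose(u.compute_vip(m1)[perm], u.compute_vip(m2), atol=1e-10)


class TestVariableSelection:
    def _bucket_table(self, values):
        return BucketTable(values=values, bucket_centers=np.arange(values.shape[1], dtype=float),
                           sample_ids=[f"s{i}" for i in range(values.shape[0])])

    def test_null_data_selects_few_variables(self):
        picked = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = rng.random((30, 25)) + 0.5
            table = self._bucket_table(values)
            labels = np.array(["a"] * 15 + ["b"] * 15)
            scaled, scaler = u.pareto_scale(table)
            model = u.fit_oplsda(scaled, labels, scaler=scaler, n_ortho=0,
                                 rng=np.random.default_rng(seed))
            report = u.select_discriminatory_variables(
                model, table, labels, n_boot=200, rng=np.random.default_rng(seed)
            )
            picked.append(report["selected"].mean())
        # expectation is <= 5%; allow Monte-Carlo error (selections are
        # correlated within a run, effective n ~ 100 -> SE ~ 2%)
        assert np.mean(picked) <= 0.05 + 0.04
        assert max(picked) <= 0.25

    def test_seeded_effect_cohort_selects_myo_inositol_upward(
        self, effect_cohort, annotation
    ):
        table, labels = effect_cohort
        scaled, scaler = u.pareto_scale(table)
        model = u.fit_oplsda(scaled, labels, scaler=scaler,
                             rng=np.random.default_rng(0), positive_class="high")
        report = u.select_discriminatory_variables(
            model, table, labels, annotation=annotation,
            rng=np.random.default_rng(0), case_class="high",
        )
        row = report[report["metabolite"] == "myo-inositol"].iloc[0]
        assert row["selected"]
        assert row["percent_difference"] > 0
        ch2 = report[report["metabolite"] == "(-CH2-)n"].iloc[0]
        assert ch2["selected"] and ch2["percent_difference"] < 0

    def test_unknown_annotation_rejected(self):
        table = self._bucket_table(np.random.default_rng(0).random((10, 5)) + 0.5)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        scaled, scaler = u.pareto_scale(table)
        model = u.fit_oplsda(scaled, labels, scaler=scaler, n_ortho=0,
                             rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="unknown buckets"):
            u.select_discriminatory_variables(
                model, table, labels, annotation={"ghost": 99},
                rng=np.random.default_rng(0),
            )


class TestPercentDifference:
    def _table(self, col_case, col_ctrl):
        values = np.array([[v] for v in col_ctrl + col_case])
        return BucketTable(values=values, bucket_centers=np.array([1.0]),
                           sample_ids=[f"s{i}" for i in range(len(values))]), \
            np.array(["ctrl"] * len(col_ctrl) + ["case"] * len(col_case))

    def test_arithmetic(self):
        table, labels = self._table([1.15, 1.15], [1.0, 1.0])
        got = u.percent_difference(table, labels, 0, case_label="case", control_label="ctrl")
        assert got == pytest.approx(15.0)

    def test_identical_groups_zero(self):
        table, labels = self._table([2.0, 2.0], [2.0, 2.0])
        assert u.percent_difference(table, labels, 0, case_label="case",
                                    control_label="ctrl") == 0.0

    def test_decrease_mirrors_lipoprotein_magnitude(self):
        table, labels = self._table([0.64, 0.64], [1.0, 1.0])
        got = u.percent_difference(table, labels, 0, case_label="case", control_label="ctrl")
        assert got == pytest.approx(-36.0)

    def test_zero_control_mean_rejected(self):
        table, labels = self._table([1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="zero"):
            u.percent_difference(table, labels, 0, case_label="case", control_label="ctrl")
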