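import numpy as np
import pandas as pd
import pytest

import germeval as g
from germeval.errors import GermevalError


def _frame(arr, prefix="c"):
    return pd.DataFrame(np.asarray(arr, dtype=float),
                        columns=[f"{prefix}{j}" for j in
                                 range(np.shape(arr)[1])])


@pytest.fixture(scope="module")
def toy4():
    """Two independent balanced binary columns: covariance diag(1/3, 1/3)."""
    return _frame([[0, 0], [1, 0], [0, 1], [1, 1]])


class TestFitPCA:
    def test_balanced_binary_eigenvalues(self, toy4):
        model = g.fit_pca(toy4)
        assert np.allclose(model.eigenvalues, [1 / 3, 1 / 3])
        assert model.total_variance == pytest.approx(2 / 3)

    def test_constant_column_contributes_zero(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 2, (30, 4)).astype(float)
        with_const = np.column_stack([base, np.ones(30)])
        a, b = g.fit_pca(_frame(base)), g.fit_pca(_frame(with_const))
        assert b.eigenvalues[-1] == pytest.approx(0.0, abs=1e-12)
        assert b.total_variance == pytest.approx(a.total_variance)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(1)
        m = _frame(rng.integers(0, 2, (20, 8)))
        model = g.fit_pca(m)
        # independent route: singular values of the centered data
        X = m.to_numpy() - m.to_numpy().mean(axis=0)
        s = np.linalg.svd(X, compute_uv=False)
        oracle = np.zeros(8)
        oracle[:len(s)] = s ** 2 / (20 - 1)
        assert np.allclose(model.eigenvalues, np.sort(oracle)[::-1],
                           atol=1e-10)

    def test_trace_conservation_for_binary_columns(self, survey_matrix):
        model = g.fit_pca(survey_matrix)
        n = survey_matrix.shape[0]
        p = survey_matrix.to_numpy(dtype=float).mean(axis=0)
        expected = np.sum(p * (1 - p) * n / (n - 1))
        assert model.total_variance == pytest.approx(expected, rel=1e-10)

    def test_contribution_rates_sum_to_100(self, survey_matrix):
        model = g.fit_pca(survey_matrix)
        assert model.contribution_rate.sum() == pytest.approx(100.0)
        assert np.all(np.diff(model.cumulative_rate) >= -1e-12)
        assert model.cumulative_rate[-1] == pytest.approx(100.0)

    def test_sign_convention_largest_loading_positive(self, survey_matrix):
        model = g.fit_pca(survey_matrix)
        L = model.loadings.to_numpy()
        peaks = L[np.argmax(np.abs(L), axis=0), np.arange(L.shape[1])]
        assert (peaks > 0).all()

    def test_single_row_errors(self):
        with pytest.raises(GermevalError):
            g.fit_pca(_frame([[0, 1]]))


class TestScores:
    def test_score_variance_equals_eigenvalue(self, survey_matrix):
        model = g.fit_pca(survey_matrix)
        scores = g.component_scores(model, survey_matrix)
        var = scores.to_numpy().var(axis=0, ddof=1)
        assert np.allclose(var, model.eigenvalues, atol=1e-9)
        assert np.allclose(scores.to_numpy().mean(axis=0), 0.0, atol=1e-9)

    def test_mean_row_projects_to_zero(self, toy4):
        model = g.fit_pca(toy4)
        mean_row = _frame([model.column_means.to_numpy()])
        scores = g.component_scores(model, mean_row)
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_projection_matches_oracle(self, toy4):
        model = g.fit_pca(toy4)
        scores = g.component_scores(model, toy4)
        X = toy4.to_numpy() - toy4.to_numpy().mean(axis=0)
        oracle = X @ model.loadings.to_numpy()
        assert np.allclose(scores.to_numpy(), oracle)

    def test_full_reconstruction(self, survey_matrix):
        model = g.fit_pca(survey_matrix)
        scores = g.component_scores(model, survey_matrix)
        X = survey_matrix.to_numpy(dtype=float)
        centered = X - X.mean(axis=0)
        rebuilt = scores.to_numpy() @ model.loadings.to_numpy().T
        assert np.allclose(rebuilt, centered, atol=1e-9)

    def test_row_order_invariance(self, survey_matrix):
        # eigenvectors are only unique within non-degenerate eigenspaces, so
        # compare the leading well-separated components
        model = g.fit_pca(survey_matrix)
        shuffled = survey_matrix.sample(frac=1.0, random_state=3)
        model2 = g.fit_pca(shuffled)
        assert np.allclose(model.eigenvalues, model2.eigenvalues, atol=1e-9)
        lead = model.loadings.to_numpy()[:, :3]
        lead2 = model2.loadings.to_numpy()[:, :3]
        gaps = -np.diff(model.eigenvalues[:4])
        assert (gaps > 1e-6).all()  # distinct, so vectors are comparable
        assert np.allclose(lead, lead2, atol=1e-8)
        scores = g.component_scores(model, survey_matrix)
        scores2 = g.component_scores(model2, shuffled).loc[scores.index]
        assert np.allclose(scores.to_numpy()[:, :3],
                           scores2.to_numpy()[:, :3], atol=1e-8)

    def test_column_mismatch_errors(self, toy4):
        model = g.fit_pca(toy4)
        with pytest.raises(GermevalError):
            g.component_scores(model, toy4.rename(columns={"c0": "z"}))


class TestSelectComponents:
    @pytest.fixture
    def survey_model(self, survey_matrix):
        return g.fit_pca(survey_matrix)

    def test_min_contribution_leading_run(self):
        # contribution profile shaped like the reference survey's PCA
        contrib = np.array([11.108, 6.934, 6.398, 5.847, 5.835])
        model = g.PCAModel(
            column_means=pd.Series(np.zeros(5)),
            eigenvalues=contrib / 100 * 3.0,
            loadings=pd.DataFrame(np.eye(5),
                                  columns=[f"PC{j+1}" for j in range(5)]),
            contribution_rate=contrib,
            cumulative_rate=np.cumsum(contrib),
        )
        assert g.select_components(model, "min_contribution",
                                   threshold=6.0) == [0, 1, 2]

    def test_top_k(self, survey_model):
        assert g.select_components(survey_model, "top_k", k=14) == \
            list(range(14))

    def test_k_zero_errors(self, survey_model):
        with pytest.raises(GermevalError):
            g.select_components(survey_model, "top_k", k=0)

    def test_k_too_large_errors(self, survey_model):
        with pytest.raises(GermevalError):
            g.select_components(survey_model, "top_k",
                                k=survey_model.n_components + 1)
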