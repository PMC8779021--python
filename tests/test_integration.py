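import numpy as np
import pandas as pd
import pytest

import viaquant as vq
from viaquant.errors import ZeroVarianceError
from viaquant.integration import METRIC_COLUMNS, score_distances

from helpers import brute_corr_pca


def _random_metrics(seed, n=6, columns=METRIC_COLUMNS):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, len(columns))),
        index=[f"R{i}" for i in range(n)],
        columns=list(columns),
    )


# ---------------------------------------------------------------------- zscore

def test_zscore_simple_column():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    out = vq.zscore(df)
    np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])


def test_zscore_contract_mean_zero_sd_one():
    df = _random_metrics(0)
    out = vq.zscore(df)
    np.testing.assert_allclose(out.mean(), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.std(ddof=1), 1.0, atol=1e-12)


def test_zscore_two_column_hand_computation():
    df = pd.DataFrame({"a": [2.0, 4.0, 6.0, 8.0], "b": [1.0, 1.0, 3.0, 3.0]})
    out = vq.zscore(df)
    # a: mean 5, sd sqrt(20/3); b: mean 2, sd sqrt(4/3)
    sd_a, sd_b = np.sqrt(20 / 3), np.sqrt(4 / 3)
    np.testing.assert_allclose(out["a"], np.array([-3, -1, 1, 3]) / sd_a)
    np.testing.assert_allclose(out["b"], np.array([-1, -1, 1, 1]) / sd_b)


def test_constant_column_error_names_the_column():
    df = _random_metrics(1)
    df["CAT"] = 5.0
    with pytest.raises(ZeroVarianceError, match="CAT"):
        vq.zscore(df)


# ------------------------------------------------------------------------- pca

def test_two_perfectly_correlated_variables_give_pc1_100_percent():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
    result = vq.pca(vq.zscore(df), k=1)
    assert result.variance_explained[0] == pytest.approx(1.0, abs=1e-12)
    assert result.eigenvalues[0] == pytest.approx(2.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(4))
def test_eigenvalues_and_loadings_match_correlation_eigensolve(seed):
    standardized = vq.zscore(_random_metrics(seed))
    k = 5  # full rank for 6 observations
    result = vq.pca(standardized, k=k)
    w, vecs = brute_corr_pca(standardized.to_numpy())
    np.testing.assert_allclose(result.eigenvalues, w[:k], atol=1e-8)
    for j in range(k):
        # eigenvectors agree up to sign
        dot = abs(float(result.loadings.iloc[:, j] @ vecs[:, j]))
        assert dot == pytest.approx(1.0, abs=1e-8)


def test_full_decomposition_variance_sums_to_one_and_eigensum_to_p():
    standardized = vq.zscore(_random_metrics(3))
    result = vq.pca(standardized, k=5)
    assert result.variance_explained.sum() == pytest.approx(1.0, abs=1e-10)
    assert result.eigenvalues.sum() == pytest.approx(9.0, abs=1e-10)
    assert result.total_variance == pytest.approx(9.0, abs=1e-10)


def test_eigenvalues_descending_and_loadings_orthonormal():
    standardized = vq.zscore(_random_metrics(4))
    result = vq.pca(standardized, k=4)
    assert (np.diff(result.eigenvalues) <= 1e-12).all()
    L = result.loadings.to_numpy()
    np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-10)


def test_scores_reconstruct_the_standardized_matrix():
    standardized = vq.zscore(_random_metrics(5))
    result = vq.pca(standardized, k=5)
    recon = result.scores.to_numpy() @ result.loadings.to_numpy().T
    np.testing.assert_allclose(recon, standardized.to_numpy(), atol=1e-8)


def test_row_reordering_leaves_eigenvalues_and_loadings_unchanged():
    standardized = vq.zscore(_random_metrics(6))
    shuffled = standardized.iloc[[3, 0, 5, 1, 4, 2]]
    a = vq.pca(standardized, k=2)
    b = vq.pca(shuffled, k=2)
    np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)
    np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-10)


def test_sign_convention_is_deterministic_across_runs():
    standardized = vq.zscore(_random_metrics(7))
    results = [vq.pca(standardized, k=2) for _ in range(3)]
    for r in results[1:]:
        np.testing.assert_array_equal(r.loadings.to_numpy(), results[0].loadings.to_numpy())
    for r in results:
        idx = np.abs(r.loadings.to_numpy()).argmax(axis=0)
        assert (r.loadings.to_numpy()[idx, [0, 1]] > 0).all()


@pytest.mark.parametrize("k", [0, 6, 10])
def test_component_count_out_of_range_rejected(k):
    standardized = vq.zscore(_random_metrics(8))
    with pytest.raises(ValueError, match="k must be"):
        vq.pca(standardized, k=k)


def test_planted_two_factor_share_is_recovered():
    metrics, planted = vq.planted_two_factor_metrics(seed=2026)
    result = vq.pca(vq.zscore(metrics), k=2)
    recovered = float(result.variance_explained.sum())
    assert abs(recovered - planted) <= 0.05


# ---------------------------------------------------------------------- biplot

def test_biplot_table_has_one_row_per_variable_and_reactor():
    standardized = vq.zscore(_random_metrics(9))
    table = vq.biplot_table(vq.pca(standardized, k=2))
    assert len(table) == 15
    assert (table["kind"] == "variable").sum() == 9
    assert (table["kind"] == "reactor").sum() == 6


def test_biplot_requires_two_components():
    standardized = vq.zscore(_random_metrics(10))
    with pytest.raises(ValueError, match="2 components"):
        vq.biplot_table(vq.pca(standardized, k=3))


def test_rank_one_toy_puts_all_arrows_on_axis_one():
    base = np.array([1.0, 2.0, 3.0, 4.0])
    df = pd.DataFrame({f"v{i}": (i + 1) * base for i in range(4)})
    table = vq.biplot_table(vq.pca(vq.zscore(df), k=2))
    arrows = table[table["kind"] == "variable"]
    np.testing.assert_allclose(arrows["y"], 0.0, atol=1e-7)
    assert (arrows["x"].abs() > 0.9).all()


def test_score_distances_symmetric_zero_diagonal():
    standardized = vq.zscore(_random_metrics(11))
    d = score_distances(vq.pca(standardized, k=2))
    np.testing.assert_allclose(d, d.T)
    np.testing.assert_allclose(np.diag(d), 0.0)


# ------------------------------------------------------------------ metrics IO

def test_load_metrics_roundtrip_and_validation(tmp_path):
    df = _random_metrics(12)
    path = tmp_path / "metrics.csv"
    df.to_csv(path)
    back = vq.load_metrics(path)
    pd.testing.assert_frame_equal(back, df)

    bad = df.drop(columns=["ROS"])
    bad_path = tmp_path / "bad.csv"
    bad.to_csv(bad_path)
    with pytest.raises(ValueError, match="ROS"):
        vq.load_metrics(bad_path)
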