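"""Standardization and two-component PCA of reactor-level variables.

Nine heterogeneous variables per reactor — TOC removal, cumulative CH4 and
CO2, ecotoxicity, the EST/GST/CAT enzyme activities, ROS generation, and the
fraction of non-viable cells — are z-scored (mean 0, sample sd 1, n−1
denominator) and decomposed by correlation-matrix PCA.  On z-scores the two
views coincide: eigenvalues of the correlation matrix equal squared singular
values of the standardized matrix divided by n−1, and they sum to the number
of variables, which makes the variance-explained fractions directly
interpretable (an eigenvalue of 4.69 out of 9 variables is 52%).

Sign convention: each loading column is flipped so its largest-magnitude
element is positive, making biplot orientation deterministic across runs and
row orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from viaquant.errors import ZeroVarianceError

#: Canonical reactor-metrics columns (order-free on input).
METRIC_COLUMNS = (
    "TOC",
    "CH4",
    "CO2",
    "Ecotox",
    "EST",
    "GST",
    "CAT",
    "ROS",
    "Nonviable",
)


def load_metrics(path: str | Path) -> pd.DataFrame:
    """Read a reactor-metrics CSV: first column = reactor id, then the nine variables.

    Header names must match :data:`METRIC_COLUMNS` (any column order); the
    matrix must be complete (no missing cells).
    """
    df = pd.read_csv(path, index_col=0)
    missing = set(METRIC_COLUMNS) - set(df.columns)
    extra = set(df.columns) - set(METRIC_COLUMNS)
    if missing or extra:
        raise ValueError(
            f"{path}: metrics header must contain exactly {','.join(METRIC_COLUMNS)}; "
            f"missing={sorted(missing)} unexpected={sorted(extra)}"
        )
    df = df[list(METRIC_COLUMNS)]
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"{path}: metrics matrix has missing cells in columns {bad}")
    return df.astype(float)


def zscore(metrics: pd.DataFrame) -> pd.DataFrame:
    """Standardize every column to mean 0 and sample (n−1) standard deviation 1."""
    sd = metrics.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        raise ZeroVarianceError(
            f"column(s) {constant} are constant and cannot be standardized"
        )
    return (metrics - metrics.mean()) / sd


@dataclass(frozen=True)
class PCAResult:
    """Two-or-more-component decomposition of a standardized metrics matrix."""

    eigenvalues: np.ndarray          # k, descending
    variance_explained: np.ndarray   # k fractions of total variance
    loadings: pd.DataFrame           # variables × k, orthonormal columns
    scores: pd.DataFrame             # observations × k
    total_variance: float            # trace of the covariance (= #variables on z-scores)

    @property
    def k(self) -> int:
        return len(self.eigenvalues)


def pca(standardized: pd.DataFrame, k: int = 2) -> PCAResult:
    """PCA of a z-scored matrix via SVD (equivalent to the correlation eigensolve).

    ``k`` components are retained, ``1 <= k <= min(n_obs − 1, n_vars)``.
    Eigenvalues are singular values squared over n−1; on standardized input
    the full set sums to the number of variables.  Deterministic sign
    convention: each loading column's largest-magnitude element is positive
    (first index on ties).
    """
    X = standardized.to_numpy(dtype=float)
    n, p = X.shape
    kmax = min(n - 1, p)
    if not 1 <= k <= kmax:
        raise ValueError(f"k must be in [1, {kmax}] for a {n}×{p} matrix, got {k}")

    _, s, vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    loadings = vt.T[:, :k]
    eig_k = eigenvalues[:k]

    # sign convention: largest-|.| element of each loading column positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip

    scores = X @ loadings
    total = float(X.var(axis=0, ddof=1).sum())
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        eigenvalues=eig_k,
        variance_explained=eig_k / total,
        loadings=pd.DataFrame(loadings, index=standardized.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=standardized.index, columns=comp_names),
        total_variance=total,
    )


def biplot_table(result: PCAResult) -> pd.DataFrame:
    """Tidy biplot coordinates: variable arrows and observation points.

    Variable arrows are loadings scaled by the square root of the eigenvalue
    (correlation-scaled), observation points are the raw scores.  Requires a
    two-component result.
    """
    if result.k != 2:
        raise ValueError(f"biplot requires exactly 2 components, got {result.k}")
    scale = np.sqrt(result.eigenvalues)
    arrows = result.loadings.to_numpy() * scale
    rows = [
        {"kind": "variable", "name": name, "x": float(x), "y": float(y)}
        for name, (x, y) in zip(result.loadings.index, arrows)
    ]
    rows += [
        {"kind": "reactor", "name": str(name), "x": float(x), "y": float(y)}
        for name, (x, y) in zip(result.scores.index, result.scores.to_numpy())
    ]
    return pd.DataFrame(rows, columns=["kind", "name", "x", "y"])


def score_distances(result: PCAResult) -> pd.DataFrame:
    """Pairwise Euclidean distances between observations in retained-score space.

    Grouping of reactors on the biplot is left to the reader; these distances
    are the quantitative backing (nearest neighbors = most similar behavior).
    """
    pts = result.scores.to_numpy()
    names = [str(i) for i in result.scores.index]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    return pd.DataFrame(d, index=names, columns=names)


def biplot_figure(result: PCAResult, ax=None):
    """Render the biplot (arrows = variables, points = observations)."""
    import matplotlib.pyplot as plt

    table = biplot_table(result)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for _, row in table[table["kind"] == "variable"].iterrows():
        ax.annotate(
            "", xy=(row.x, row.y), xytext=(0, 0), arrowprops=dict(arrowstyle="->", color="tab:blue")
        )
        ax.annotate(row["name"], xy=(row.x * 1.08, row.y * 1.08), color="tab:blue")
    pts = table[table["kind"] == "reactor"]
    ax.scatter(pts.x, pts.y, color="tab:red")
    for _, row in pts.iterrows():
        ax.annotate(row["name"], xy=(row.x, row.y), xytext=(3, 3), textcoords="offset points")
    ve = result.variance_explained * 100
    ax.set_xlabel(f"PC1 ({ve[0]:.1f}% of variance)")
    ax.set_ylabel(f"PC2 ({ve[1]:.1f}% of variance)")
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    return ax


def planted_two_factor_metrics(
    n_obs: int = 100,
    shares: tuple[float, float] = (0.52, 0.23),
    seed: int = 0,
    columns: tuple[str, ...] = METRIC_COLUMNS,
) -> tuple[pd.DataFrame, float]:
    """Simulate a metrics matrix from a known 2-factor model.

    Each column j is ``a_j1·f1 + a_j2·f2 + e_j`` with unit-variance independent
    factors and isotropic noise, and ``a_j1² + a_j2² + var(e_j) = 1`` so the
    two factors carry exactly ``sum(shares)`` of the population variance.
    Loading signs alternate across columns so the factors spread over the
    variables.

    Returns the matrix together with the model's exact population PC1+PC2
    variance share.  Note this is ``s1 + s2 + 2·(1 − s1 − s2)/p``, not
    ``s1 + s2``: isotropic noise of variance σ² raises *every* population
    eigenvalue by σ², including the top two, so the true two-component share
    exceeds the factor share whenever noise is present.  The default 100
    simulated observations keep eigenvalue sampling noise small (a few rows
    would leave the sample share dominated by small-sample inflation).
    """
    s1, s2 = shares
    if s1 <= 0 or s2 <= 0 or s1 + s2 >= 1:
        raise ValueError("factor shares must be positive and sum below 1")
    rng = np.random.default_rng(seed)
    p = len(columns)

    f = rng.normal(size=(n_obs, 2))
    signs1 = np.where(np.arange(p) % 2 == 0, 1.0, -1.0)
    signs2 = np.where(np.arange(p) % 3 == 0, 1.0, -1.0)
    a1 = signs1 * np.sqrt(s1)
    a2 = signs2 * np.sqrt(s2)
    noise_var = 1.0 - s1 - s2
    X = f[:, :1] * a1 + f[:, 1:2] * a2 + rng.normal(
        scale=np.sqrt(noise_var), size=(n_obs, p)
    )
    index = [f"R{i + 1}" for i in range(n_obs)]
    # rank-2 structural part contributes |a1|^2 + |a2|^2 = p*(s1+s2) to the top
    # two eigenvalues; isotropic noise adds noise_var to each of them
    planted_top2_share = s1 + s2 + 2.0 * noise_var / p
    return pd.DataFrame(X, index=index, columns=list(columns)), planted_top2_share
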