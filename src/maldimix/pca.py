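"""PCA diagnostics: discrimination of pure populations and mixtures, and
scree/explained-variance analysis.

The decomposition is a plain SVD of the (column-mean-centered) fingerprint
matrix.  Explained-variance fractions are relative to the total variance of
the full matrix, so they sum to 1 over a full decomposition regardless of
how many components are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .preprocess import IntensityMatrix


@dataclass
class PCAResult:
    """Scores (m x c), loadings (n x c) and explained-variance fractions.

    Component signs follow a fixed convention (the largest-magnitude loading
    entry of each component is positive) so results are reproducible.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    row_ids: list[str]
    col_mz: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scree_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.n_components + 1),
                "explained_variance_fraction": self.explained_variance_fraction,
                "cumulative_fraction": np.cumsum(self.explained_variance_fraction),
            }
        )


def pca_decompose(
    matrix: IntensityMatrix, n_components: int, center: bool = True
) -> PCAResult:
    """Mean-centered SVD of the fingerprint matrix.

    If ``n_components`` exceeds the matrix rank the result is truncated to
    the rank with a warning (not an error).
    """
    X = matrix.values
    m, n = X.shape
    if m < 2:
        raise ValidationError("PCA needs at least 2 rows")
    if n_components < 1:
        raise ParameterError("n_components must be >= 1")
    Xc = X - X.mean(axis=0) if center else X.copy()
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(m, n) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    rank = int(np.sum(S > tol))
    k = min(n_components, rank) if rank > 0 else 1
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but matrix rank is {rank}; "
            f"truncating",
            stacklevel=2,
        )
    total = float(np.sum(S**2))
    frac = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    loadings = Vt[:k].T.copy()
    scores = U[:, :k] * S[:k]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=frac,
        row_ids=list(matrix.row_ids),
        col_mz=matrix.col_mz.copy(),
    )


def cumulative_variance(result: PCAResult, k: int) -> float:
    """Fraction of total variance explained by the first k components."""
    if k < 0 or k > result.n_components:
        raise ParameterError(
            f"k={k} out of range for {result.n_components} components"
        )
    if k == 0:
        return 0.0
    return float(np.sum(result.explained_variance_fraction[:k]))
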