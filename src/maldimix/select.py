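"""Informative-peak selection.

Three selectors rank/select m/z columns whose variation tracks the mixture
composition:

* normalized-SD ranking — SD of each column divided by the pooled SD of
  all matrix entries (a scale-free variability score),
* Lasso — L1-penalized linear regression of the contaminant cell count on
  the fingerprint, penalty chosen by cross-validation with the
  one-standard-error rule,
* sparse PLS — PLS1 with soft-thresholded loading weights.

``combine_panels`` merges the three into a fixed-size panel by vote count,
then SD score, then ascending m/z.  Because columns are grid bins rather
than centroided peaks, an optional minimum m/z spacing prevents one strong
peak from occupying the whole panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .errors import DegenerateInputError, ParameterError, ValidationError
from .preprocess import IntensityMatrix


@dataclass
class SelectionScores:
    """Per-column variability scores with a descending ranking."""

    col_mz: np.ndarray
    score: np.ndarray  # SD(column) / pooled SD, dimensionless, >= 0
    order: np.ndarray  # column indices, descending score, ties by ascending m/z
    method: str = "sd"

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


@dataclass
class PeakPanel:
    """The selected peak panel: column indices into the thresholded matrix,
    their m/z values, and which selectors chose each column."""

    indices: np.ndarray
    mz: np.ndarray
    sd_score: np.ndarray
    chosen_by: list[tuple[str, ...]]
    target_size: int

    def __len__(self) -> int:
        return len(self.indices)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.indices) + 1),
                "mz": self.mz,
                "sd_score": self.sd_score,
                "chosen_by": ["+".join(c) for c in self.chosen_by],
            }
        )


def sd_ranking(matrix: IntensityMatrix) -> SelectionScores:
    """Score each column by SD(column) / SD(all entries pooled).

    Requires >= 2 rows.  Ranking is descending by score with ties broken by
    ascending m/z; invariant to row permutation and to global positive
    scaling of the matrix.
    """
    X = matrix.values
    if X.shape[0] < 2:
        raise DegenerateInputError("sd_ranking needs at least 2 rows")
    pooled = float(np.std(X, ddof=1))
    if pooled == 0:
        raise DegenerateInputError("matrix is constant; pooled SD is zero")
    score = np.std(X, axis=0, ddof=1) / pooled
    order = np.lexsort((matrix.col_mz, -score))
    return SelectionScores(col_mz=matrix.col_mz.copy(), score=score, order=order)


def lasso_select(
    matrix: IntensityMatrix,
    y: np.ndarray,
    n_lambda: int = 100,
    cv_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Columns with nonzero Lasso coefficients at the one-standard-error
    penalty.

    The penalty path is logarithmic (as generated by scikit-learn); the
    chosen penalty is the largest one whose mean CV error is within one
    standard error of the minimum.  Deterministic given the seed (which
    fixes the CV fold shuffle).
    """
    X = matrix.values
    y = np.asarray(y, dtype=float)
    if len(y) != X.shape[0]:
        raise ValidationError("y length must match matrix rows")
    if np.std(y) == 0:
        raise ValidationError("y has zero variance; nothing to regress on")
    if X.shape[0] < cv_folds:
        raise ValidationError(f"need >= {cv_folds} rows for {cv_folds}-fold CV")
    # standardize for a scale-free path; selection happens in standardized space
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd_safe
    ys = (y - y.mean()) / y.std()
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    lcv = LassoCV(alphas=n_lambda, cv=cv, max_iter=20000, tol=1e-4)
    lcv.fit(Xs, ys)
    # one-standard-error rule over the CV error path (alphas descend)
    mse_mean = lcv.mse_path_.mean(axis=1)
    mse_se = lcv.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv_folds)
    i_min = int(np.argmin(mse_mean))
    limit = mse_mean[i_min] + mse_se[i_min]
    admissible = np.flatnonzero(mse_mean <= limit)
    alpha_1se = float(lcv.alphas_[admissible.min()])  # largest admissible penalty
    fit = Lasso(alpha=alpha_1se, max_iter=20000, tol=1e-4).fit(Xs, ys)
    selected = np.flatnonzero((fit.coef_ != 0) & (sd > 0))
    return selected


def spls_select(
    matrix: IntensityMatrix,
    y: np.ndarray,
    n_components: int = 2,
    sparsity: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Columns with nonzero loading weight in any retained sparse-PLS
    component.

    Each component's weight vector w = X'y (on standardized data) is
    soft-thresholded at ``sparsity`` times its largest magnitude, then X and
    y are deflated as in NIPALS PLS1.  sparsity=0 keeps every column.  The
    procedure is deterministic; ``seed`` is accepted for interface symmetry
    with the other selectors.
    """
    X = matrix.values
    y = np.asarray(y, dtype=float)
    if len(y) != X.shape[0]:
        raise ValidationError("y length must match matrix rows")
    if not 0 <= sparsity < 1:
        raise ParameterError("sparsity must be in [0, 1)")
    m, n = X.shape
    if n_components >= min(m, n) or n_components < 1:
        raise ParameterError(
            f"n_components={n_components} must be in [1, min(m, n) - 1] "
            f"for an {m} x {n} matrix"
        )
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xc = (X - mu) / sd_safe
    yc = y - y.mean()
    support = np.zeros(n, dtype=bool)
    for _ in range(n_components):
        w = Xc.T @ yc
        wmax = np.abs(w).max()
        if wmax <= 0:
            break
        thr = sparsity * wmax
        w = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        support |= w != 0
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 1e-300:
            break
        p = Xc.T @ t / tt
        q = float(yc @ t / tt)
        Xc = Xc - np.outer(t, p)
        yc = yc - q * t
    support &= sd > 0
    return np.flatnonzero(support)


def _cluster_columns(col_mz: np.ndarray, min_spacing_da: float) -> list[list[int]]:
    """Group columns into peak clusters: consecutive columns closer than
    ``min_spacing_da`` belong to one peak.  Spacing 0 keeps every column
    its own cluster."""
    n = len(col_mz)
    if min_spacing_da <= 0:
        return [[j] for j in range(n)]
    order = np.argsort(col_mz, kind="stable")
    clusters: list[list[int]] = [[int(order[0])]]
    for j in order[1:]:
        if col_mz[j] - col_mz[clusters[-1][-1]] < min_spacing_da:
            clusters[-1].append(int(j))
        else:
            clusters.append([int(j)])
    return clusters


def combine_panels(
    sd: SelectionScores,
    lasso: np.ndarray,
    spls: np.ndarray,
    target_size: int,
    min_spacing_da: float = 0.0,
) -> PeakPanel:
    """Merge the three selectors into the final panel.

    Candidates are ranked by (number of methods selecting them, SD score,
    ascending m/z) and truncated to ``target_size``; the SD selector
    "votes" for its ``target_size`` top-ranked candidates.  With
    ``min_spacing_da`` = 0 every column is its own candidate (the literal
    vote -> score -> m/z rule).  With a positive spacing, columns closer
    than the spacing are first merged into one peak cluster — represented
    by its highest-SD bin, voted for by any method that hit any of its
    bins — so the panel covers distinct peaks rather than adjacent bins of
    one strong peak.  Panel size is min(target_size, candidates available).
    """
    n = len(sd.score)
    if target_size < 1 or target_size > n:
        raise ParameterError(
            f"target_size={target_size} out of range for {n} columns"
        )
    lasso = np.asarray(lasso, dtype=int)
    spls = np.asarray(spls, dtype=int)
    for name, idx in (("lasso", lasso), ("spls", spls)):
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ValidationError(f"{name} indices outside the column space")
    lasso_set, spls_set = set(map(int, lasso)), set(map(int, spls))

    clusters = _cluster_columns(sd.col_mz, min_spacing_da)
    reps = np.array([c[int(np.argmax(sd.score[c]))] for c in clusters])
    rep_score = sd.score[reps]
    rep_mz = sd.col_mz[reps]
    # the SD selector votes for its top target_size candidates
    sd_rank = np.lexsort((rep_mz, -rep_score))
    sd_votes = np.zeros(len(reps), dtype=bool)
    sd_votes[sd_rank[:target_size]] = True
    lasso_votes = np.array([any(j in lasso_set for j in c) for c in clusters])
    spls_votes = np.array([any(j in spls_set for j in c) for c in clusters])
    votes = sd_votes.astype(int) + lasso_votes + spls_votes

    order = np.lexsort((rep_mz, -rep_score, -votes))[:target_size]
    idx = reps[order]
    provenance = [
        tuple(
            tag
            for tag, hit in (("sd", sd_votes[c]), ("lasso", lasso_votes[c]),
                             ("spls", spls_votes[c]))
            if hit
        )
        for c in order
    ]
    return PeakPanel(
        indices=idx,
        mz=sd.col_mz[idx],
        sd_score=sd.score[idx],
        chosen_by=provenance,
        target_size=target_size,
    )
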