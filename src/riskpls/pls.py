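"""Cross-covariance partial least squares (PLS correlation).

Given a z-scored brain matrix X (n subjects x p regions) and behavior
matrix Y (n x q risk factors), the cross-covariance R = X'Y/(n-1) is
decomposed by SVD into paired saliences (latent variables) that maximally
covary across the two blocks.  Each latent variable carries a singular
value, its share of the total cross-block covariance (S_i^2 / sum S_j^2),
and per-subject brain/behavior scores (projections X.U_i and Y.V_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PLSModel", "ScoreSet", "cross_covariance", "pls_svd", "compute_scores", "fit_pls"]


@dataclass
class PLSModel:
    U: np.ndarray  # p x k brain saliences, orthonormal columns
    V: np.ndarray  # q x k behavior saliences, orthonormal columns
    S: np.ndarray  # k singular values, descending, nonnegative
    covexp: np.ndarray  # k covariance-explained fractions, sums to 1
    x_names: list[str] | None = None
    y_names: list[str] | None = None
    n_subjects: int | None = None

    @property
    def k(self) -> int:
        return len(self.S)


@dataclass
class ScoreSet:
    brain_scores: np.ndarray  # n x k, X @ U
    behavior_scores: np.ndarray  # n x k, Y @ V
    score_correlations: np.ndarray  # k, corr(L_x_i, L_y_i)
    row_ids: list[str] | None = None


def cross_covariance(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """R = X'Y / (n-1).

    With column-z-scored inputs the entries are Pearson correlations in
    [-1, 1]; the decomposition itself only assumes centered columns (any
    positive column rescaling rescales S but leaves saliences and
    covariance-explained unchanged).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with the same number of rows")
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing entries in input matrices")
    return X.T @ Y / (n - 1)


def pls_svd(
    R: np.ndarray,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
    n_subjects: int | None = None,
) -> PLSModel:
    """SVD of the cross-covariance matrix with a fixed sign convention.

    All k = min(p, q) components are computed; downstream reporting decides
    how many to interpret.  The sign of each component is fixed so that the
    largest-magnitude element of its behavior salience is positive (ties
    broken by first index), removing the decomposition's arbitrary sign.
    """
    R = np.asarray(R, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("cross-covariance matrix has non-finite entries")
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for i in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, i])))
        if V[j, i] < 0:
            V[:, i] = -V[:, i]
            U[:, i] = -U[:, i]
    total = float(np.sum(S**2))
    covexp = S**2 / total if total > 0 else np.zeros_like(S)
    return PLSModel(
        U=U, V=V, S=S, covexp=covexp,
        x_names=x_names, y_names=y_names, n_subjects=n_subjects,
    )


def compute_scores(
    X: np.ndarray,
    Y: np.ndarray,
    model: PLSModel,
    row_ids: list[str] | None = None,
) -> ScoreSet:
    """Per-subject latent-variable scores: L_x = X.U, L_y = Y.V.

    The per-LV Pearson correlation between brain and behavior scores is
    reported alongside (how coherently subjects express the paired
    patterns).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != model.U.shape[0] or Y.shape[1] != model.V.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} columns vs model p="
            f"{model.U.shape[0]}; Y has {Y.shape[1]} vs q={model.V.shape[0]}"
        )
    Lx = X @ model.U
    Ly = Y @ model.V
    corrs = np.full(model.k, np.nan)
    for i in range(model.k):
        sx, sy = Lx[:, i].std(), Ly[:, i].std()
        if sx > 0 and sy > 0:
            corrs[i] = float(np.corrcoef(Lx[:, i], Ly[:, i])[0, 1])
    return ScoreSet(
        brain_scores=Lx, behavior_scores=Ly, score_correlations=corrs, row_ids=row_ids
    )


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> PLSModel:
    """Convenience: cross-covariance then SVD in one call."""
    R = cross_covariance(X, Y)
    return pls_svd(R, x_names=x_names, y_names=y_names, n_subjects=X.shape[0])
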