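"""Resampling inference for PLS latent variables.

Three complementary procedures:

* **Permutation test** — subject rows of the brain matrix are shuffled to
  break the brain-behavior pairing; the ordered singular values of each of
  ``n_perm`` refits form the null, and each observed LV is compared with
  the matching ordered null value with the add-one counting rule (p-values
  are never zero, minimum 1/(n_perm+1)).
* **Bootstrap ratios** — subjects are resampled with replacement, the
  model refit, and each variable's salience x singular value tracked; the
  bootstrap ratio is the observed product over its bootstrap standard
  error, with |BSR| > 1.95 treated as a reliable contribution (analogous
  to p < 0.05 for an approximately normal quantity).
* **Split-half stability** — the sample is repeatedly split into two
  stratum-balanced halves, the model refit on each, and the absolute
  Pearson correlation of the two halves' saliences recorded; the Z
  statistic (mean / SD of that distribution over iterations) flags a
  loading pattern as stable when |Z| > 1.96.

Every procedure re-standardizes the matrices within each resample (pass
``rezscore=False`` to disable) and is deterministic given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pls import PLSModel, cross_covariance, pls_svd

__all__ = [
    "PermutationResult",
    "BootstrapResult",
    "SplitHalfResult",
    "permutation_test",
    "bootstrap_ratios",
    "split_half_stability",
    "significant_variables",
]


@dataclass
class PermutationResult:
    n_perm: int
    p_values: np.ndarray  # k, in (0, 1]
    null_singulars: np.ndarray  # n_perm x k
    observed_singulars: np.ndarray  # k


@dataclass
class BootstrapResult:
    n_boot: int
    bsr: np.ndarray  # (p+q) x k bootstrap ratios, brain rows then behavior
    se: np.ndarray  # (p+q) x k bootstrap standard errors
    observed: np.ndarray  # (p+q) x k salience x singular value
    threshold: float = 1.95

    @property
    def significant(self) -> np.ndarray:
        return np.abs(self.bsr) > self.threshold


@dataclass
class SplitHalfResult:
    n_iter: int
    r_brain: np.ndarray  # n_iter x k absolute correlations
    r_behavior: np.ndarray  # n_iter x k
    z_brain: np.ndarray  # k
    z_behavior: np.ndarray  # k
    threshold: float = 1.96

    @property
    def stable(self) -> np.ndarray:
        """LV stable when both domains' |Z| exceed the threshold."""
        return (np.abs(self.z_brain) > self.threshold) & (
            np.abs(self.z_behavior) > self.threshold
        )


def _rezscore(M: np.ndarray) -> np.ndarray:
    """Column z-score (n-1); raises on a constant column."""
    sd = M.std(axis=0, ddof=1)
    if np.any(sd < 1e-12):
        raise FloatingPointError("constant column in resample")
    return (M - M.mean(axis=0)) / sd


def permutation_test(
    X: np.ndarray, Y: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> PermutationResult:
    """Row-shuffle permutation test of LV significance.

    p_i = (1 + #{b : null S_b,i >= observed S_i}) / (1 + n_perm), comparing
    the i-th ordered null singular value to the i-th observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    observed = pls_svd(cross_covariance(X, Y)).S
    k = len(observed)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, k))
    n = X.shape[0]
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = np.linalg.svd(X[perm].T @ Y / (n - 1), compute_uv=False)
    p = (1 + np.sum(null >= observed[None, :], axis=0)) / (1 + n_perm)
    return PermutationResult(
        n_perm=n_perm, p_values=p, null_singulars=null, observed_singulars=observed
    )


def bootstrap_ratios(
    X: np.ndarray,
    Y: np.ndarray,
    model: PLSModel,
    n_boot: int = 5000,
    seed: int = 0,
    rezscore: bool = True,
    max_retries: int = 10,
) -> BootstrapResult:
    """Bootstrap ratios of salience x singular value per variable and LV.

    Each draw resamples subjects with replacement, re-standardizes, refits,
    and sign-aligns every LV to the original model by the sign of the
    combined salience dot product.  The bootstrapped quantity for variable
    j in LV i is w_ji^(b) * S_i^(b); its standard deviation over draws is
    the SE, and BSR_ji = (w_ji * S_i) / SE_ji.  Brain rows come first in
    the stacked output, then behavior rows.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    k = model.k
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, X.shape[1] + Y.shape[1], k))
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(n, size=n)
            try:
                Xb = _rezscore(X[idx]) if rezscore else X[idx]
                Yb = _rezscore(Y[idx]) if rezscore else Y[idx]
            except FloatingPointError:
                if attempt == max_retries:
                    raise RuntimeError(
                        "bootstrap draw kept producing a constant column"
                    )
                continue
            break
        mb = pls_svd(cross_covariance(Xb, Yb))
        align = np.sum(mb.U * model.U, axis=0) + np.sum(mb.V * model.V, axis=0)
        signs = np.where(align < 0, -1.0, 1.0)
        W = np.vstack([mb.U, mb.V]) * signs[None, :]
        draws[b] = W * mb.S[None, :]
    observed = np.vstack([model.U, model.V]) * model.S[None, :]
    se = draws.std(axis=0, ddof=1)
    zero_se = se == 0
    if zero_se.any():
        warnings.warn(
            "zero bootstrap SE for some variables; BSR reported as +/-inf",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(zero_se, np.inf * np.sign(observed), observed / se)
    return BootstrapResult(n_boot=n_boot, bsr=bsr, se=se, observed=observed)


def _balanced_split(
    rng: np.random.Generator, strata: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Random half-split balanced within strata; singleton strata are
    assigned at random with a warning."""
    first, second = [], []
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        if len(idx) == 1:
            warnings.warn(f"stratum {s!r} has a single subject; assigned at random")
            (first if rng.random() < 0.5 else second).append(idx)
            continue
        half = len(idx) // 2
        if len(idx) % 2 and rng.random() < 0.5:
            half += 1  # odd stratum: extra subject on a random side
        first.append(idx[:half])
        second.append(idx[half:])
    a = np.concatenate(first) if first else np.array([], dtype=int)
    b = np.concatenate(second) if second else np.array([], dtype=int)
    return a, b


def split_half_stability(
    X: np.ndarray,
    Y: np.ndarray,
    strata: np.ndarray | None = None,
    n_iter: int = 200,
    seed: int = 0,
    rezscore: bool = True,
    max_retries: int = 10,
) -> SplitHalfResult:
    """Split-half stability of the saliences.

    Each iteration splits subjects into two stratum-balanced halves, refits
    PLS on each, and records |corr| between the halves' brain saliences and
    between their behavior saliences per LV (absolute value absorbs the
    arbitrary sign).  Z = mean/SD of each r distribution.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 20:
        raise ValueError(f"need at least 20 subjects for split-half, got {n}")
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    if len(strata) != n:
        raise ValueError("strata labels must cover all subjects")
    k = min(X.shape[1], Y.shape[1])
    rng = np.random.default_rng(seed)
    r_brain = np.empty((n_iter, k))
    r_behavior = np.empty((n_iter, k))
    for it in range(n_iter):
        for attempt in range(max_retries + 1):
            ia, ib = _balanced_split(rng, strata)
            try:
                Xa = _rezscore(X[ia]) if rezscore else X[ia]
                Ya = _rezscore(Y[ia]) if rezscore else Y[ia]
                Xb = _rezscore(X[ib]) if rezscore else X[ib]
                Yb = _rezscore(Y[ib]) if rezscore else Y[ib]
            except FloatingPointError:
                if attempt == max_retries:
                    raise RuntimeError("half-splits kept producing constant columns")
                continue
            break
        ma = pls_svd(cross_covariance(Xa, Ya))
        mb = pls_svd(cross_covariance(Xb, Yb))
        for i in range(k):
            r_brain[it, i] = abs(np.corrcoef(ma.U[:, i], mb.U[:, i])[0, 1])
            r_behavior[it, i] = abs(np.corrcoef(ma.V[:, i], mb.V[:, i])[0, 1])
    with np.errstate(invalid="ignore"):
        z_brain = r_brain.mean(axis=0) / r_brain.std(axis=0, ddof=1)
        z_behavior = r_behavior.mean(axis=0) / r_behavior.std(axis=0, ddof=1)
    return SplitHalfResult(
        n_iter=n_iter,
        r_brain=r_brain,
        r_behavior=r_behavior,
        z_brain=z_brain,
        z_behavior=z_behavior,
    )


def significant_variables(
    result: BootstrapResult, threshold: float = 1.95
) -> np.ndarray:
    """Mask of variables whose bootstrap-ratio magnitude strictly exceeds
    the threshold (default 1.95, analogous to two-sided p < 0.05)."""
    return np.abs(result.bsr) > threshold
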