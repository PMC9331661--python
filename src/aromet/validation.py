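"""Model validation: Procrustes cross-validation, ROC analysis, group statistics.

Procrustes cross-validation (PCV) replaces classical segment-wise
cross-validation of a PCA model with a single *pseudo-validation* matrix:
for each segment a local PCA is fitted without the segment, and the held-out
rows are rebuilt so that, projected onto the GLOBAL model, they reproduce the
score and orthogonal distances the local model would have assigned them.
The pseudo-set can then be pushed through the already-fitted classifier like
any external test set.

Construction per held-out (autoscaled) row x with local loadings P_k and
local/global eigenvalues lambda^k_a / lambda_a:

    t_a   = (P_k^T x)_a                       local scores
    t~_a  = t_a sqrt(lambda_a / lambda^k_a)   rescaled so h matches globally
    e     = x - P_k t                         local residual
    x~    = P t~ + e_perp |e| / |e_perp|      residual re-oriented into the
                                              global orthogonal complement

where e_perp = (I - P P^T) e.  By construction the global score distance of
x~ equals the local (classical CV) score distance and the orthogonal
distances agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simca import PcaModel, fit_pca

__all__ = [
    "PseudoValidationSet",
    "RocCurve",
    "holm_adjust",
    "kruskal_wallis",
    "make_segments",
    "mann_whitney",
    "procrustes_cv",
    "roc",
]


# ---- Procrustes cross-validation ------------------------------------------


@dataclass(frozen=True)
class PseudoValidationSet:
    """Pseudo-validation matrix (autoscaled space) and the segment scheme used."""

    matrix: np.ndarray
    segments: tuple[tuple[int, ...], ...]


def make_segments(n: int, scheme="loo") -> list[list[int]]:
    """Row segments: 'loo' (leave-one-out) or an integer k for contiguous k-fold."""
    if scheme == "loo":
        return [[i] for i in range(n)]
    k = int(scheme)
    if not 2 <= k <= n:
        raise ValueError(f"k-fold scheme needs 2 <= k <= n, got {k}")
    bounds = np.linspace(0, n, k + 1).astype(int)
    return [list(range(bounds[i], bounds[i + 1])) for i in range(k)]


def procrustes_cv(
    X_cal: np.ndarray, n_components: int, segments="loo"
) -> PseudoValidationSet:
    """Build the pseudo-validation matrix for an autoscaled calibration matrix.

    ``segments`` is 'loo', an integer fold count, or an explicit partition of
    row indices.  Raises when a segment's complement cannot support the
    requested number of components.
    """
    X = np.asarray(X_cal, dtype=float)
    n, p = X.shape
    if isinstance(segments, (str, int)):
        segs = make_segments(n, segments)
    else:
        segs = [list(s) for s in segments]
        covered = sorted(i for s in segs for i in s)
        if covered != list(range(n)):
            raise ValueError("segments must partition the row indices")

    global_model = fit_pca(X, n_components)
    P = global_model.loadings
    lam = global_model.eigenvalues

    X_pv = np.empty_like(X)
    for seg in segs:
        rest = [i for i in range(n) if i not in seg]
        if len(rest) - 1 < n_components:
            raise ValueError(
                f"segment of size {len(seg)} leaves too few rows for {n_components} components"
            )
        local = fit_pca(X[rest], n_components)
        P_k = local.loadings.copy()
        lam_k = local.eigenvalues.copy()
        # Align local component signs with the global ones (SVD sign is arbitrary).
        signs = np.sign(np.sum(P_k * P, axis=0))
        signs[signs == 0] = 1.0
        P_k = P_k * signs

        for i in seg:
            x = X[i]
            t = P_k.T @ x
            t_scaled = t * np.sqrt(lam / lam_k)
            e = x - P_k @ t
            e_perp = e - P @ (P.T @ e)
            norm_e = np.linalg.norm(e)
            norm_perp = np.linalg.norm(e_perp)
            if norm_e == 0 or norm_perp == 0:
                resid = np.zeros(p)
            else:
                resid = e_perp * (norm_e / norm_perp)
            X_pv[i] = P @ t_scaled + resid

    return PseudoValidationSet(matrix=X_pv, segments=tuple(tuple(s) for s in segs))


# ---- ROC analysis ----------------------------------------------------------


@dataclass(frozen=True)
class RocCurve:
    """ROC points from (0,0) to (1,1) and the area under the curve.

    Orientation: a higher score means "more non-survivor-like" (positive
    class).  ``auc`` is the trapezoidal area, which is verified at
    construction against the pair-counting (rank) statistic with ties
    counted one half.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC points must be monotone nondecreasing")


def roc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC curve of a prognostic score against a binary outcome.

    ``labels``: True for the positive (non-survivor) class.  Thresholds sweep
    the unique score values; the AUC is computed by the trapezoid rule and
    cross-checked against the Mann-Whitney pair-counting statistic
    (P(score_pos > score_neg) + 0.5 P(tie)) — the two are equal by
    construction and any disagreement raises.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("one class empty: ROC undefined")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = labels[order]
    # Cut only between distinct score values.
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(scores) - 1]
    tp = np.cumsum(sorted_pos)[distinct]
    fp = np.cumsum(~sorted_pos)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]

    auc_trapz = float(np.trapezoid(tpr, fpr))
    pos = scores[labels][:, None]
    neg = scores[~labels][None, :]
    auc_pairs = float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (n_pos * n_neg))
    if not np.isclose(auc_trapz, auc_pairs, atol=1e-10):
        raise AssertionError(
            f"trapezoid AUC {auc_trapz} != pair-counting AUC {auc_pairs}"
        )
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc_trapz)


# ---- nonparametric group statistics ----------------------------------------


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    return float((x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum())


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    Exact permutation enumeration when the combined sample size is at most
    12 (handles ties correctly); tie-corrected normal approximation (scipy)
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    U = _u_statistic(x, y)
    n, m = x.size, y.size
    if n + m <= 12:
        pooled = np.concatenate([x, y])
        center = n * m / 2.0
        dev = abs(U - center)
        total = hits = 0
        for idx in combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - center) >= dev - 1e-12:
                hits += 1
        return U, hits / total
    if np.all(np.concatenate([x, y]) == x[0]):
        return U, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return U, float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-squared p (k-1 dof).

    All-identical input is a defined no-difference case: (H, p) = (0, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]
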