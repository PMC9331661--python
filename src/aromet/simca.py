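"""Data-driven SIMCA: a one-class classifier with chi-squared acceptance region.

The target class (healthy volunteers + survivors) is modelled by PCA on the
autoscaled relative-area matrix.  Every sample gets two distances to the
model: the score distance

    h = sum_a t_a^2 / lambda_a

(a Mahalanobis-type distance within the A-dimensional score space, with
eigenvalues lambda_a = score variances, n-1 denominator) and the orthogonal
distance

    v = || x - P t ||^2

(squared residual norm outside the model plane).  Under the data-driven
framework each distance is treated as a scaled chi-squared variable
d ~ (d0 / N) chi^2(N); the scale d0 and the integer degrees of freedom N are
estimated from the calibration distances by the method of moments.  The two
distances combine into the full distance

    f = Nh h / h0 + Nv v / v0  ~  chi^2(Nh + Nv),

and a sample is accepted into the class iff f <= chi^2 quantile at 1 - alpha
with Nh + Nv degrees of freedom.  The same scaled chi-squared construction in
one dimension yields a data-driven cutoff for a univariate marker.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .preprocess import ScalingParams, autoscale

__all__ = [
    "DistanceParams",
    "PcaModel",
    "SimcaModel",
    "classify",
    "distances",
    "estimate_dof",
    "false_negative_rate",
    "fit_pca",
    "fit_simca",
    "full_distance",
    "model_from_json",
    "model_to_json",
    "outlier_cutoff",
    "univariate_cutoff",
]

_DOF_MAX = 250


@dataclass(frozen=True)
class PcaModel:
    """PCA decomposition of the autoscaled calibration matrix.

    ``loadings``: variables x A orthonormal matrix (top right singular
    vectors); ``eigenvalues``: variances of the score columns (n-1
    denominator), nonincreasing.
    """

    loadings: np.ndarray
    eigenvalues: np.ndarray
    n_components: int
    scaling: ScalingParams | None = None

    def __post_init__(self) -> None:
        P = self.loadings
        if not np.allclose(P.T @ P, np.eye(self.n_components), atol=1e-8):
            raise ValueError("loadings columns must be orthonormal")
        ev = np.asarray(self.eigenvalues)
        if np.any(ev <= 0) or np.any(np.diff(ev) > 1e-12):
            raise ValueError("eigenvalues must be positive and nonincreasing")


@dataclass(frozen=True)
class DistanceParams:
    """Scaled chi-squared parameters of the two distances and the cutoff."""

    h0: float
    Nh: int
    v0: float
    Nv: int
    alpha: float
    f_crit: float

    def __post_init__(self) -> None:
        if self.h0 <= 0 or self.v0 <= 0:
            raise ValueError("distance scales must be positive")
        for N in (self.Nh, self.Nv):
            if not 1 <= N <= _DOF_MAX:
                raise ValueError(f"degrees of freedom {N} outside [1, {_DOF_MAX}]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class SimcaModel:
    pca: PcaModel
    dist: DistanceParams
    variables: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.variables) != self.pca.loadings.shape[0]:
            raise ValueError("variable list must match the loadings dimension")


def fit_pca(X: np.ndarray, n_components: int) -> PcaModel:
    """PCA via SVD of the (already autoscaled) calibration matrix."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components < 1:
        raise ValueError("need at least one component")
    rank = np.linalg.matrix_rank(X)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt[:n_components].T
    eigenvalues = (s[:n_components] ** 2) / (n - 1)
    return PcaModel(loadings=loadings, eigenvalues=eigenvalues, n_components=n_components)


def distances(
    model: PcaModel, X: np.ndarray, scaled: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Score distance h and orthogonal distance v for each row of ``X``.

    ``X`` is raw-scale by default; the model's stored calibration scaling is
    applied internally.  Pass ``scaled=True`` for matrices already in the
    autoscaled space (e.g. a Procrustes pseudo-validation set).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.loadings.shape[0]:
        raise ValueError(
            f"variable mismatch: X has {X.shape[1]}, model has {model.loadings.shape[0]}"
        )
    if not scaled:
        if model.scaling is None:
            raise ValueError("model carries no scaling; pass scaled=True")
        X, _ = autoscale(X, model.scaling)
    T = X @ model.loadings
    h = np.sum(T**2 / model.eigenvalues, axis=1)
    E = X - T @ model.loadings.T
    v = np.sum(E**2, axis=1)
    return h, v


def estimate_dof(d: Sequence[float]) -> tuple[float, int]:
    """Method-of-moments fit of the scaled chi-squared law d ~ (d0/N) chi^2(N).

    d0 = mean(d);  N = round(2 mean(d)^2 / var(d)), clipped to [1, 250].
    """
    d = np.asarray(d, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 distances")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    m = float(d.mean())
    var = float(d.var(ddof=1))
    if var == 0:
        raise ValueError("degenerate distance distribution (zero variance)")
    N = int(round(2.0 * m * m / var))
    return m, int(np.clip(N, 1, _DOF_MAX))


def full_distance(h, v, params: DistanceParams):
    """f = Nh h / h0 + Nv v / v0 (per sample)."""
    return params.Nh * np.asarray(h) / params.h0 + params.Nv * np.asarray(v) / params.v0


def outlier_cutoff(params: DistanceParams, gamma: float, n: int) -> float:
    """Outer (outlier) full-distance limit at Bonferroni-corrected gamma/n."""
    return float(stats.chi2.ppf(1.0 - gamma / n, params.Nh + params.Nv))


def fit_simca(
    X_cal: np.ndarray,
    n_components: int = 3,
    alpha: float = 0.01,
    variables: Sequence[str] | None = None,
    drop_constant: bool = False,
) -> SimcaModel:
    """Fit the one-class model on the target-class calibration matrix.

    Autoscales, decomposes with PCA, computes the calibration distances,
    moment-fits (h0, Nh) and (v0, Nv) separately, and sets the acceptance
    cutoff ``f_crit = chi^2_{1-alpha}(Nh + Nv)``.  Only target-class samples
    may enter ``X_cal``.

    ``drop_constant=True`` silently removes zero-variance columns before
    scaling — useful for sparse panels where a rarely detected analyte may be
    absent from every calibration sample.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    if variables is None:
        variables = tuple(f"x{j}" for j in range(X_cal.shape[1]))
    variables = tuple(variables)
    if drop_constant:
        keep = np.flatnonzero(X_cal.std(axis=0, ddof=1) > 0)
        X_cal = X_cal[:, keep]
        variables = tuple(variables[j] for j in keep)
    X_scaled, scaling = autoscale(X_cal)
    pca = fit_pca(X_scaled, n_components)
    pca = PcaModel(
        loadings=pca.loadings, eigenvalues=pca.eigenvalues,
        n_components=pca.n_components, scaling=scaling,
    )
    h, v = distances(pca, X_scaled, scaled=True)
    h0, Nh = estimate_dof(h)
    v0, Nv = estimate_dof(v)
    f_crit = float(stats.chi2.ppf(1.0 - alpha, Nh + Nv))
    dist = DistanceParams(h0=h0, Nh=Nh, v0=v0, Nv=Nv, alpha=alpha, f_crit=f_crit)
    return SimcaModel(pca=pca, dist=dist, variables=variables)


def classify(
    model: SimcaModel, X: np.ndarray, scaled: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Accept (True) or reject each sample; also return the full distances.

    Acceptance: f <= f_crit.  The f values double as a ranking score for ROC
    analysis and as the 1-D plotting coordinate.
    """
    h, v = distances(model.pca, X, scaled=scaled)
    f = full_distance(h, v, model.dist)
    return f <= model.dist.f_crit, f


def false_negative_rate(accepted: Sequence[bool]) -> float:
    """Fraction of target-class samples rejected by the model."""
    accepted = np.asarray(accepted, dtype=bool)
    if accepted.size == 0:
        raise ValueError("empty classification result")
    return float(np.mean(~accepted))


def univariate_cutoff(values: Sequence[float], alpha: float = 0.01) -> float:
    """Data-driven cutoff for a single positive marker.

    One-dimensional analogue of the acceptance region: fit the scaled
    chi-squared law to the target-class values by moments and return
    ``d0 chi^2_{1-alpha}(N) / N``; a sample is non-survivor-like iff its
    value exceeds the cutoff.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("marker values must be nonnegative")
    d0, N = estimate_dof(values)
    return float(d0 * stats.chi2.ppf(1.0 - alpha, N) / N)


# ---- serialization ---------------------------------------------------------


def model_to_json(model: SimcaModel) -> str:
    payload = {
        "variables": list(model.variables),
        "loadings": model.pca.loadings.tolist(),
        "eigenvalues": model.pca.eigenvalues.tolist(),
        "n_components": model.pca.n_components,
        "scaling_mean": model.pca.scaling.mean.tolist(),
        "scaling_sd": model.pca.scaling.sd.tolist(),
        "h0": model.dist.h0,
        "Nh": model.dist.Nh,
        "v0": model.dist.v0,
        "Nv": model.dist.Nv,
        "alpha": model.dist.alpha,
        "f_crit": model.dist.f_crit,
    }
    return json.dumps(payload, sort_keys=True, indent=2)


def model_from_json(text: str) -> SimcaModel:
    d = json.loads(text)
    scaling = ScalingParams(mean=np.array(d["scaling_mean"]), sd=np.array(d["scaling_sd"]))
    pca = PcaModel(
        loadings=np.array(d["loadings"]),
        eigenvalues=np.array(d["eigenvalues"]),
        n_components=d["n_components"],
        scaling=scaling,
    )
    dist = DistanceParams(
        h0=d["h0"], Nh=d["Nh"], v0=d["v0"], Nv=d["Nv"],
        alpha=d["alpha"], f_crit=d["f_crit"],
    )
    return SimcaModel(pca=pca, dist=dist, variables=tuple(d["variables"]))
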