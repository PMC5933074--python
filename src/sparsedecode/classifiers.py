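"""Supervised decision rules for volume-wise decoding.

Three classifiers share the same contract (ingest labeled training
volumes, score one query at a time):

* residual SRC -- code the query on the labeled dictionary and pick the
  class whose atoms reconstruct it with the smallest l2 residual;
* SRC-AVE -- same code, but pick the class with the largest mean
  coefficient (zeros included);
* LDC -- linear discriminant with a shrunk pooled covariance, needed
  because voxel counts exceed sample counts by an order of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sparse_core import SparseCode, SparseProblem, default_tau, solve_l1, split_by_class

__all__ = [
    "LabeledDictionary",
    "ClassScores",
    "LDCModel",
    "SolverSettings",
    "score_src",
    "predict_src",
    "predict_src_ave",
    "fit_ldc",
    "predict_ldc",
]


@dataclass(frozen=True)
class SolverSettings:
    """Knobs forwarded to the l1 solver.

    ``tau`` overrides the penalty outright; otherwise it is set per query
    to ``tau_scale * ||A^T y||_inf``.
    """

    tau: float | None = None
    tau_scale: float = 0.01
    tol: float = 1e-6
    max_iter: int = 1000

    def resolve_tau(self, A: np.ndarray, y: np.ndarray) -> float:
        if self.tau is not None:
            return float(self.tau)
        return default_tau(A, y, self.tau_scale)


class LabeledDictionary:
    """Training matrix with per-column class labels.

    Columns are training volumes (features x samples); the dictionary
    grows in place via :meth:`append_sample` during self-training.
    """

    def __init__(self, A: np.ndarray, labels) -> None:
        A = np.asarray(A, dtype=float)
        labels = np.asarray(labels)
        if A.ndim != 2:
            raise ValueError("A must be 2-D (features x samples)")
        if labels.shape[0] != A.shape[1]:
            raise ValueError(
                f"labels length {labels.shape[0]} != column count {A.shape[1]}"
            )
        if A.shape[1] == 0:
            raise ValueError("dictionary must have at least one column")
        if not np.all(np.isfinite(A)):
            raise ValueError("dictionary contains non-finite entries")
        self._A = A
        self._labels = labels
        self._classes = np.unique(labels)

    @property
    def A(self) -> np.ndarray:
        return self._A

    @property
    def labels(self) -> np.ndarray:
        return self._labels

    @property
    def classes(self) -> np.ndarray:
        """Distinct class ids, sorted ascending."""
        return self._classes

    @property
    def n_features(self) -> int:
        return self._A.shape[0]

    @property
    def n_samples(self) -> int:
        return self._A.shape[1]

    def class_counts(self) -> dict:
        return {c: int(np.sum(self._labels == c)) for c in self._classes}

    def append_sample(self, y: np.ndarray, label) -> None:
        """Append one column and its label (``A <- [A, y]; L <- [L, label]``)."""
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != self.n_features:
            raise ValueError(
                f"sample length {y.shape[0]} != feature count {self.n_features}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("sample contains non-finite entries")
        self._A = np.column_stack([self._A, y])
        self._labels = np.append(self._labels, label)
        if label not in self._classes:
            self._classes = np.unique(self._labels)

    def copy(self) -> "LabeledDictionary":
        return LabeledDictionary(self._A.copy(), self._labels.copy())


@dataclass
class ClassScores:
    """Per-class statistics of one coded query."""

    classes: np.ndarray
    residuals: np.ndarray
    averages: np.ndarray
    predicted: object = None
    code: SparseCode | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (len(self.classes) == len(self.residuals) == len(self.averages)):
            raise ValueError("classes, residuals and averages must align")
        if np.any(self.residuals < 0):
            raise ValueError("residuals must be nonnegative")


def score_src(
    dictionary: LabeledDictionary,
    y: np.ndarray,
    settings: SolverSettings | None = None,
) -> ClassScores:
    """Code ``y`` on the dictionary and compute per-class residuals/averages.

    ``residuals[i]`` is ``||y - A @ delta_i(x_hat)||_2`` where ``delta_i``
    keeps only class-i coefficients; ``averages[i]`` is the mean of ALL
    class-i coefficients (zeros included: class-i coefficient sum divided
    by class-i column count).  The ``predicted`` field is left ``None``
    for the caller's decision rule.
    """
    settings = settings or SolverSettings()
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != dictionary.n_features:
        raise ValueError(
            f"query length {y.shape[0]} != feature count {dictionary.n_features}"
        )
    A, labels = dictionary.A, dictionary.labels
    tau = settings.resolve_tau(A, y)
    code = solve_l1(
        SparseProblem(A=A, y=y, tau=tau, tol=settings.tol, max_iter=settings.max_iter)
    )
    classes = dictionary.classes
    residuals = np.empty(len(classes))
    averages = np.empty(len(classes))
    for i, c in enumerate(classes):
        mask = labels == c
        xc = np.where(mask, code.x_hat, 0.0)
        residuals[i] = float(np.linalg.norm(y - A @ xc))
        averages[i] = float(code.x_hat[mask].sum() / mask.sum())
    return ClassScores(classes=classes, residuals=residuals, averages=averages, code=code)


def predict_src(scores: ClassScores):
    """Residual rule: class with the smallest residual, ties to lowest id."""
    if len(scores.classes) == 0:
        raise ValueError("empty scores")
    return scores.classes[int(np.argmin(scores.residuals))]


def predict_src_ave(scores: ClassScores):
    """Average-coefficient rule: largest class mean, ties to lowest id."""
    if len(scores.classes) == 0:
        raise ValueError("empty scores")
    return scores.classes[int(np.argmax(scores.averages))]


@dataclass
class LDCModel:
    """Linear discriminant with shrunk pooled covariance.

    Stores per-class means, the shrunk common covariance and class
    priors; prediction uses the linear discriminant score
    ``g_i(x) = ln P_i - 0.5 mu_i' S^-1 mu_i + mu_i' S^-1 x``.
    """

    classes: np.ndarray
    means: np.ndarray  # (n_classes, n_features)
    pooled_cov: np.ndarray  # (n_features, n_features), after shrinkage
    priors: np.ndarray
    shrinkage: float
    _cov_inv_means: np.ndarray = field(default=None, repr=False)  # S^-1 mu_i, cached

    def __post_init__(self) -> None:
        if abs(float(self.priors.sum()) - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")
        if self._cov_inv_means is None:
            # solve once; every query reuses the factorization result
            self._cov_inv_means = np.linalg.solve(self.pooled_cov, self.means.T).T

    def discriminants(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float).ravel()
        lin = self._cov_inv_means @ y
        quad = 0.5 * np.einsum("ij,ij->i", self.means, self._cov_inv_means)
        return np.log(self.priors) - quad + lin


def _ledoit_wolf_gamma(centered: np.ndarray) -> float:
    """Ledoit-Wolf shrinkage intensity toward the scaled identity.

    ``centered`` holds class-mean-centered samples in rows.
    """
    from sklearn.covariance import ledoit_wolf

    _, gamma = ledoit_wolf(centered, assume_centered=True)
    return float(gamma)


def fit_ldc(X: np.ndarray, labels, shrinkage: float | None = None) -> LDCModel:
    """Fit the linear discriminant from rows-as-samples data.

    ``pooled_cov = (1 - g) * S + g * mu * I`` with ``S`` the pooled
    within-class covariance and ``mu = trace(S)/p``; ``g`` defaults to
    the Ledoit-Wolf analytic intensity computed on class-centered data.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match sample count")
    classes = np.unique(labels)
    n, p = X.shape
    means = np.empty((len(classes), p))
    priors = np.empty(len(classes))
    centered = np.empty_like(X)
    for i, c in enumerate(classes):
        mask = labels == c
        if not mask.any():
            raise ValueError(f"class {c!r} has no samples")
        means[i] = X[mask].mean(axis=0)
        priors[i] = mask.sum() / n
        centered[mask] = X[mask] - means[i]
    S = (centered.T @ centered) / n
    if shrinkage is None:
        shrinkage = _ledoit_wolf_gamma(centered)
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    mu = float(np.trace(S)) / p
    if mu <= 0.0:
        mu = 1.0  # degenerate zero-variance data: keep the matrix SPD
    pooled = (1.0 - shrinkage) * S + shrinkage * mu * np.eye(p)
    return LDCModel(
        classes=classes,
        means=means,
        pooled_cov=pooled,
        priors=priors,
        shrinkage=shrinkage,
    )


def predict_ldc(model: LDCModel, y: np.ndarray):
    """Largest discriminant score wins; ties break to the lowest class id."""
    g = model.discriminants(y)
    return model.classes[int(np.argmax(g))]
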