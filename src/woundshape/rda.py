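"""Regularized discriminant analysis with double shrinkage, plus diagnostics.

Class covariances are shrunk twice (Friedman-style):

    Sigma_k(lambda)        = (1 - lambda) * S_k + lambda * S_pooled
    Sigma_k(lambda, gamma) = (1 - gamma) * Sigma_k(lambda)
                             + gamma * (trace(Sigma_k(lambda)) / p) * I

``lambda = 1, gamma = 0`` recovers LDA (one pooled covariance),
``lambda = gamma = 0`` recovers QDA.  With few samples per class and tens
of descriptors the per-class covariances are singular, which is exactly why
the shrinkage is needed; the defaults ``lambda = 0.99, gamma = 0.001`` are
an almost-linear model with a whisper of ridge.

Samples are classified by the quadratic discriminant score

    ds_k(x) = (x - mu_k)^T Sigma_k^{-1} (x - mu_k) + ln det Sigma_k
              - 2 ln prior_k

(argmin wins; ties break to the lowest class index).  An alternative
``gamma`` target — the literal diagonal of Sigma_k(lambda) instead of the
scaled identity — is available via ``gamma_target="diagonal"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

log = logging.getLogger(__name__)


class DiscriminantError(ValueError):
    pass


class SingularCovarianceError(DiscriminantError):
    """A shrunken class covariance is not positive definite; increase gamma."""


@dataclass
class RDAParams:
    lam: float = 0.99  # shrinkage toward the pooled covariance
    gamma: float = 0.001  # shrinkage toward the scaled identity
    priors: np.ndarray | None = None  # default: uniform
    gamma_target: str = "identity"  # or "diagonal"

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0 and 0.0 <= self.gamma <= 1.0):
            raise ValueError("lambda and gamma must lie in [0, 1]")
        if self.priors is not None:
            self.priors = np.asarray(self.priors, dtype=float)
            if np.any(self.priors < 0) or abs(self.priors.sum() - 1.0) > 1e-12:
                raise ValueError("priors must be non-negative and sum to 1")
        if self.gamma_target not in ("identity", "diagonal"):
            raise ValueError("gamma_target must be 'identity' or 'diagonal'")


def lda_params() -> RDAParams:
    """The LDA baseline expressed as the RDA limit lambda=1, gamma=0."""
    return RDAParams(lam=1.0, gamma=0.0)


@dataclass
class Standardization:
    mean: np.ndarray
    sd: np.ndarray


def standardize(
    matrix: np.ndarray, reference: Standardization | None = None
) -> tuple[np.ndarray, Standardization]:
    """Center/scale columns to mean 0, sd 1 (sample sd, ddof=1).

    When ``reference`` is given (test data), its training-derived statistics
    are applied instead of recomputing them — the leakage guard.
    """
    matrix = np.asarray(matrix, dtype=float)
    if reference is None:
        mean = matrix.mean(axis=0)
        sd = matrix.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if len(zero):
            raise DiscriminantError(
                f"zero-variance training column(s) {zero.tolist()}; "
                "these should have been filtered out"
            )
        reference = Standardization(mean=mean, sd=sd)
    elif reference.mean.shape[0] != matrix.shape[1]:
        raise DiscriminantError("standardization statistics do not match matrix width")
    return (matrix - reference.mean) / reference.sd, reference


@dataclass
class RDAModel:
    standardization: Standardization
    class_labels: np.ndarray
    means: np.ndarray  # (k, p)
    covariances: np.ndarray  # (k, p, p) shrunken
    priors: np.ndarray
    params: RDAParams
    feature_indices: np.ndarray | None = None  # indices into the 1284 vector
    _chol: np.ndarray = field(init=False, repr=False)
    _logdet: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        chols, logdets = [], []
        for k, cov in enumerate(self.covariances):
            try:
                c = linalg.cholesky(cov, lower=True)
            except linalg.LinAlgError as exc:
                raise SingularCovarianceError(
                    f"class {self.class_labels[k]!r}: shrunken covariance is "
                    "singular; increase gamma"
                ) from exc
            chols.append(c)
            logdets.append(2.0 * np.sum(np.log(np.diag(c))))
        self._chol = np.stack(chols)
        self._logdet = np.asarray(logdets)


@dataclass
class ClassificationResult:
    predicted: np.ndarray  # class labels
    scores: np.ndarray  # (n, k) discriminant scores ds (lower = closer)
    weights: np.ndarray  # (n, k) softmax-style posterior weights
    class_labels: np.ndarray


def fit_rda(
    matrix: np.ndarray,
    labels: np.ndarray,
    params: RDAParams | None = None,
    standardization: Standardization | None = None,
    feature_indices: np.ndarray | None = None,
) -> RDAModel:
    """Fit RDA on a standardized training matrix.

    ``standardization`` records the statistics that produced the matrix so
    the model can transform test data identically.
    """
    params = params or RDAParams()
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    n, p = matrix.shape
    groups = [np.flatnonzero(labels == c) for c in classes]
    for c, g in zip(classes, groups):
        if len(g) < 2:
            raise DiscriminantError(f"class {c!r} has fewer than 2 samples")
    means = np.stack([matrix[g].mean(axis=0) for g in groups])
    covs = np.stack([np.cov(matrix[g].T, ddof=1).reshape(p, p) for g in groups])
    dof = sum(len(g) - 1 for g in groups)
    pooled = sum((len(g) - 1) * c for g, c in zip(groups, covs)) / dof
    lam, gamma = params.lam, params.gamma
    shrunk = []
    for cov in covs:
        s_lam = (1.0 - lam) * cov + lam * pooled
        if params.gamma_target == "identity":
            target = (np.trace(s_lam) / p) * np.eye(p)
        else:
            target = np.diag(np.diag(s_lam))
        shrunk.append((1.0 - gamma) * s_lam + gamma * target)
    priors = (
        params.priors
        if params.priors is not None
        else np.full(len(classes), 1.0 / len(classes))
    )
    if len(priors) != len(classes):
        raise DiscriminantError("priors length does not match number of classes")
    if standardization is None:
        standardization = Standardization(mean=np.zeros(p), sd=np.ones(p))
    return RDAModel(
        standardization=standardization,
        class_labels=classes,
        means=means,
        covariances=np.stack(shrunk),
        priors=priors,
        params=params,
        feature_indices=feature_indices,
    )


def discriminant_scores(model: RDAModel, matrix: np.ndarray) -> np.ndarray:
    """(n, k) matrix of ds_k(x); lower score = more likely member."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] != model.means.shape[1]:
        raise DiscriminantError("feature count does not match the fitted model")
    n = matrix.shape[0]
    k = len(model.class_labels)
    scores = np.empty((n, k))
    for i in range(k):
        diff = matrix - model.means[i]
        y = linalg.solve_triangular(model._chol[i], diff.T, lower=True)
        maha2 = np.sum(y**2, axis=0)
        scores[:, i] = maha2 + model._logdet[i] - 2.0 * np.log(model.priors[i])
    return scores


def classify(model: RDAModel, matrix: np.ndarray) -> ClassificationResult:
    """Assign each (already standardized) sample to the argmin-score class."""
    scores = discriminant_scores(model, matrix)
    pred_idx = np.argmin(scores, axis=1)  # argmin breaks ties to lowest index
    shifted = -0.5 * (scores - scores.min(axis=1, keepdims=True))
    weights = np.exp(shifted)
    weights /= weights.sum(axis=1, keepdims=True)
    return ClassificationResult(
        predicted=model.class_labels[pred_idx],
        scores=scores,
        weights=weights,
        class_labels=model.class_labels,
    )


def mahalanobis_distances(model: RDAModel, matrix: np.ndarray) -> np.ndarray:
    """(n, k) Mahalanobis distances to every class mean under Sigma_k."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    k = len(model.class_labels)
    out = np.empty((n, k))
    for i in range(k):
        diff = matrix - model.means[i]
        y = linalg.solve_triangular(model._chol[i], diff.T, lower=True)
        out[:, i] = np.sqrt(np.sum(y**2, axis=0))
    return out


def roc_auc_one_vs_rest(result: ClassificationResult, labels: np.ndarray) -> dict:
    """Per-class one-vs-rest AUC from the negated discriminant scores.

    Computed with the rank (Mann-Whitney) formula using midranks for ties:
    AUC_k = (R_pos - n_pos (n_pos + 1) / 2) / (n_pos * n_neg) where R_pos is
    the rank sum of the class-k samples under the membership score -ds_k.
    """
    labels = np.asarray(labels)
    aucs = {}
    for i, c in enumerate(result.class_labels):
        pos = labels == c
        n_pos = int(pos.sum())
        n_neg = len(labels) - n_pos
        if n_pos == 0 or n_neg == 0:
            raise DiscriminantError(f"class {c!r} absent from labels; AUC undefined")
        score = -result.scores[:, i]
        ranks = stats.rankdata(score)
        aucs[c] = float(
            (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        )
    return aucs


DEFAULT_LAMBDA_GRID = (0.0, 0.25, 0.5, 0.75, 0.9, 0.99, 1.0)
DEFAULT_GAMMA_GRID = (0.0, 0.001, 0.01, 0.1, 1.0)


def grid_search(
    matrix: np.ndarray,
    labels: np.ndarray,
    lambdas=DEFAULT_LAMBDA_GRID,
    gammas=DEFAULT_GAMMA_GRID,
) -> list[dict]:
    """Training-set CRR over a crude (lambda, gamma) grid.

    Combinations whose covariances stay singular are reported with CRR None.
    """
    labels = np.asarray(labels)
    rows = []
    for lam in lambdas:
        for gamma in gammas:
            try:
                model = fit_rda(matrix, labels, RDAParams(lam=lam, gamma=gamma))
                pred = classify(model, matrix).predicted
                crr = float(np.mean(pred == labels))
            except SingularCovarianceError:
                crr = None
            rows.append({"lambda": lam, "gamma": gamma, "training_crr": crr})
    return rows
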