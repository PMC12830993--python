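"""Rejection-capable PCA-LDA classification with Mahalanobis gating.

The model reduces TIC-normalised binned spectra with PCA (components kept
until a configured fraction of variance, default 95%, optionally hard-capped),
projects the retained scores onto LDA discriminant axes (one axis for the
two-class problem), and summarises each class in LDA space by its cluster
centre and covariance. A query spectrum is classified to the class with the
smallest Mahalanobis distance — the number of standard deviations from the
cluster centre — unless that minimum exceeds the rejection threshold
(default 4 SD), in which case the spectrum is *unclassifiable* and no call
is made. Class probabilities follow the Gaussian-likelihood softmax
p_c ∝ exp(-d_c²/2) over the per-class distances.

Per-class covariances are population (ddof=0) estimates shrunk toward the
pooled covariance (λ=0.1 by default) so that a small class cannot produce a
degenerate or wildly optimistic spread. Mahalanobis distances are invariant
to any affine rescaling of the LDA axis, which keeps classifications stable
under exact duplication of the training set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "RejectionLdaModel",
    "ClassificationResult",
    "SpecimenCall",
    "fit",
    "mahalanobis",
    "classify",
    "classify_matrix",
    "classify_specimen",
]

OUTCOME_CLASSIFIED = "classified"
OUTCOME_UNCLASSIFIABLE = "unclassifiable"
OUTCOME_BAD = "bad_data"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ClassificationResult:
    event_id: str
    outcome: str  # classified | unclassifiable | bad_data
    label: str | None = None
    distances: dict[str, float] | None = None
    probabilities: dict[str, float] | None = None

    @property
    def winning_probability(self) -> float | None:
        if self.outcome != OUTCOME_CLASSIFIED:
            return None
        return self.probabilities[self.label]


@dataclass
class RejectionLdaModel:
    """Fitted PCA basis + LDA projection + per-class LDA-space statistics."""

    classes: list[str]
    pca_mean: np.ndarray
    pca_components: np.ndarray  # (k, n_features)
    explained_variance_fraction: float
    lda: LinearDiscriminantAnalysis
    class_means: np.ndarray  # (n_classes, n_axes)
    class_covs: np.ndarray  # (n_classes, n_axes, n_axes), shrunk
    sd_threshold: float
    n_features: int
    config: dict = field(default_factory=dict)

    def project(self, X: np.ndarray) -> np.ndarray:
        """PCA then LDA projection of raw feature vectors to LDA scores."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        scores = (X - self.pca_mean) @ self.pca_components.T
        return self.lda.transform(scores)


def mahalanobis(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Mahalanobis distance sqrt((x-μ)ᵀ Σ⁻¹ (x-μ)); |x-μ|/σ in one dimension.

    Raises on a singular covariance — regularisation is the caller's job.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    diff = x - mean
    try:
        chol = scipy.linalg.cho_factor(cov)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular covariance: {err}") from None
    z = scipy.linalg.cho_solve(chol, diff)
    return float(np.sqrt(diff @ z))


def _class_stats(
    scores: np.ndarray, y: np.ndarray, classes: list[str], shrinkage: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class mean and shrunk covariance of LDA scores.

    Population (ddof=0) covariances, each shrunk toward the pooled
    within-class covariance: Σ_c ← (1-λ) Σ_c + λ Σ_pooled.
    """
    n_axes = scores.shape[1]
    means = np.zeros((len(classes), n_axes))
    raw = np.zeros((len(classes), n_axes, n_axes))
    pooled = np.zeros((n_axes, n_axes))
    for i, c in enumerate(classes):
        pts = scores[y == c]
        means[i] = pts.mean(axis=0)
        centred = pts - means[i]
        raw[i] = centred.T @ centred / len(pts)
        pooled += centred.T @ centred
    pooled /= len(scores)
    covs = (1.0 - shrinkage) * raw + shrinkage * pooled[None, :, :]
    # floor to avoid exact singularity in pathological (zero-variance) cases
    eps = 1e-12 * max(np.trace(pooled) / n_axes, 1.0)
    covs += eps * np.eye(n_axes)[None, :, :]
    return means, covs


def fit(
    X: np.ndarray,
    y: np.ndarray,
    variance_fraction: float = 0.95,
    sd_threshold: float = 4.0,
    component_cap: int | None = None,
    shrinkage: float = 0.1,
    oversampler=None,
) -> RejectionLdaModel:
    """Fit the rejection-capable PCA-LDA model.

    Parameters
    ----------
    X, y
        QC-good feature matrix (events × bins) and class labels.
    variance_fraction
        Keep the smallest number of leading PCA components whose cumulative
        explained-variance ratio reaches this fraction.
    component_cap
        Optional hard cap on retained components (the fixed-cap behaviour of
        projection-based modelling software; e.g. 262). Applied after the
        variance rule.
    oversampler
        Optional callable ``(scores, y) -> (scores, y)`` applied to PCA
        scores before the LDA step (e.g. SMOTE augmentation of a minority
        class). Only the training path is affected.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes to fit a discriminant model")
    counts = Counter(y.tolist())
    if min(counts.values()) < 2:
        raise ValueError("each class needs at least two events")

    max_rank = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=max_rank, svd_solver="full").fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_fraction) + 1)
    k = min(k, max_rank)
    if component_cap is not None:
        k = min(k, component_cap)
    components = pca.components_[:k]
    scores = (X - pca.mean_) @ components.T

    if oversampler is not None:
        scores_fit, y_fit = oversampler(scores, y)
    else:
        scores_fit, y_fit = scores, y

    lda = LinearDiscriminantAnalysis(solver="svd").fit(scores_fit, y_fit)
    lda_scores = lda.transform(scores_fit)
    means, covs = _class_stats(lda_scores, np.asarray(y_fit), classes, shrinkage)

    return RejectionLdaModel(
        classes=classes,
        pca_mean=pca.mean_,
        pca_components=components,
        explained_variance_fraction=float(cum[k - 1]),
        lda=lda,
        class_means=means,
        class_covs=covs,
        sd_threshold=sd_threshold,
        n_features=X.shape[1],
        config={
            "variance_fraction": variance_fraction,
            "component_cap": component_cap,
            "shrinkage": shrinkage,
            "n_components": k,
        },
    )


def classify(
    x: np.ndarray,
    model: RejectionLdaModel,
    event_id: str = "",
    sd_threshold: float | None = None,
) -> ClassificationResult:
    """Classify one QC-good feature vector, or reject it as unclassifiable.

    The winning class is the argmin of the per-class Mahalanobis distances;
    if even that distance exceeds the threshold the spectrum is rejected.
    Equidistant ties resolve to the first class in the model's declared
    order (alphabetical; 'lymphoma' precedes 'pdx').
    """
    return classify_matrix(np.atleast_2d(x), model, [event_id], sd_threshold)[0]


def classify_matrix(
    X: np.ndarray,
    model: RejectionLdaModel,
    event_ids: list[str] | None = None,
    sd_threshold: float | None = None,
) -> list[ClassificationResult]:
    """Vectorised :func:`classify` over the rows of a feature matrix."""
    threshold = model.sd_threshold if sd_threshold is None else sd_threshold
    scores = model.project(X)
    if event_ids is None:
        event_ids = [str(i) for i in range(scores.shape[0])]

    n_axes = scores.shape[1]
    dists = np.empty((scores.shape[0], len(model.classes)))
    for c in range(len(model.classes)):
        diff = scores - model.class_means[c]
        chol = scipy.linalg.cho_factor(model.class_covs[c])
        z = scipy.linalg.cho_solve(chol, diff.T)
        dists[:, c] = np.sqrt(np.einsum("ij,ji->i", diff, z))

    results = []
    for i, eid in enumerate(event_ids):
        d = dists[i]
        dist_map = dict(zip(model.classes, d.tolist()))
        best = int(np.argmin(d))  # argmin takes the first index on ties
        if d[best] > threshold:
            results.append(
                ClassificationResult(eid, OUTCOME_UNCLASSIFIABLE, distances=dist_map)
            )
            continue
        logp = -0.5 * d**2
        p = np.exp(logp - logp.max())
        p /= p.sum()
        results.append(
            ClassificationResult(
                eid,
                OUTCOME_CLASSIFIED,
                label=model.classes[best],
                distances=dist_map,
                probabilities=dict(zip(model.classes, p.tolist())),
            )
        )
    return results


@dataclass(frozen=True)
class SpecimenCall:
    specimen_id: str
    label: str  # class label or 'indeterminate'
    concordance: float | None  # fraction of classified events agreeing
    n_classified: int
    n_events: int


def classify_specimen(
    results: list[ClassificationResult], specimen_id: str = ""
) -> SpecimenCall:
    """Majority call over a specimen's classified events plus the spatial
    concordance (fraction of classified events agreeing with the majority).

    A vote tie, or a specimen with no classified event at all, is
    indeterminate.
    """
    labels = [r.label for r in results if r.outcome == OUTCOME_CLASSIFIED]
    if not labels:
        return SpecimenCall(specimen_id, INDETERMINATE, None, 0, len(results))
    votes = Counter(labels)
    ranked = votes.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return SpecimenCall(specimen_id, INDETERMINATE, None, len(labels), len(results))
    label, n_agree = ranked[0]
    return SpecimenCall(
        specimen_id, label, n_agree / len(labels), len(labels), len(results)
    )
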