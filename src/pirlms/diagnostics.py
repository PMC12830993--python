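"""Unsupervised and post-hoc views of the spectral feature space.

Three diagnostics complement the supervised classifier, none of which may
feed back into a classification decision:

* :func:`umap_embed` — an unsupervised 2-D UMAP embedding of the binned
  spectra, used to check that class separation is visible without labels;
* :func:`correlation_map` / :func:`map_similarity` — 900×900 Pearson
  correlation maps over the 1 Da features of an event subset, the tool used
  to probe *why* particular specimens misclassify by comparing their map
  against per-class control maps built from perfectly-classified specimens;
* :func:`jitter_data` — per-event 1-D LDA scores with a class-overlap
  statistic, quantifying the "degree of mixing" a scores plot shows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import RejectionLdaModel
from .config import UmapParams
from .preprocess import BinnedMatrix

__all__ = [
    "CorrelationMap",
    "umap_embed",
    "correlation_map",
    "map_similarity",
    "control_maps",
    "jitter_data",
]


def umap_embed(matrix: BinnedMatrix, params: UmapParams = UmapParams()) -> pd.DataFrame:
    """2-D UMAP embedding of the feature matrix (visualisation only).

    Deterministic for a fixed seed. Returns one row per event with the
    embedding coordinates and the event annotations for plotting.
    """
    import umap  # deferred: numba compilation is slow at import time

    n = matrix.values.shape[0]
    if n < params.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={params.n_neighbors + 1} events, got {n}"
        )
    reducer = umap.UMAP(
        n_neighbors=params.n_neighbors,
        n_components=params.n_components,
        n_epochs=params.n_epochs,
        metric=params.metric,
        random_state=params.seed,
    )
    coords = reducer.fit_transform(matrix.values)
    out = matrix.annotations.copy()
    for j in range(params.n_components):
        out[f"umap{j + 1}"] = coords[:, j]
    return out


@dataclass
class CorrelationMap:
    """Pearson correlation matrix over 1 Da features across an event subset.

    ``mask`` marks undefined entries (at least one zero-variance feature).
    """

    values: np.ndarray  # (n_features, n_features), NaN where undefined
    mask: np.ndarray  # True where undefined
    tag: str = ""

    @property
    def n_features(self) -> int:
        return self.values.shape[0]


def correlation_map(matrix_1da: BinnedMatrix, tag: str = "") -> CorrelationMap:
    """Feature-by-feature Pearson correlation across the subset's events.

    Requires at least 3 events (2 points pin the coefficient at ±1).
    Zero-variance features yield undefined (masked) coefficients.
    """
    n = matrix_1da.values.shape[0]
    if n < 3:
        raise ValueError(f"correlation map needs >=3 events, got {n}")
    df = pd.DataFrame(matrix_1da.values)
    corr = df.corr().to_numpy()  # pandas leaves zero-variance columns at NaN
    mask = np.isnan(corr)
    return CorrelationMap(values=corr, mask=mask, tag=tag)


def map_similarity(query: CorrelationMap, control: CorrelationMap) -> float:
    """Pearson correlation between the upper triangles of two maps,
    restricted to entries defined in both. The scalar stand-in for the
    visual map comparison: 1 for identical structure, -1 for inverted."""
    if query.n_features != control.n_features:
        raise ValueError("maps must share the feature grid")
    iu = np.triu_indices(query.n_features, k=1)
    a, b = query.values[iu], control.values[iu]
    ok = ~(query.mask[iu] | control.mask[iu])
    if not ok.any():
        raise ValueError("no jointly defined correlation entries")
    a, b = a[ok], b[ok]
    a_c, b_c = a - a.mean(), b - b.mean()
    denom = np.sqrt((a_c**2).sum() * (b_c**2).sum())
    if denom == 0:
        raise ValueError("degenerate (constant) correlation map")
    return float(np.clip((a_c * b_c).sum() / denom, -1.0, 1.0))


def control_maps(
    matrix_1da: BinnedMatrix,
    specimen_calls: pd.DataFrame,
    labels: pd.Series | None = None,
) -> dict[str, CorrelationMap]:
    """Per-class control maps from specimens whose sampling events were all
    correctly classified (concordance 1.0), pooled per class."""
    ann = matrix_1da.annotations
    truth = labels if labels is not None else ann["class_label"]
    perfect = specimen_calls[specimen_calls["concordance"] == 1.0]
    out: dict[str, CorrelationMap] = {}
    for cls_label in sorted(pd.unique(truth.dropna())):
        spec_ids = set(perfect.loc[perfect["call"] == cls_label, "specimen_id"])
        m = ann["specimen_id"].isin(spec_ids).to_numpy()
        if m.sum() >= 3:
            out[cls_label] = correlation_map(
                matrix_1da.subset(m), tag=f"control:{cls_label}"
            )
    return out


def jitter_data(
    model: RejectionLdaModel, matrix: BinnedMatrix, labels: np.ndarray | pd.Series
) -> tuple[pd.DataFrame, float]:
    """Per-event 1-D LDA scores for jitter plotting, plus an overlap statistic.

    The overlap statistic is the fraction of events whose score falls inside
    the intersection of the two classes' score ranges — ≈0 for cleanly
    separated classes, ≈1 when the class distributions coincide.
    """
    if len(model.classes) != 2:
        raise ValueError("jitter data is defined for the 2-class model")
    scores = model.project(matrix.values)[:, 0]
    y = np.asarray(labels)
    groups = sorted(np.unique(y).tolist())
    if len(groups) != 2:
        raise ValueError("jitter overlap needs exactly two label groups")
    records = matrix.annotations.copy()
    records["lda_score"] = scores
    records["class_label"] = y

    a, b = (scores[y == c] for c in groups)
    lo, hi = max(a.min(), b.min()), min(a.max(), b.max())
    overlap = float(np.mean((scores >= lo) & (scores <= hi))) if hi > lo else 0.0
    return records, overlap
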