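"""Specimen-grouped validation and accounting for the rejection classifier.

Multiple sampling events from one specimen share a specimen-level random
effect, so event-level cross-validation would leak. All validation here is
*full-group*: every event of a specimen travels with it into exactly one
fold (StratifiedGroupKFold), and a permuted-label null reassigns whole
specimens to two pseudo-groups, each a mixture of both true classes.

Accounting follows the two-denominator convention of rejection-capable
classification: *per-classifiable* accuracy divides correct calls by
correct + misclassified (rejected spectra carry no decision), while
*per-all* accuracy divides by every sampling attempt. The duty cycle is the
fraction of attempts that yield a class prediction at all — attempts lost
to QC ("bad data") and to Mahalanobis rejection ("unclassifiable") both
count against it.

SMOTE augmentation of the minority class is implemented in-package (linear
interpolation between a minority point and one of its k nearest minority
neighbours, in PCA-score space) and applied inside each training fold only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.neighbors import NearestNeighbors

from . import classifier as clf
from .preprocess import QC_GOOD, BinnedMatrix
from .synthetic import SealedGroundTruth

__all__ = [
    "FoldPlan",
    "CvReport",
    "BlindReport",
    "make_folds",
    "cross_validate",
    "permute_labels",
    "smote_cross_validate",
    "make_smote_oversampler",
    "roc_curve",
    "blind_evaluate",
    "sensitivity",
    "specificity",
    "duty_cycle",
]


# ---------------------------------------------------------------------------
# small accounting primitives (Table-style arithmetic)
# ---------------------------------------------------------------------------

def sensitivity(tp: int, fn: int) -> float:
    """True-positive rate, in percent."""
    return 100.0 * tp / (tp + fn)


def specificity(tn: int, fp: int) -> float:
    """True-negative rate, in percent."""
    return 100.0 * tn / (tn + fp)


def duty_cycle(classifiable: int, attempts: int) -> float:
    """Percent of sampling attempts yielding a class prediction."""
    return 100.0 * classifiable / attempts


# ---------------------------------------------------------------------------
# fold planning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Specimen-level fold assignment for full-group cross-validation."""

    k: int
    assignment: dict[str, int]  # specimen id -> fold index
    seed: int

    def test_specimens(self, fold: int) -> set[str]:
        return {s for s, f in self.assignment.items() if f == fold}

    def event_fold(self, specimen_ids: pd.Series | np.ndarray) -> np.ndarray:
        return np.array([self.assignment[s] for s in specimen_ids])


def make_folds(
    annotations: pd.DataFrame, k: int = 5, seed: int = 0
) -> FoldPlan:
    """Class-stratified specimen-grouped k-fold plan.

    ``annotations`` needs event-level ``specimen_id`` and ``class_label``
    columns; every event of a specimen lands in exactly one fold.
    """
    specimens = annotations[["specimen_id", "class_label"]].drop_duplicates()
    if specimens["specimen_id"].duplicated().any():
        raise ValueError("class label inconsistent within a specimen")
    if len(specimens) < k:
        raise ValueError(f"only {len(specimens)} specimens for {k} folds")
    sgk = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    y = annotations["class_label"].to_numpy()
    groups = annotations["specimen_id"].to_numpy()
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(
        sgk.split(np.zeros(len(annotations)), y, groups)
    ):
        for s in np.unique(groups[test_idx]):
            assignment[str(s)] = fold
    return FoldPlan(k=k, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# cross-validation report
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Per-fold and total accounting of a full-group cross-validation.

    ``folds`` columns: fold, total, correct, misclassified, unclassifiable.
    ``confusion`` rows are true classes, columns predicted classes plus an
    'unclassifiable' column.
    """

    folds: pd.DataFrame
    confusion: pd.DataFrame | None = None
    event_results: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        f = self.folds
        if not (
            f["correct"] + f["misclassified"] + f["unclassifiable"] == f["total"]
        ).all():
            raise ValueError("fold counts do not conserve: c + m + u != total")

    @classmethod
    def from_counts(
        cls, total: int, correct: int, misclassified: int, unclassifiable: int
    ) -> "CvReport":
        """Single-row report from raw counts (e.g. a published table row)."""
        return cls(
            pd.DataFrame(
                {
                    "fold": [0],
                    "total": [total],
                    "correct": [correct],
                    "misclassified": [misclassified],
                    "unclassifiable": [unclassifiable],
                }
            )
        )

    # -- totals ------------------------------------------------------------
    @property
    def total(self) -> int:
        return int(self.folds["total"].sum())

    @property
    def correct(self) -> int:
        return int(self.folds["correct"].sum())

    @property
    def misclassified(self) -> int:
        return int(self.folds["misclassified"].sum())

    @property
    def unclassifiable(self) -> int:
        return int(self.folds["unclassifiable"].sum())

    @property
    def classifiable(self) -> int:
        return self.correct + self.misclassified

    # -- derived metrics ----------------------------------------------------
    @property
    def accuracy_per_classifiable(self) -> float:
        """Correct / (correct + misclassified), percent; rejected spectra
        carry no decision and are excluded."""
        return 100.0 * self.correct / self.classifiable

    @property
    def accuracy_per_all(self) -> float:
        """Correct / all sampling attempts (classifiable + unclassifiable),
        percent."""
        return 100.0 * self.correct / self.total

    @property
    def fold_averaged_per_classifiable(self) -> float:
        """Mean over folds of the per-classifiable accuracy (the published
        convention for the permuted-model number)."""
        f = self.folds
        per_fold = 100.0 * f["correct"] / (f["correct"] + f["misclassified"])
        return float(per_fold.mean())

    @property
    def duty_cycle(self) -> float:
        return duty_cycle(self.classifiable, self.total)

    def to_table(self) -> pd.DataFrame:
        """Table-1-style layout: per-fold rows plus a total row."""
        rows = self.folds.copy()
        rows["classifiable"] = rows["correct"] + rows["misclassified"]
        rows["per_classifiable_pct"] = (
            100.0 * rows["correct"] / rows["classifiable"]
        ).round(2)
        rows["per_all_pct"] = (100.0 * rows["correct"] / rows["total"]).round(2)
        total = pd.DataFrame(
            {
                "fold": ["total"],
                "total": [self.total],
                "correct": [self.correct],
                "misclassified": [self.misclassified],
                "unclassifiable": [self.unclassifiable],
                "classifiable": [self.classifiable],
                "per_classifiable_pct": [round(self.accuracy_per_classifiable, 2)],
                "per_all_pct": [round(self.accuracy_per_all, 2)],
            }
        )
        return pd.concat([rows, total], ignore_index=True)[total.columns]


def _count_fold(results: list[clf.ClassificationResult], truth: np.ndarray) -> dict:
    correct = sum(
        1
        for r, t in zip(results, truth)
        if r.outcome == clf.OUTCOME_CLASSIFIED and r.label == t
    )
    mis = sum(
        1
        for r, t in zip(results, truth)
        if r.outcome == clf.OUTCOME_CLASSIFIED and r.label != t
    )
    uncl = sum(1 for r in results if r.outcome == clf.OUTCOME_UNCLASSIFIABLE)
    return {
        "total": len(results),
        "correct": correct,
        "misclassified": mis,
        "unclassifiable": uncl,
    }


def cross_validate(
    matrix: BinnedMatrix,
    labels: np.ndarray | pd.Series,
    plan: FoldPlan,
    oversampler_factory=None,
    **fit_kwargs,
) -> CvReport:
    """Full-group k-fold cross-validation of the rejection PCA-LDA model.

    Only QC-good events are scored. For each fold a model is fit on the
    training specimens' events and every held-out event is classified;
    counts are aggregated per fold and in total. Deterministic given the
    fold plan and fit settings.
    """
    good = matrix.good_mask() & ~matrix.annotations["empty_row"].to_numpy()
    ann = matrix.annotations.loc[good].reset_index(drop=True)
    X = matrix.values[good]
    y = np.asarray(labels)[good] if len(labels) == len(good) else np.asarray(labels)
    if len(y) != len(ann):
        raise ValueError("labels must align with events (all or QC-good only)")
    folds_of_events = plan.event_fold(ann["specimen_id"])

    rows, conf_rows, event_rows = [], [], []
    classes = sorted(np.unique(y).tolist())
    conf = pd.DataFrame(
        0, index=classes, columns=classes + ["unclassifiable"], dtype=int
    )
    for fold in range(plan.k):
        test = folds_of_events == fold
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {fold}: training set contains a single class")
        oversampler = (
            oversampler_factory(fold) if oversampler_factory is not None else None
        )
        model = clf.fit(X[train], y[train], oversampler=oversampler, **fit_kwargs)
        results = clf.classify_matrix(
            X[test], model, ann.loc[test, "event_id"].tolist()
        )
        truth = y[test]
        rows.append({"fold": fold, **_count_fold(results, truth)})
        for r, t in zip(results, truth):
            if r.outcome == clf.OUTCOME_CLASSIFIED:
                conf.loc[t, r.label] += 1
            elif r.outcome == clf.OUTCOME_UNCLASSIFIABLE:
                conf.loc[t, "unclassifiable"] += 1
            event_rows.append(
                {
                    "event_id": r.event_id,
                    "fold": fold,
                    "true": t,
                    "outcome": r.outcome,
                    "predicted": r.label,
                    "probability": r.winning_probability,
                }
            )
        conf_rows.append(fold)

    return CvReport(
        folds=pd.DataFrame(rows),
        confusion=conf,
        event_results=pd.DataFrame(event_rows),
    )


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def permute_labels(
    annotations: pd.DataFrame, seed: int = 0
) -> tuple[pd.Series, pd.DataFrame]:
    """Specimen-level label permutation into two balanced pseudo-groups.

    Each true class's specimens are split (near-)evenly between pseudo-group
    1 and 2, so both groups are a mixture of both classes with near-equal
    specimen counts — the null under which any residual discrimination is
    specimen noise, not biology. Whole specimens move together so the
    full-group CV structure survives.

    Returns event-level pseudo-labels (aligned with ``annotations``) and the
    specimen-level assignment table.
    """
    specimens = annotations[["specimen_id", "class_label"]].drop_duplicates()
    if specimens["class_label"].nunique() < 2:
        raise ValueError("permutation needs two true classes present")
    if len(specimens) < 4:
        raise ValueError("too few specimens to permute meaningfully")
    rng = np.random.default_rng(seed)
    assign: dict[str, str] = {}
    flip = 0
    for _, cls_specimens in specimens.groupby("class_label", sort=True):
        ids = cls_specimens["specimen_id"].to_numpy().copy()
        rng.shuffle(ids)
        half = len(ids) // 2
        extra = len(ids) - 2 * half
        # alternate which pseudo-group receives an odd specimen
        first = half + (extra if flip % 2 == 0 else 0)
        flip += extra
        for s in ids[:first]:
            assign[s] = "group1"
        for s in ids[first:]:
            assign[s] = "group2"
    table = pd.DataFrame(
        {"specimen_id": list(assign), "pseudo_group": list(assign.values())}
    )
    event_labels = annotations["specimen_id"].map(assign).rename("pseudo_group")
    return event_labels, table


# ---------------------------------------------------------------------------
# SMOTE (in-package; interpolation between minority neighbours)
# ---------------------------------------------------------------------------

def _smote_oversample(
    scores: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance all classes up to the majority count by SMOTE interpolation."""
    y = np.asarray(y)
    counts = pd.Series(y).value_counts()
    n_target = int(counts.max())
    out_X, out_y = [scores], [y]
    for cls_label, n in counts.items():
        deficit = n_target - int(n)
        if deficit == 0:
            continue
        pts = scores[y == cls_label]
        k = min(k_neighbors, len(pts) - 1)
        if k < 1:
            raise ValueError(f"class {cls_label!r} too small for SMOTE")
        if k < k_neighbors:
            warnings.warn(
                f"SMOTE neighbours reduced to {k} for class {cls_label!r}",
                stacklevel=2,
            )
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
        _, idx = nn.kneighbors(pts)  # column 0 is the point itself
        base = rng.integers(0, len(pts), size=deficit)
        neigh = idx[base, rng.integers(1, k + 1, size=deficit)]
        gap = rng.random(deficit)[:, None]
        synth = pts[base] + gap * (pts[neigh] - pts[base])
        out_X.append(synth)
        out_y.append(np.full(deficit, cls_label, dtype=y.dtype))
    return np.vstack(out_X), np.concatenate(out_y)


def make_smote_oversampler(seed: int = 0, k_neighbors: int = 5):
    """Oversampler factory for :func:`cross_validate` / :func:`pirlms.classifier.fit`."""

    def factory(fold: int):
        rng = np.random.default_rng(np.random.SeedSequence([seed, fold]))

        def oversample(scores, y):
            return _smote_oversample(scores, y, rng, k_neighbors)

        return oversample

    return factory


def smote_cross_validate(
    matrix: BinnedMatrix,
    labels: np.ndarray | pd.Series,
    plan: FoldPlan,
    seed: int = 0,
    k_neighbors: int = 5,
    **fit_kwargs,
) -> CvReport:
    """Cross-validation with per-fold SMOTE augmentation of the minority
    class, applied to PCA scores before the LDA step. Test folds are never
    augmented and are identical to those of :func:`cross_validate`."""
    return cross_validate(
        matrix,
        labels,
        plan,
        oversampler_factory=make_smote_oversampler(seed, k_neighbors),
        **fit_kwargs,
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_curve(
    scores: np.ndarray, labels: np.ndarray, positive_class: str | int = "lymphoma"
) -> tuple[pd.DataFrame, float]:
    """Threshold-independent performance: ROC points and its AUC.

    ``scores`` are per-event scores for the positive class (softmax
    probability by default upstream; a signed LDA score works equally).
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, pos_label=positive_class)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return curve, float(_sk_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# blind evaluation
# ---------------------------------------------------------------------------

@dataclass
class BlindReport:
    """Blind-set accounting: attempts, losses, 2×2 contingency and the
    headline rates, with '± half SD' dispersion for probability and spatial
    concordance (the reporting convention used for these cohorts)."""

    attempts: int
    bad: int
    unclassifiable: int
    contingency: pd.DataFrame  # rows: true class; columns: predicted class
    mean_probability: float
    probability_halfsd: float
    mean_concordance: float
    concordance_halfsd: float
    sd_scale: float = 0.5
    event_results: pd.DataFrame | None = None
    specimen_calls: pd.DataFrame | None = None

    @property
    def classifiable(self) -> int:
        return int(self.contingency.to_numpy().sum())

    @property
    def duty_cycle(self) -> float:
        return duty_cycle(self.classifiable, self.attempts)

    def sensitivity(self, positive_class: str) -> float:
        tp = int(self.contingency.loc[positive_class, positive_class])
        fn = int(self.contingency.loc[positive_class].sum()) - tp
        return sensitivity(tp, fn)

    def specificity(self, positive_class: str) -> float:
        neg = [c for c in self.contingency.index if c != positive_class]
        tn = int(self.contingency.loc[neg, neg].to_numpy().sum())
        fp = int(self.contingency.loc[neg, positive_class].sum())
        return specificity(tn, fp)


def blind_evaluate(
    matrix: BinnedMatrix,
    model: clf.RejectionLdaModel,
    sealed: SealedGroundTruth | pd.DataFrame,
    sd_scale: float = 0.5,
) -> BlindReport:
    """Score a sealed blind set against a fitted model.

    Every sampling attempt is accounted for: QC failures are *bad*,
    Mahalanobis rejections *unclassifiable*, and the 2×2 contingency (and
    hence sensitivity/specificity) uses classified events only. Truth is
    unsealed here, at scoring time, and nowhere else.
    """
    ann = matrix.annotations
    truth = sealed.unseal() if isinstance(sealed, SealedGroundTruth) else sealed
    truth = truth.set_index("event_id")

    good = matrix.good_mask() & ~ann["empty_row"].to_numpy()
    results: dict[str, clf.ClassificationResult] = {}
    for eid in ann.loc[~good, "event_id"]:
        results[eid] = clf.ClassificationResult(eid, clf.OUTCOME_BAD)
    for r in clf.classify_matrix(
        matrix.values[good], model, ann.loc[good, "event_id"].tolist()
    ):
        results[r.event_id] = r

    classes = model.classes
    contingency = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    rows = []
    n_bad = n_uncl = 0
    for eid, r in results.items():
        true_label = truth.loc[eid, "class_label"]
        if r.outcome == clf.OUTCOME_BAD:
            n_bad += 1
        elif r.outcome == clf.OUTCOME_UNCLASSIFIABLE:
            n_uncl += 1
        else:
            contingency.loc[true_label, r.label] += 1
        rows.append(
            {
                "event_id": eid,
                "specimen_id": truth.loc[eid, "specimen_id"],
                "true": true_label,
                "outcome": r.outcome,
                "predicted": r.label,
                "probability": r.winning_probability,
            }
        )
    events = pd.DataFrame(rows)

    probs = events.loc[events["outcome"] == clf.OUTCOME_CLASSIFIED, "probability"]
    calls = []
    for spec, grp in events.groupby("specimen_id"):
        res = [results[e] for e in grp["event_id"]]
        call = clf.classify_specimen(res, spec)
        calls.append(
            {
                "specimen_id": spec,
                "call": call.label,
                "concordance": call.concordance,
                "n_classified": call.n_classified,
                "n_events": call.n_events,
            }
        )
    calls_df = pd.DataFrame(calls)
    conc = calls_df["concordance"].dropna()

    return BlindReport(
        attempts=len(events),
        bad=n_bad,
        unclassifiable=n_uncl,
        contingency=contingency,
        mean_probability=float(probs.mean()) if len(probs) else float("nan"),
        probability_halfsd=float(sd_scale * probs.std(ddof=1)) if len(probs) > 1 else 0.0,
        mean_concordance=float(conc.mean()) if len(conc) else float("nan"),
        concordance_halfsd=float(sd_scale * conc.std(ddof=1)) if len(conc) > 1 else 0.0,
        sd_scale=sd_scale,
        event_results=events,
        specimen_calls=calls_df,
    )
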