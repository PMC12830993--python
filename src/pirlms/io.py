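"""File formats and report writers binding the pipeline together.

Plain CSV is the interchange format throughout: long-format scan tables
(event_id, scan_index, mz, intensity), per-event metadata tables, binned
matrices with a sidecar annotation table, and JSON+CSV report pairs whose
table layouts mirror the cross-validation and blind-test accounting tables.
Every JSON report embeds the configuration hash and seed that produced it.

Models serialise to a single portable ``.npz`` archive (arrays plus a JSON
manifest).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import RejectionLdaModel
from .config import RunConfig
from .preprocess import BinnedMatrix
from .validation import BlindReport, CvReport

__all__ = [
    "read_scans",
    "write_scans",
    "read_metadata",
    "write_metadata",
    "write_matrix",
    "read_matrix",
    "write_reports",
    "save_model",
    "load_model",
]

SCAN_COLUMNS = ["event_id", "scan_index", "mz", "intensity"]


def read_scans(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Read a long-format scan table.

    Only the CSV format is supported (mzML would require a reader that is
    not available in this environment). Malformed rows are rejected with
    their line numbers.
    """
    if format != "csv":
        raise ValueError(
            f"unsupported scan format {format!r}: only 'csv' is available"
        )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty scan file {path}", stacklevel=2)
        return pd.DataFrame(columns=SCAN_COLUMNS)
    missing = [c for c in SCAN_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing scan columns {missing}")
    table = table[SCAN_COLUMNS]
    if len(table) == 0:
        warnings.warn(f"scan file {path} has a header but no rows", stacklevel=2)
        return table

    def _offending_lines(bad_mask: pd.Series) -> list[int]:
        # +2: header line plus 1-based numbering
        return (table.index[bad_mask] + 2).tolist()[:10]

    bad = table["intensity"] < 0
    if bad.any():
        raise ValueError(
            f"{path}: negative intensity at lines {_offending_lines(bad)}"
        )
    bad = table["mz"] <= 0
    if bad.any():
        raise ValueError(f"{path}: non-positive m/z at lines {_offending_lines(bad)}")
    bad = table["scan_index"] < 0
    if bad.any():
        raise ValueError(
            f"{path}: negative scan index at lines {_offending_lines(bad)}"
        )
    dup = table.duplicated(subset=["event_id", "scan_index", "mz"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (scan, m/z) pairs at lines {_offending_lines(dup)}"
        )
    return table


def write_scans(scans: pd.DataFrame, path: str | Path) -> None:
    scans[SCAN_COLUMNS].to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, keep_default_na=False)
    if "event_id" not in meta.columns or "specimen_id" not in meta.columns:
        raise ValueError(f"{path}: metadata needs event_id and specimen_id columns")
    if "class_label" in meta.columns:
        per_spec = meta.groupby("specimen_id")["class_label"].nunique()
        if (per_spec > 1).any():
            bad = per_spec[per_spec > 1].index.tolist()
            raise ValueError(f"{path}: inconsistent class within specimens {bad}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def write_matrix(matrix: BinnedMatrix, prefix: str | Path) -> None:
    """Write a binned matrix as ``<prefix>.csv`` (events × bins, bin-centre
    headers) plus ``<prefix>.annotations.csv``."""
    prefix = Path(prefix)
    centres = (matrix.bin_edges[:-1] + matrix.bin_edges[1:]) / 2
    pd.DataFrame(matrix.values, columns=[f"{c:.2f}" for c in centres]).to_csv(
        prefix.with_suffix(".csv"), index=False
    )
    matrix.annotations.to_csv(
        prefix.parent / (prefix.name + ".annotations.csv"), index=False
    )


def read_matrix(prefix: str | Path) -> BinnedMatrix:
    prefix = Path(prefix)
    values_df = pd.read_csv(prefix.with_suffix(".csv"))
    ann = pd.read_csv(
        prefix.parent / (prefix.name + ".annotations.csv"), keep_default_na=False
    )
    centres = np.array([float(c) for c in values_df.columns])
    width = centres[1] - centres[0]
    edges = np.concatenate([centres - width / 2, [centres[-1] + width / 2]])
    if "empty_row" in ann.columns:
        ann["empty_row"] = ann["empty_row"].astype(bool)
    return BinnedMatrix(values_df.to_numpy(float), edges, ann)


def _provenance(config: RunConfig | None, seed: int | None) -> dict:
    out: dict = {}
    if config is not None:
        out["config_hash"] = config.hash()
        out["config"] = config.to_dict()
    if seed is not None:
        out["seed"] = seed
    return out


def write_reports(
    reports: dict[str, CvReport | BlindReport],
    out_dir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write each report as a JSON (machine) + CSV (table) pair.

    CvReport CSVs follow the cross-validation table layout (per-fold rows,
    total row, both accuracy denominators); BlindReport CSVs hold the 2×2
    contingency. JSON carries the same numbers plus config hash and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, report in reports.items():
        json_path = out_dir / f"{name}.json"
        csv_path = out_dir / f"{name}.csv"
        if isinstance(report, CvReport):
            payload = {
                "kind": "cross_validation",
                "totals": {
                    "total": report.total,
                    "correct": report.correct,
                    "misclassified": report.misclassified,
                    "unclassifiable": report.unclassifiable,
                    "classifiable": report.classifiable,
                },
                "accuracy_per_classifiable_pct": round(
                    report.accuracy_per_classifiable, 2
                ),
                "accuracy_per_all_pct": round(report.accuracy_per_all, 2),
                "fold_averaged_per_classifiable_pct": round(
                    report.fold_averaged_per_classifiable, 2
                ),
                "duty_cycle_pct": round(report.duty_cycle, 2),
                "folds": report.folds.to_dict(orient="records"),
            }
            if report.confusion is not None:
                payload["confusion"] = report.confusion.to_dict()
            report.to_table().to_csv(csv_path, index=False)
        elif isinstance(report, BlindReport):
            payload = {
                "kind": "blind_evaluation",
                "attempts": report.attempts,
                "bad": report.bad,
                "unclassifiable": report.unclassifiable,
                "classifiable": report.classifiable,
                "duty_cycle_pct": round(report.duty_cycle, 2),
                "contingency": report.contingency.to_dict(),
                "sensitivity_pct": {
                    c: round(report.sensitivity(c), 2) for c in report.contingency.index
                },
                "specificity_pct": {
                    c: round(report.specificity(c), 2) for c in report.contingency.index
                },
                "mean_probability": report.mean_probability,
                "probability_halfsd": report.probability_halfsd,
                "mean_concordance": report.mean_concordance,
                "concordance_halfsd": report.concordance_halfsd,
            }
            report.contingency.to_csv(csv_path)
        else:
            raise TypeError(f"cannot serialise report of type {type(report)!r}")
        payload["provenance"] = _provenance(config, seed)
        json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written += [json_path, csv_path]
    return written


def save_model(model: RejectionLdaModel, path: str | Path) -> None:
    """Serialise a fitted model to one portable .npz archive."""
    manifest = {
        "classes": model.classes,
        "sd_threshold": model.sd_threshold,
        "n_features": model.n_features,
        "explained_variance_fraction": model.explained_variance_fraction,
        "config": model.config,
    }
    np.savez(
        path,
        manifest=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
        pca_mean=model.pca_mean,
        pca_components=model.pca_components,
        class_means=model.class_means,
        class_covs=model.class_covs,
        lda_scalings=model.lda.scalings_,
        lda_xbar=model.lda.xbar_,
    )


class _FrozenLda:
    """Projection-only stand-in for a fitted LDA (transform path only)."""

    def __init__(self, scalings: np.ndarray, xbar: np.ndarray):
        self.scalings_ = scalings
        self.xbar_ = xbar

    def transform(self, X: np.ndarray) -> np.ndarray:
        n_axes = self.scalings_.shape[1]
        return ((X - self.xbar_) @ self.scalings_)[:, :n_axes]


def load_model(path: str | Path) -> RejectionLdaModel:
    with np.load(path, allow_pickle=False) as archive:
        manifest = json.loads(archive["manifest"].tobytes().decode())
        lda = _FrozenLda(archive["lda_scalings"], archive["lda_xbar"])
        return RejectionLdaModel(
            classes=manifest["classes"],
            pca_mean=archive["pca_mean"],
            pca_components=archive["pca_components"],
            explained_variance_fraction=manifest["explained_variance_fraction"],
            lda=lda,
            class_means=archive["class_means"],
            class_covs=archive["class_covs"],
            sd_threshold=manifest["sd_threshold"],
            n_features=manifest["n_features"],
            config=manifest["config"],
        )
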