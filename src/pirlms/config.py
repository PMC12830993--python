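"""Run-level configuration: every numeric constant of the pipeline in one place.

The defaults reproduce the acquisition and modelling settings of the
10-second PIRL-MS workflow: negative-ion spectra over 100-1000 Da binned at
0.1 Da, lock-mass correction against m/z 717.5070, the three spectral QC
criteria (lock-mass present, signal duration > 3 s, event TIC > 10^3), the
instrument-software sampling-event recognition parameters (per-scan TIC
trigger 10^4, 13 scans per spectrum, 13 s timeout), a PCA retaining 95% of
variance followed by LDA, a Mahalanobis rejection threshold of 4 SD, and
5-fold specimen-grouped cross-validation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "UmapParams"]


@dataclass(frozen=True)
class UmapParams:
    """UMAP embedding settings (visualisation only).

    ``iterations`` is carried as provenance metadata: the embedding
    algorithm exposes a single epoch count, and ``n_epochs`` drives it.
    """

    n_neighbors: int = 25
    n_components: int = 2
    n_epochs: int = 200
    seed: int = 123
    metric: str = "euclidean"
    iterations: int = 250

    def __post_init__(self) -> None:
        for name in ("n_neighbors", "n_components", "n_epochs", "iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"UmapParams.{name} must be a positive integer")


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds and parameters, with validated defaults."""

    # spectral axis / binning
    mz_lo: float = 100.0
    mz_hi: float = 1000.0
    bin_width: float = 0.1
    # lock-mass correction
    lockmass_mz: float = 717.5070
    lockmass_window: float = 0.25
    # spectral QC ("bad data" criteria)
    qc_min_duration_s: float = 3.0  # duration must strictly exceed this
    qc_min_tic: float = 1e3  # event TIC must strictly exceed this
    # sampling-event recognition
    tic_trigger: float = 1e4
    scans_per_spectrum: int = 13
    timeout_s: float = 13.0
    # classifier
    variance_fraction: float = 0.95
    sd_threshold: float = 4.0
    component_cap: int | None = None
    covariance_shrinkage: float = 0.1
    # validation
    n_folds: int = 5
    sd_scale: float = 0.5  # "average ± 0.5 SD" reporting convention
    seed: int = 0
    umap: UmapParams = field(default_factory=UmapParams)

    def __post_init__(self) -> None:
        if self.mz_hi <= self.mz_lo:
            raise ValueError("mz_hi must exceed mz_lo")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not (self.mz_lo <= self.lockmass_mz < self.mz_hi):
            raise ValueError("lockmass_mz must lie inside the acquisition range")
        if not (0 < self.variance_fraction <= 1):
            raise ValueError("variance_fraction must be in (0, 1]")
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if self.component_cap is not None and self.component_cap < 1:
            raise ValueError("component_cap must be >= 1 when set")
        if not (0 <= self.covariance_shrinkage <= 1):
            raise ValueError("covariance_shrinkage must be in [0, 1]")
        for name in ("lockmass_window", "qc_min_tic", "tic_trigger", "timeout_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scans_per_spectrum < 1 or self.n_folds < 2:
            raise ValueError("scans_per_spectrum >= 1 and n_folds >= 2 required")

    @property
    def n_bins(self) -> int:
        return int(round((self.mz_hi - self.mz_lo) / self.bin_width))

    # ---- (de)serialisation -------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build a config from a mapping, rejecting unknown keys."""
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "umap" in data and isinstance(data["umap"], dict):
            umap_known = {f.name for f in dataclasses.fields(UmapParams)}
            bad = set(data["umap"]) - umap_known
            if bad:
                raise ValueError(f"unknown umap config keys: {sorted(bad)}")
            data["umap"] = UmapParams(**data["umap"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def hash(self) -> str:
        """Stable digest of the full configuration, for output provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
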