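"""From raw 1 Hz scans to QC-annotated, lock-mass-corrected feature vectors.

The stages mirror the acquisition-to-matrix path of 10-second ambient
laser-ablation mass spectrometry:

1. :func:`detect_events` — instrument-style sampling-event recognition: an event
   opens at the first scan whose TIC exceeds the trigger (10^4), collects
   up to 13 qualifying scans and closes on count or on a 13 s timeout.
   Alternatively :func:`events_from_table` groups scans by a known event id
   (the natural route for synthetic or pre-segmented streams).
2. :func:`qc_check` — the three "bad data" criteria: no lock-mass peak
   (m/z 717.5070) found, signal duration of 3 s or less, event TIC of
   10^3 or less.
3. :func:`lockmass_correct` — a single additive mass-axis shift per event
   so the observed lock-mass lands exactly on the reference.
4. :func:`bin_and_normalize` — 0.1 Da binning over [100, 1000) Da
   (9,000 features) followed by TIC normalisation of each row; and
   :func:`rebin_1da` — the 900-feature 1 Da rebinning used for
   correlation-map diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = [
    "Scan",
    "SamplingEvent",
    "EventRecognitionParams",
    "BinnedMatrix",
    "detect_events",
    "events_from_table",
    "qc_check",
    "lockmass_correct",
    "bin_and_normalize",
    "rebin_1da",
    "preprocess_events",
    "run_pipeline",
]

QC_GOOD = "good"
QC_NO_LOCKMASS = "bad_no_lockmass"
QC_SHORT = "bad_short_duration"
QC_LOW_TIC = "bad_low_tic"


@dataclass(frozen=True)
class Scan:
    """One 1-second mass spectrum (centroided peak list)."""

    index: int  # acquisition index; at 1 Hz, index differences are seconds
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be strictly positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class EventRecognitionParams:
    """Sampling-event recognition settings (per-scan TIC trigger of >10^4,
    13 scans per spectrum, 13 s wait-for-good-spectrum timeout)."""

    tic_trigger: float = 1e4
    scans_per_spectrum: int = 13
    timeout_s: float = 13.0

    def __post_init__(self) -> None:
        if self.tic_trigger <= 0 or self.scans_per_spectrum <= 0 or self.timeout_s <= 0:
            raise ValueError("recognition parameters must be positive")


@dataclass(frozen=True)
class SamplingEvent:
    """A contiguous group of scans forming one ~10 s sampling attempt.

    The combined spectrum is the concatenation of member-scan peak lists
    (equivalent to their sum once binned).
    """

    event_id: str
    scans: tuple[Scan, ...]
    mz: np.ndarray
    intensity: np.ndarray
    qc_status: str | None = None
    lockmass_observed: float | None = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_scans(cls, event_id: str, scans: list[Scan], **meta) -> "SamplingEvent":
        if not scans:
            raise ValueError("an event needs at least one scan")
        mz = np.concatenate([s.mz for s in scans])
        inten = np.concatenate([s.intensity for s in scans])
        return cls(event_id, tuple(scans), mz, inten, meta=meta)

    @property
    def duration_s(self) -> float:
        """Signal duration in seconds: member-scan count at 1 scan/s."""
        return float(len(self.scans))

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


def detect_events(
    scans: list[Scan], params: EventRecognitionParams = EventRecognitionParams()
) -> list[SamplingEvent]:
    """Segment an ordered scan stream into sampling events.

    An event opens at the first scan with TIC above the trigger; subsequent
    qualifying scans are accumulated until ``scans_per_spectrum`` are
    collected or ``timeout_s`` seconds have elapsed since opening. Scans are
    never shared between events.
    """
    events: list[SamplingEvent] = []
    current: list[Scan] = []
    open_index: int | None = None

    def close() -> None:
        nonlocal current, open_index
        if current:
            events.append(
                SamplingEvent.from_scans(f"detected-{len(events):05d}", current)
            )
        current, open_index = [], None

    for scan in scans:
        if open_index is not None and scan.index - open_index >= params.timeout_s:
            close()
        if scan.tic > params.tic_trigger:
            if open_index is None:
                open_index = scan.index
            current.append(scan)
            if len(current) >= params.scans_per_spectrum:
                close()
    close()
    return events


def events_from_table(
    scans: pd.DataFrame, event_order: list[str] | None = None
) -> list[SamplingEvent]:
    """Group a long-format scan table (event_id, scan_index, mz, intensity)
    into sampling events, preserving acquisition order."""
    events = []
    order = event_order or list(dict.fromkeys(scans["event_id"]))
    grouped = dict(tuple(scans.groupby("event_id", sort=False)))
    for event_id in order:
        df = grouped[event_id]
        member = [
            Scan(int(idx), g["mz"].to_numpy(float), g["intensity"].to_numpy(float))
            for idx, g in df.groupby("scan_index", sort=True)
        ]
        events.append(SamplingEvent.from_scans(str(event_id), member))
    return events


def _find_lockmass(
    event: SamplingEvent, reference: float, window: float
) -> float | None:
    """Most intense combined-spectrum peak within ±window of the reference."""
    in_window = np.abs(event.mz - reference) <= window
    if not in_window.any():
        return None
    idx = np.flatnonzero(in_window)
    return float(event.mz[idx[np.argmax(event.intensity[idx])]])


def qc_check(
    event: SamplingEvent,
    reference: float = 717.5070,
    window: float = 0.25,
    min_duration_s: float = 3.0,
    min_tic: float = 1e3,
) -> str:
    """Apply the three bad-data criteria in order; return the QC status.

    Good requires (a) a lock-mass peak within ±window of the reference,
    (b) signal duration strictly greater than ``min_duration_s`` and
    (c) event TIC strictly greater than ``min_tic``. The first failing
    criterion names the status.
    """
    if _find_lockmass(event, reference, window) is None:
        return QC_NO_LOCKMASS
    if event.duration_s <= min_duration_s:
        return QC_SHORT
    if event.tic <= min_tic:
        return QC_LOW_TIC
    return QC_GOOD


def lockmass_correct(
    event: SamplingEvent, reference: float = 717.5070, window: float = 0.25
) -> SamplingEvent:
    """Shift the combined spectrum so the lock-mass sits exactly on the
    reference. The shift is uniform and additive (single internal standard).
    """
    if event.qc_status == QC_NO_LOCKMASS:
        raise ValueError("cannot lock-mass correct an event with no lock-mass peak")
    observed = _find_lockmass(event, reference, window)
    if observed is None:
        raise ValueError(f"no peak within ±{window} Da of {reference}")
    shift = reference - observed
    mz = event.mz + shift
    # pin the identified lock-mass peak to the reference, avoiding a ±1 ulp
    # residue from the float addition
    in_window = np.abs(event.mz - observed) < 1e-12
    mz[in_window] = reference
    return replace(event, mz=mz, lockmass_observed=observed)


@dataclass
class BinnedMatrix:
    """Events × m/z-bin feature matrix with per-event annotations.

    ``values`` rows are TIC-normalised (each good row sums to 1); rows with
    no in-range signal are left at zero and flagged in
    ``annotations['empty_row']``. ``annotations`` carries event id,
    specimen id, class label (when known) and qc_status, row-aligned with
    ``values``.
    """

    values: np.ndarray
    bin_edges: np.ndarray
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.annotations):
            raise ValueError("annotation table must be row-aligned with values")
        if self.values.shape[1] != self.bin_edges.size - 1:
            raise ValueError("bin_edges inconsistent with column count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def bin_width(self) -> float:
        return float((self.bin_edges[-1] - self.bin_edges[0]) / self.n_features)

    def good_mask(self) -> np.ndarray:
        return (self.annotations["qc_status"] == QC_GOOD).to_numpy()

    def subset(self, mask: np.ndarray) -> "BinnedMatrix":
        return BinnedMatrix(
            self.values[mask],
            self.bin_edges,
            self.annotations.loc[mask].reset_index(drop=True),
        )


def bin_and_normalize(
    events: list[SamplingEvent],
    lo: float = 100.0,
    hi: float = 1000.0,
    width: float = 0.1,
    annotations: pd.DataFrame | None = None,
) -> BinnedMatrix:
    """Bin combined spectra onto a fixed half-open grid and TIC-normalise.

    A peak with lo <= m/z < hi contributes its full intensity to bin
    ``floor((m/z - lo)/width)``; each row is then divided by its sum.
    Rows with zero in-range signal are flagged, not divided.
    """
    if hi <= lo or width <= 0:
        raise ValueError("need hi > lo and width > 0")
    n_bins = int(round((hi - lo) / width))
    edges = lo + width * np.arange(n_bins + 1)
    values = np.zeros((len(events), n_bins))
    for i, ev in enumerate(events):
        in_range = (ev.mz >= lo) & (ev.mz < hi)
        # +1e-6 bin guards against a peak on an exact bin edge falling one
        # bin low through float representation of the edge
        idx = np.floor((ev.mz[in_range] - lo) / width + 1e-6).astype(np.intp)
        np.add.at(values[i], idx, ev.intensity[in_range])

    row_sums = values.sum(axis=1)
    empty = row_sums == 0
    values[~empty] /= row_sums[~empty, None]

    if annotations is None:
        annotations = pd.DataFrame(
            {
                "event_id": [ev.event_id for ev in events],
                "qc_status": [ev.qc_status or QC_GOOD for ev in events],
            }
        )
    annotations = annotations.copy().reset_index(drop=True)
    annotations["empty_row"] = empty
    return BinnedMatrix(values, edges, annotations)


def rebin_1da(matrix: BinnedMatrix) -> BinnedMatrix:
    """Collapse the 9,000-feature 0.1 Da matrix to 900 1 Da features by
    summing blocks of 10 consecutive bins; row sums are preserved."""
    if matrix.n_features != 9000:
        raise ValueError("rebin_1da expects the 9000-column 0.1 Da matrix")
    values = matrix.values.reshape(matrix.values.shape[0], 900, 10).sum(axis=2)
    edges = matrix.bin_edges[::10]
    return BinnedMatrix(values, edges, matrix.annotations.copy())


def preprocess_events(
    events: list[SamplingEvent],
    config: RunConfig = RunConfig(),
    annotations: pd.DataFrame | None = None,
) -> BinnedMatrix:
    """QC, lock-mass correct and bin a list of sampling events.

    Events failing QC are kept as rows (flagged via qc_status) so that
    sampling-attempt accounting — duty cycle, bad-data counts — stays
    possible downstream; events without a lock-mass are binned uncorrected.
    """
    processed = []
    for ev in events:
        status = qc_check(
            ev,
            reference=config.lockmass_mz,
            window=config.lockmass_window,
            min_duration_s=config.qc_min_duration_s,
            min_tic=config.qc_min_tic,
        )
        ev = replace(ev, qc_status=status)
        if status != QC_NO_LOCKMASS:
            ev = lockmass_correct(ev, config.lockmass_mz, config.lockmass_window)
        processed.append(ev)

    if annotations is not None:
        order = pd.DataFrame({"event_id": [ev.event_id for ev in processed]})
        annotations = order.merge(annotations, on="event_id", how="left")
    else:
        annotations = pd.DataFrame({"event_id": [ev.event_id for ev in processed]})
    annotations["qc_status"] = [ev.qc_status for ev in processed]
    return bin_and_normalize(
        processed, config.mz_lo, config.mz_hi, config.bin_width, annotations
    )


def run_pipeline(
    scans: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    config: RunConfig = RunConfig(),
) -> BinnedMatrix:
    """Full preprocessing: long-format scan table → annotated BinnedMatrix."""
    events = events_from_table(scans)
    return preprocess_events(events, config, annotations=metadata)
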