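"""Synthetic scan-stream generator for two-class tissue fingerprinting.

The raw spectra behind the PDX imposter-screening study are not publicly
deposited, so every downstream stage of this package is exercised against
synthetic data with the same statistical structure the analysis assumes:

* two classes (lymphoproliferative outgrowths vs. true solid-tumour PDXs),
  each carrying a class-specific panel of lipid-range peaks (600-900 Da)
  plus peaks shared by both classes;
* log-normal peak intensities with a per-specimen random effect and
  per-scan noise, so sampling events from one specimen are correlated;
* multiple ~13-scan sampling events per specimen (1 scan/s acquisition);
* a lock-mass peak at m/z 717.5070 in every scan, with a single uniform
  mass-axis drift per sampling event;
* injected "bad data" modes that each violate exactly one spectral QC
  criterion: missing lock-mass, short signal duration (3 scans), or a
  combined-spectrum total ion count below 10^3.

Default cohort shape follows the modelling cohort of the study: 20 lymphoma
and 90 solid-tumour specimens with on average ~12 sampling events each.
Default bad-event rates follow the blind-set accounting (11 missing
lock-mass and 23 short-duration events out of 2,079 attempts; no low-TIC
events were reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SealedGroundTruth",
    "generate_cohort",
    "generate_blind_set",
    "DEFAULT_LYMPHOMA_PANEL",
    "DEFAULT_PDX_PANEL",
    "DEFAULT_SHARED_PEAKS",
]

CLASS_LYMPHOMA = "lymphoma"
CLASS_PDX = "pdx"

# lipid-plausible default panels: (m/z centre [Da], mean log-intensity).
# Mean log-intensities near 10 put single-scan TICs well above the 10^4
# event-recognition trigger.
DEFAULT_LYMPHOMA_PANEL: tuple[tuple[float, float], ...] = (
    (621.3, 10.5),
    (655.4, 10.0),
    (682.6, 10.2),
    (744.5, 10.8),
    (788.5, 10.0),
    (810.6, 9.8),
    (885.5, 10.4),
)
DEFAULT_PDX_PANEL: tuple[tuple[float, float], ...] = (
    (609.4, 10.3),
    (671.5, 10.1),
    (700.5, 10.6),
    (726.5, 10.2),
    (766.5, 10.9),
    (835.5, 9.9),
    (863.6, 10.3),
)
DEFAULT_SHARED_PEAKS: tuple[tuple[float, float], ...] = (
    (281.2, 9.5),
    (303.2, 9.3),
    (465.3, 9.0),
    (599.3, 9.2),
    (747.5, 9.8),
)

TRAIN_CANCER_TYPES = ("colon", "head & neck", "lung", "ovarian", "pancreas")
BLIND_CANCER_TYPES = TRAIN_CANCER_TYPES + ("mesothelial", "esophageal")

BAD_MODES = ("missing_lockmass", "short_duration", "low_tic")


@dataclass(frozen=True)
class CohortConfig:
    """Stated world for one synthetic cohort.

    ``n_specimens_per_class`` is (lymphoma, solid-tumour PDX).
    ``events_per_specimen`` is either a fixed count or an inclusive
    (lo, hi) range sampled uniformly per specimen.
    ``mass_drift_sd`` is the standard deviation (Da) of the per-event
    uniform mass-axis shift.
    ``bad_event_rates`` are per-event probabilities of the three injected
    failure modes, in the order of :data:`BAD_MODES`.
    """

    n_specimens_per_class: tuple[int, int] = (20, 90)
    events_per_specimen: int | tuple[int, int] = (10, 14)
    scans_per_event: int = 13
    class_peak_panels: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: {
            CLASS_LYMPHOMA: DEFAULT_LYMPHOMA_PANEL,
            CLASS_PDX: DEFAULT_PDX_PANEL,
        }
    )
    shared_peaks: tuple[tuple[float, float], ...] = DEFAULT_SHARED_PEAKS
    lockmass_mz: float = 717.5070
    lockmass_log_intensity: float = 10.0
    specimen_effect_sd: float = 0.3
    scan_noise_sd: float = 0.4
    panel_covariation_sd: float = 0.5
    mass_drift_sd: float = 0.02
    baseline_noise_peaks: int = 40
    baseline_log_intensity: float = 6.0
    bad_event_rates: tuple[float, float, float] = (11 / 2079, 23 / 2079, 0.0)
    cancer_types: tuple[str, ...] = TRAIN_CANCER_TYPES
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_specimens_per_class):
            raise ValueError("need at least one specimen per class")
        if not self.class_peak_panels or any(
            len(panel) == 0 for panel in self.class_peak_panels.values()
        ):
            raise ValueError(
                "empty class peak panel: classes would be indistinguishable"
            )
        for panel in list(self.class_peak_panels.values()) + [self.shared_peaks]:
            for mz, _ in panel:
                if not (100.0 <= mz < 1000.0):
                    raise ValueError(f"panel m/z {mz} outside [100, 1000)")
        if not (100.0 <= self.lockmass_mz < 1000.0):
            raise ValueError("lockmass_mz outside [100, 1000)")
        if any(not (0.0 <= p <= 1.0) for p in self.bad_event_rates):
            raise ValueError("bad_event_rates must be probabilities")
        if sum(self.bad_event_rates) > 1.0:
            raise ValueError("bad_event_rates sum above 1")
        if self.scans_per_event < 4:
            raise ValueError("scans_per_event must be >= 4 to pass duration QC")
        if isinstance(self.events_per_specimen, int):
            if self.events_per_specimen < 1:
                raise ValueError("events_per_specimen must be positive")
        else:
            lo, hi = self.events_per_specimen
            if lo < 1 or hi < lo:
                raise ValueError("events_per_specimen range invalid")
        for name in (
            "specimen_effect_sd",
            "scan_noise_sd",
            "panel_covariation_sd",
            "mass_drift_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class SealedGroundTruth:
    """Ground truth with class labels withheld from the classification path.

    The public :attr:`metadata` table exposes only specimen identity and QC
    bookkeeping; true class labels (and injected-badness modes) are
    retrievable solely through :meth:`unseal`, which is meant to be called
    once, at scoring time.
    """

    _HIDDEN = ("class_label", "cancer_type", "bad_mode")

    def __init__(self, truth: pd.DataFrame):
        self._truth = truth.copy()

    @property
    def metadata(self) -> pd.DataFrame:
        """Per-event metadata with the class fields removed."""
        return self._truth.drop(columns=list(self._HIDDEN))

    def unseal(self) -> pd.DataFrame:
        """Return the full per-event ground truth, for scoring only."""
        return self._truth.copy()

    def __repr__(self) -> str:  # pragma: no cover
        return f"SealedGroundTruth({len(self._truth)} events, labels hidden)"


def _draw_events_per_specimen(config: CohortConfig, rng: np.random.Generator) -> int:
    if isinstance(config.events_per_specimen, int):
        return config.events_per_specimen
    lo, hi = config.events_per_specimen
    return int(rng.integers(lo, hi + 1))


def _event_scans(
    config: CohortConfig,
    rng: np.random.Generator,
    panel_mz: np.ndarray,
    panel_logmean: np.ndarray,
    specimen_effect: np.ndarray,
    n_class_peaks: int,
    bad_mode: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build one sampling event; returns (scan offsets, m/z, intensity) arrays."""
    n_scans = 3 if bad_mode == "short_duration" else config.scans_per_event
    # one uniform additive mass shift per event, SD = mass_drift_sd
    half_width = config.mass_drift_sd * np.sqrt(3.0)
    drift = rng.uniform(-half_width, half_width) if half_width > 0 else 0.0
    # per-event activity of the co-regulated class panel: all class peaks
    # rise and fall together across sampling spots, as co-regulated lipid
    # panels do; this is what gives correlation maps class-specific blocks
    panel_activity = np.zeros(panel_mz.size)
    panel_activity[:n_class_peaks] = rng.normal(0.0, config.panel_covariation_sd)

    offs, mzs, intens = [], [], []
    for s in range(n_scans):
        scan_noise = rng.normal(0.0, config.scan_noise_sd, size=panel_mz.size)
        peak_int = np.exp(panel_logmean + specimen_effect + panel_activity + scan_noise)
        mz = panel_mz + drift
        inten = peak_int
        if bad_mode != "missing_lockmass":
            lm_int = np.exp(
                config.lockmass_log_intensity + rng.normal(0.0, config.scan_noise_sd)
            )
            mz = np.append(mz, config.lockmass_mz + drift)
            inten = np.append(inten, lm_int)
        if config.baseline_noise_peaks > 0:
            base_mz = rng.uniform(100.0, 1000.0, size=config.baseline_noise_peaks)
            if bad_mode == "missing_lockmass":
                # the injected mode must violate exactly its QC criterion:
                # keep random baseline peaks out of the lock-mass search window
                near = np.abs(base_mz - config.lockmass_mz) < 0.3
                base_mz = base_mz[~near]
            base_int = np.exp(
                rng.normal(config.baseline_log_intensity, 1.0, size=base_mz.size)
            )
            mz = np.concatenate([mz, base_mz + drift])
            inten = np.concatenate([inten, base_int])
        offs.append(np.full(mz.size, s))
        mzs.append(mz)
        intens.append(inten)

    off = np.concatenate(offs)
    mz_all = np.concatenate(mzs)
    int_all = np.concatenate(intens)
    if bad_mode == "low_tic":
        # scale the whole event so its combined-spectrum TIC sits below 10^3
        int_all = int_all * (500.0 / int_all.sum())
    return off, mz_all, int_all


def generate_cohort(
    config: CohortConfig, *, role: str = "train"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a scan stream and its ground truth.

    Returns
    -------
    scans : DataFrame with columns ``event_id, scan_index, mz, intensity``
        (long format, one row per peak), ordered by event then scan.
        ``scan_index`` is a global 1 Hz acquisition index; successive
        events are separated by silent gaps.
    truth : DataFrame with one row per event: ``event_id, specimen_id,
        class_label, cancer_type, role, bad_mode`` (empty string when the
        event is clean).
    """
    rng = np.random.default_rng(config.seed)
    class_names = list(config.class_peak_panels)
    shared = np.array(config.shared_peaks, dtype=float).reshape(-1, 2)

    scan_frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    scan_cursor = 0
    event_counter = 0
    rates = np.asarray(config.bad_event_rates)

    for class_idx, class_name in enumerate(class_names):
        panel = np.array(config.class_peak_panels[class_name], dtype=float)
        all_mz = np.concatenate([panel[:, 0], shared[:, 0]]) if shared.size else panel[:, 0]
        all_logmean = (
            np.concatenate([panel[:, 1], shared[:, 1]]) if shared.size else panel[:, 1]
        )
        n_specimens = config.n_specimens_per_class[class_idx]
        for spec_i in range(n_specimens):
            specimen_id = f"{role}-{class_name}-{spec_i:03d}"
            cancer_type = (
                class_name
                if class_name == CLASS_LYMPHOMA
                else config.cancer_types[spec_i % len(config.cancer_types)]
            )
            specimen_effect = rng.normal(0.0, config.specimen_effect_sd, all_mz.size)
            n_events = _draw_events_per_specimen(config, rng)
            for _ in range(n_events):
                u = rng.random()
                bad_mode = ""
                acc = 0.0
                for mode, p in zip(BAD_MODES, rates):
                    acc += p
                    if u < acc:
                        bad_mode = mode
                        break
                event_id = f"{role}-ev{event_counter:05d}"
                event_counter += 1
                off, mz, inten = _event_scans(
                    config, rng, all_mz, all_logmean, specimen_effect,
                    panel.shape[0], bad_mode,
                )
                scan_frames.append(
                    pd.DataFrame(
                        {
                            "event_id": event_id,
                            "scan_index": scan_cursor + off,
                            "mz": mz,
                            "intensity": inten,
                        }
                    )
                )
                scan_cursor += int(off.max()) + 1 + 5  # 5 s silent gap
                truth_rows.append(
                    {
                        "event_id": event_id,
                        "specimen_id": specimen_id,
                        "class_label": class_name,
                        "cancer_type": cancer_type,
                        "role": role,
                        "bad_mode": bad_mode,
                    }
                )

    scans = pd.concat(scan_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return scans, truth


def generate_blind_set(
    config: CohortConfig, hide_labels: bool = True
) -> tuple[pd.DataFrame, SealedGroundTruth | pd.DataFrame]:
    """Generate a blind evaluation cohort.

    With ``hide_labels=True`` (the default, emulating a blinded operator)
    the second return value is a :class:`SealedGroundTruth` whose public
    metadata carries no class information; call ``unseal()`` to score.
    """
    scans, truth = generate_cohort(config, role="blind")
    if hide_labels:
        return scans, SealedGroundTruth(truth)
    return scans, truth
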