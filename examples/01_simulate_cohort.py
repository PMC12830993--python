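"""Simulate a two-class cohort of 1 Hz laser-ablation mass spectra.

Each specimen (lymphoma or solid-tumour PDX) is sampled several times;
each sampling event is ~13 one-second scans carrying class-specific lipid
peaks, a lock-mass at m/z 717.5070, per-event mass drift and occasional
injected bad-data modes.
"""

import pirlms

cfg = pirlms.CohortConfig(
    n_specimens_per_class=(5, 12),  # lymphoma, solid-tumour PDX
    events_per_specimen=(4, 6),
    seed=42,
)
scans, truth = pirlms.generate_cohort(cfg)

print(f"{truth['specimen_id'].nunique()} specimens, {len(truth)} sampling events, "
      f"{len(scans)} peak rows")
print("events per class:")
print(truth["class_label"].value_counts().to_string())
bad = truth[truth["bad_mode"] != ""]
print(f"injected bad events: {len(bad)} ({', '.join(bad['bad_mode']) or 'none'})")
# The scan table is the long-format interchange CSV: one row per peak,
# (event_id, scan_index, mz, intensity); truth maps events to specimens,
# classes and any injected QC failure.
print(scans.head(3).to_string(index=False))
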