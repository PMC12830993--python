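"""Post-hoc views: UMAP embedding, LDA jitter overlap, correlation maps.

None of these feed classification decisions; they visualise why the model
separates the classes (or why a specimen misclassifies).
"""

import pirlms
from pirlms import diagnostics

cfg = pirlms.CohortConfig(n_specimens_per_class=(8, 8), events_per_specimen=8,
                          bad_event_rates=(0, 0, 0), seed=5)
scans, truth = pirlms.generate_cohort(cfg)
matrix = pirlms.run_pipeline(scans, truth)
ann = matrix.annotations
y = ann["class_label"].to_numpy()

# unsupervised view: classes should separate without labels
emb = diagnostics.umap_embed(matrix, pirlms.UmapParams(n_neighbors=15, n_epochs=100))
for cls, grp in emb.groupby("class_label"):
    print(f"UMAP centroid {cls}: ({grp['umap1'].mean():.2f}, {grp['umap2'].mean():.2f})")

# supervised view: jitter scores along the single discriminant axis
model = pirlms.fit(matrix.values, y)
records, overlap = diagnostics.jitter_data(model, matrix, y)
print(f"LDA-axis overlap fraction: {overlap:.3f} "
      "(0 = cleanly separated score distributions)")

# correlation maps: class-specific covariation of 1 Da features
coarse = pirlms.rebin_1da(matrix)
query = diagnostics.correlation_map(
    coarse.subset(ann["class_label"].eq("lymphoma").to_numpy()), tag="query:lymphoma")
cfg2 = pirlms.CohortConfig(n_specimens_per_class=(8, 8), events_per_specimen=8,
                           bad_event_rates=(0, 0, 0), seed=6)
scans2, truth2 = pirlms.generate_cohort(cfg2)
coarse2 = pirlms.rebin_1da(pirlms.run_pipeline(scans2, truth2))
ann2 = coarse2.annotations
for cls in ("lymphoma", "pdx"):
    control = diagnostics.correlation_map(
        coarse2.subset(ann2["class_label"].eq(cls).to_numpy()), tag=f"control:{cls}")
    sim = diagnostics.map_similarity(query, control)
    print(f"map similarity, lymphoma query vs {cls} control: {sim:+.4f}")
print("(the query resembles its own class's control map: misclassification "
      "probes compare an unknown's map against both controls this way)")
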