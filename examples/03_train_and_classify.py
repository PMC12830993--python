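"""Fit the rejection-capable PCA-LDA model and classify spectra.

A spectrum is assigned to the class whose cluster centre is nearest in
Mahalanobis distance (SD units along the discriminant axis) — unless even
the nearest centre is more than 4 SD away, in which case no call is made
("unclassifiable"). Per-specimen majority calls give the spatial
concordance across sampling positions.
"""

import pirlms

cfg = pirlms.CohortConfig(n_specimens_per_class=(6, 8), events_per_specimen=4, seed=11)
scans, truth = pirlms.generate_cohort(cfg)
matrix = pirlms.run_pipeline(scans, truth)
good = matrix.good_mask()
X = matrix.values[good]
y = matrix.annotations.loc[good, "class_label"].to_numpy()

model = pirlms.fit(X, y, variance_fraction=0.95, sd_threshold=4.0)
print(f"PCA kept {model.config['n_components']} components "
      f"({100 * model.explained_variance_fraction:.1f}% of variance), "
      f"LDA projects to {model.class_means.shape[1]} axis")

results = pirlms.classify_matrix(X, model, matrix.annotations.loc[good, "event_id"].tolist())
r = results[0]
print(f"\nfirst event: {r.outcome} as {r.label} "
      f"(p={r.winning_probability:.3f}; distances "
      + ", ".join(f"{c}={d:.2f} SD" for c, d in r.distances.items()) + ")")

spec_ids = matrix.annotations.loc[good, "specimen_id"].to_numpy()
for spec in list(dict.fromkeys(spec_ids))[:3]:
    call = pirlms.classify_specimen(
        [r for r, s in zip(results, spec_ids) if s == spec], spec
    )
    print(f"{spec}: called {call.label}, spatial concordance "
          f"{call.concordance:.2f} over {call.n_classified} classified events")
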