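"""Blinded evaluation of a trained model on a sealed cohort.

The blind set's class labels are sealed away from the classification path
and only unsealed for scoring, emulating a blinded operator. The report
accounts for every sampling attempt: bad data (QC), unclassifiable
(Mahalanobis rejection) and the 2x2 contingency of classified events.
"""

import pirlms

# train on one cohort
train_cfg = pirlms.CohortConfig(n_specimens_per_class=(6, 10), events_per_specimen=5, seed=1)
scans, truth = pirlms.generate_cohort(train_cfg)
matrix = pirlms.run_pipeline(scans, truth)
good = matrix.good_mask()
model = pirlms.fit(matrix.values[good],
                   matrix.annotations.loc[good, "class_label"].to_numpy())

# evaluate blind on an independent one
blind_cfg = pirlms.CohortConfig(n_specimens_per_class=(4, 10), events_per_specimen=5, seed=2)
blind_scans, sealed = pirlms.generate_blind_set(blind_cfg)
print(f"sealed metadata columns: {list(sealed.metadata.columns)} (no class field)")

blind_matrix = pirlms.run_pipeline(blind_scans, sealed.metadata)
report = pirlms.blind_evaluate(blind_matrix, model, sealed)

print(f"\n{report.attempts} sampling attempts: {report.bad} bad, "
      f"{report.unclassifiable} unclassifiable, {report.classifiable} classified")
print(f"duty cycle {report.duty_cycle:.1f}% (fraction of attempts yielding a call)")
print("\ncontingency (rows true, columns predicted):")
print(report.contingency.to_string())
print(f"\nsensitivity {report.sensitivity('lymphoma'):.2f}% / "
      f"specificity {report.specificity('lymphoma'):.2f}% for imposter detection")
print(f"prediction probability {100 * report.mean_probability:.1f} "
      f"± {100 * report.probability_halfsd:.1f} % (mean ± half SD)")
print(f"spatial concordance {100 * report.mean_concordance:.1f} "
      f"± {100 * report.concordance_halfsd:.1f} % across sampling positions")
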