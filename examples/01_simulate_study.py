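"""Generate the synthetic six-group toxicity/rescue study and look inside.

The study emulates a 63-rat design: control (C), toxin-only (T) and four
treated groups (T/HQD, T/SS, T/BB, T/SF) sampled at days -1, 1, 4, 7, 10,
with pooled-QC and blank injections, planted perturbed metabolites,
decoction-only exogenous peaks and background contaminants.
"""

from metaboeval import generate_study

table, phenotypes, truth = generate_study(seed=1)

print(f"peak table: {table.n_samples} samples x {table.n_features} features")
print(f"  study/qc/blank: {len(table.study_ids)}/{len(table.qc_ids)}/{len(table.blank_ids)}")
print(f"  groups: {table.groups}")
print(f"  missing fraction: {table.intensities.isna().mean().mean():.3f}")
print(f"planted: {len(truth.perturbed_feature_ids)} perturbed metabolites, "
      f"{sum(len(v) for v in truth.exogenous_feature_ids.values())} exogenous, "
      f"{len(truth.background_feature_ids)} background")
print("\nper-animal phenotypes at day 4 (first rows):")
print(phenotypes[phenotypes.day == 4].head(5).to_string(index=False))
print("\nDS rises and RBW falls with the true planted deregulation; the "
      "toxin group peaks at day 4 and recovers by day 10.")
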