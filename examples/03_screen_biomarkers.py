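"""Exogenous-feature removal and the biomarker selection cascade.

Decoction-only peaks are flagged against the pooled control+toxin (CT)
reference; then per-day OPLS-DA (VIP > 1) combined with BH-adjusted
Mann-Whitney tests (p < 0.05) selects discriminating metabolites, and the
Spearman filter keeps those tracking diarrhea score or body weight
(|rho| >= 0.5).
"""

from metaboeval import PipelineConfig, generate_study
from metaboeval.pipeline import stage_preprocess, stage_screen

table, phenotypes, truth = generate_study(seed=1)
cfg = PipelineConfig(seed=1)
clean, _ = stage_preprocess(table, cfg)
endo, exogenous, markers = stage_screen(clean, phenotypes, cfg)

planted_exo = set(truth.all_exogenous())
found_exo = {f for ids in exogenous.values() for f in ids}
print(f"exogenous features: {len(found_exo)} flagged, "
      f"{len(found_exo & planted_exo)} of {len(planted_exo)} planted recovered, "
      f"{len(found_exo - planted_exo)} false flags")

pre = set(markers.evidence.loc[markers.evidence.selected, "feature_id"])
pert = set(truth.perturbed_feature_ids)
print(f"selected before phenotype filter: {len(pre)} "
      f"(recall of planted {len(pre & pert) / len(pert):.2f})")
print(f"after Spearman filter: {len(markers.selected)} markers, "
      f"{len(set(markers.selected) - pert)} false positives")
print("\nfirst marker evidence rows:")
ev = markers.evidence
print(ev[ev.selected].head(5).to_string(index=False))
print("\nVIP measures a feature's weight in the toxin-vs-other OPLS-DA "
      "model; p_adj is the BH-adjusted Mann-Whitney p within that comparison.")
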