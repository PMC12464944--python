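"""Does homotopic coupling predict where lesions are detectable?

The generator scales each lesioned ROI's contralesional effect by that
ROI's homotopic coupling in controls.  Per-ROI lesion-presence models are
fit, and their MCC is correlated (Spearman) with control-cohort homotopic
FC — and, as a specificity check, with non-homotopic FC, which should
show no association.
"""

from contraconn import experiments as ex
from contraconn import ml_engine as ml
from contraconn import synthetic_cohort as syn

atlas = syn.generate_atlas(20, (24, 24, 24), seed=1)
emap = syn.default_effect_map(atlas, network_rois=[])
cohort = syn.generate_cohort(
    atlas, 80, 40,
    syn.EffectConfig(delta=2.0, noise_sd=1.0, seed=0,
                     homotopic_scaling=True, effect_map=emap),
    lesion_center_choices=list(range(7, 15)),
    lesion_radius_range=(1, 2),
    pair_coupling_range=(0.05, 1.5),
)

config = ml.CVConfig(inner="loocv", C_grid=(1.0,), mrmr_threshold=0.05,
                     mrmr_max_features=20, seed=0)
report = ex.run_homotopic(cohort, config, seed=0, min_patient_fraction=0.08)

print(f"ROIs analyzed: {report['included_rois']}")
for roi, mcc, h in zip(report["included_rois"], report["mcc"],
                       report["homotopic_fc"]):
    print(f"  ROI {roi:2d}: MCC {mcc:+.2f}, control homotopic FC {h:.2f}")
h = report["spearman_homotopic"]
n = report["spearman_nonhomotopic"]
print(f"Spearman(MCC, homotopic FC):     rho = {h['rho']:+.2f}, p = {h['p']:.3f}")
print(f"Spearman(MCC, non-homotopic FC): rho = {n['rho']:+.2f}, p = {n['p']:.3f}")
# A positive, significant homotopic association with a null non-homotopic
# one recovers the injected coupling-dependence.
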