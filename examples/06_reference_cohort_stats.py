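"""Statistics on the bundled reference glioma cohort table.

Loads the 48-patient demographic table (genotype, grade, age, MNI-space
lesion volume) and reproduces the non-parametric group comparisons used
throughout the pipeline: a rank-sum test of lesion volume by IDH
genotype and the median split used for the relative-size classifier.
"""

from contraconn import datasets, stats_core
from contraconn.experiments import median_split

df = datasets.load_glioma_demographics()
print(f"{len(df)} patients; IDH: {df.idh.value_counts().to_dict()}; "
      f"grade: {df.who_grade.value_counts().to_dict()}")

mutant = df.loc[df.idh == "mutant", "lesion_volume"]
wildtype = df.loc[df.idh == "wildtype", "lesion_volume"]
z, p = stats_core.wilcoxon_ranksum(mutant, wildtype)
print(f"lesion volume, mutant vs wildtype: z = {z:.2f}, p = {p:.2f}")
# No volume difference between genotypes -> genotype classification from
# connectivity cannot be explained by tumor size.

labels = median_split(df.lesion_volume)
print(f"median split: {(labels == 'small').sum()} small / "
      f"{(labels == 'large').sum()} large "
      f"(median volume {int(df.lesion_volume.median())} voxels)")
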