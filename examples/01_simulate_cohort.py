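"""Generate the stratified study cohort and its synthetic sperm methylome.

The default design mirrors a 96-man study: four narrow age categories
(22-24, 30, 40-41, >48 years), each split into normal-BMI and
high/obese-BMI halves of 12 men. The methylome is an array-like beta
matrix whose 51 "clock" regions drift linearly with age on the M scale.
"""

import germclock as g

cohort = g.generate_cohort(seed=1)
beta, region_map, truth = g.simulate_methylome(cohort, g.SimulationParams(), seed=1)

print(f"cohort: {len(cohort)} participants")
print(cohort.groupby(["age_category", "bmi_category"]).size().rename("n").to_string())
print(f"\nbeta matrix: {beta.shape[0]} CpGs x {beta.shape[1]} samples, "
      f"values in ({beta.values.min():.2g}, {beta.values.max():.6g})")
print(f"regions: {len(region_map.regions)} "
      f"({len(region_map.clock_regions)} clock, marker = {region_map.marker_region} "
      f"with {len(region_map.probes(region_map.marker_region))} CpGs)")
# Every cell of the design holds exactly 12 men; the marker region is the
# 14-CpG locus used downstream to screen for somatic contamination.
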