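# Silage maize: thermophile C4 crop, whole-plant harvest (harvest_index 1).
# max_monthly_growth calibrated so trial-level regional dry-matter output
# matches mid-1980s..2000s regional prediction levels (~20-22 t DM/ha).
name: maize
pathway: C4
season: [5, 6, 7, 8, 9]
max_monthly_growth: 6.6
temp_optimum: 18.0
temp_base: 8.0
crop_coefficient: 1.0
harvest_index: 1.0
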