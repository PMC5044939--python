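# Cup plant (Silphium perfoliatum), perennial C3 energy crop; established
# stand assumed (first production year onward), whole-plant harvest in early
# autumn.  Summer-centred season makes it the most water-demanding C3 crop.
name: cup_plant
pathway: C3
season: [4, 5, 6, 7, 8, 9]
max_monthly_growth: 5.3
temp_optimum: 16.0
temp_base: 5.0
crop_coefficient: 1.2
harvest_index: 1.0
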