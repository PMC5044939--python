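# Winter wheat, whole-plant biomass (grain share recovered downstream via the
# dry-matter -> grain regression).  Sown in autumn of the previous year;
# harvest-year months run Oct..Jul across the year boundary.
name: winter_wheat
pathway: C3
season: [10, 11, 12, 1, 2, 3, 4, 5, 6, 7]
max_monthly_growth: 4.4
temp_optimum: 14.0
temp_base: 3.0
crop_coefficient: 0.75
harvest_index: 1.0
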