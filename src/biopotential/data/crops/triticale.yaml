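# Winter triticale harvested whole-plant for biogas.  Builds most biomass on
# winter soil moisture in the first half of the year, hence the early-ending
# season and the low water-demand coefficient (weak nFK sensitivity).
name: triticale
pathway: C3
season: [10, 11, 12, 1, 2, 3, 4, 5, 6]
max_monthly_growth: 6.1
temp_optimum: 13.0
temp_base: 3.0
crop_coefficient: 0.9
harvest_index: 1.0
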