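# Default transition pathways and scenario sampling windows.
# min_age: minimum stand age (years) a cell must reach to be eligible;
# age_reset: whether the transition resets stand age to zero;
# prob_map: name of the landscape weight layer steering cell selection.
transitions:
  - {name: urbanization_grass, group: urbanization, from_class: grassland, to_class: developed}
  - {name: urbanization_shrub, group: urbanization, from_class: shrubland, to_class: developed}
  - {name: urbanization_crop, group: urbanization, from_class: annual_crop, to_class: developed}
  - {name: ag_expansion_grass, group: ag_expansion, from_class: grassland, to_class: annual_crop, age_reset: true}
  - {name: ag_expansion_shrub, group: ag_expansion, from_class: shrubland, to_class: annual_crop, age_reset: true}
  - {name: ag_contraction, group: ag_contraction, from_class: annual_crop, to_class: grassland, age_reset: true}
  - {name: clear_cut, group: clear_cut, from_class: forest, to_class: forest,
     min_age: 40, age_reset: true, respects_protection: true}
  - {name: selection_harvest, group: selection, from_class: forest, to_class: forest,
     min_age: 20, age_reset: false, respects_protection: true}
  - {name: orchard_removal, group: orchard_removal, from_class: perennial_crop, to_class: perennial_crop, age_reset: true}
  - {name: fire, group: fire, from_class: forest, to_class: forest, prob_map: fire_rel_prob}
  - {name: drought_mortality, group: drought, from_class: forest, to_class: forest, prob_map: drought_rel_prob}

# Historical-year sampling windows (inclusive) per transition category;
# omitted categories sample the full historical series.
scenario_windows:
  BAU: {urbanization_multiplier: 1.0}
  low: {ag: [1993, 1996], harvest: [2010, 2014], urbanization_multiplier: 0.6}
  medium: {urbanization_multiplier: 0.85}
  high: {ag: [1997, 2002], harvest: [2002, 2009], urbanization_multiplier: 1.3}
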