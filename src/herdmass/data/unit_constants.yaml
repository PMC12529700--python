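# Reference liveweights for the standard biomass aggregation units and
# the per-category coefficients used when converting head counts.
#
# LSU: one grazing adult dairy cow (650 kg liveweight equivalent).
# TLU: tropical livestock unit, 250 kg liveweight.
# PCU: population correction unit, originally 450 kg per adult cow.
unit_constants:
  lsu_kg: 650
  tlu_kg: 250
  pcu_adult_cow_kg: 450

# LSU coefficients per bovine category (EU convention).
lsu_coefficients:
  adult_cow: 1.0
  bovine_over_2y: 1.0
  bovine_1_to_2y: 0.7
  bovine_under_1y: 0.4

# PCU liveweights (kg) per bovine category.
pcu_weights:
  adult_cow: 450
  bovine_over_2y: 450
  bovine_1_to_2y: 200
  bovine_under_1y: 80
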