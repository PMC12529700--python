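# Market animal category -> inclusive age range in months.
#
# The category/age crosswalk used in the original validation is not
# publicly available; these are plausible industry ranges and are fully
# user-replaceable. All shipped tests rely on synthetic ground truth, not
# on the correctness of these particular ranges.
category_age_map:
  calf: [0, 3]
  weaned: [4, 9]
  maiden_heifer: [10, 15]
  in_calf_heifer: [16, 24]
  young_bull_feeder: [10, 16]
  light_store: [10, 16]
  forward_store: [17, 24]
  lactation_1: [24, 36]
  lactation_2: [36, 48]
  lactation_3: [48, 60]
  lactation_4plus: [60, 96]
  finished: [20, 30]
  cull_cow: [60, 120]
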