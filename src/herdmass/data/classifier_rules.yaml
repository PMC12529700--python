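# Threshold set for the herd-classification decision tree.
#
# The operational tree's exact thresholds are not publicly available;
# these defaults reproduce the taxonomy's behaviour on the synthetic
# archetypes and are fully user-replaceable. Rules fire in the order the
# classifier documents (see herdmass.classifier); this file only names
# the thresholds they read.
thresholds:
  adult_age_days: 730          # females older than this count as cows
  dairy_cow_fraction: 0.5      # >= this share of adult females dairy-breed -> dairy
  mixed_cow_fraction: 0.3      # both dairy and beef cow shares >= this -> mixed
  min_births: 1                # calvings required for a breeding herd
  youngstock_fraction: 0.6     # share of members <= adult age for store/rearing
  male_young_fraction: 0.25    # share of young males marking dairy male-rearing
  rearing_young_per_birth: 0.25  # young present per calving marking own-rearing
  progeny_max_age: 1000        # departures older than this are culls, not progeny
  weanling_max_age: 365        # progeny leaving at or under this -> weanling seller
  youngstock_max_age: 550      # progeny leaving at or under this -> youngstock seller
  breed_purity_pedigree: 0.95  # single-code purity marking a pedigree herd
  fattening_min_inflow_age: 450  # mean inflow age at or above this -> fattening
  trading_throughput: 2.0      # (inflow+outflow)/mean members marking trading
  trading_max_stay_days: 60    # mean stay at or under this marks trading
  contract_heifer_inflow_age: [550, 1000]  # returning in-calf heifers (DnR_C)
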