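# Default breed-code -> category map.
#
# The national list used operationally is not publicly available, so this
# map is assembled from common Irish/UK herdbook code conventions and is
# fully user-replaceable: pass your own file to BreedMap.from_yaml().
# Cross-bred codes carry a terminal marker (e.g. FRX = Friesian cross) and
# are resolved to the sire breed before lookup.
cross_suffixes: ["X"]
mapping:
  # dairy
  FR: dairy          # Friesian
  HO: dairy          # Holstein
  HF: dairy          # Holstein-Friesian
  JE: dairy          # Jersey
  AY: dairy          # Ayrshire
  MB: dairy          # Montbeliarde
  NR: dairy          # Norwegian Red
  # continental beef
  CH: continental_beef   # Charolais
  LM: continental_beef   # Limousin
  BB: continental_beef   # Belgian Blue
  SI: continental_beef   # Simmental
  BA: continental_beef   # Blonde d'Aquitaine
  PT: continental_beef   # Parthenaise
  SAL: continental_beef  # Salers
  # British-Irish beef
  AA: british_irish_beef  # Aberdeen Angus
  HE: british_irish_beef  # Hereford
  SH: british_irish_beef  # Shorthorn
  DEX: british_irish_beef # Dexter
  GA: british_irish_beef  # Galloway
  KY: british_irish_beef  # Kerry
  LH: british_irish_beef  # Longhorn
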