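# Dose-directive extraction grammar.
#
# Sites extend this file rather than the code: add local verbs, medication
# abbreviations and unit spellings seen in their communication orders.
schema_version: 1

# verb polarity decides the kind of a relative ("by") directive
increase_verbs: [increase, titrate, up]
decrease_verbs: [decrease, wean, reduce, down]
neutral_verbs: [change, adjust, run, set, go, start]

# prepositions: set_preps introduce an absolute target, relative_prep a delta
set_preps: [to, at]
relative_prep: by

# site shorthand -> canonical medication name
abbreviations:
  dopa: dopamine
  dobut: dobutamine
  epi: epinephrine
  fent: fentanyl
  mso4: morphine
  tpn: total parenteral nutrition
  ivf: intravenous fluids
  iv fluids: intravenous fluids
  d10: intravenous fluids

# unit spellings -> canonical unit strings
unit_aliases:
  units/hr: Units/hr
  unit/hr: Units/hr
  u/hr: Units/hr
  units/hour: Units/hr
  mcg/kg/min: mcg/kg/min
  mcg/kg/hr: mcg/kg/hr
  ug/kg/min: mcg/kg/min
  ml/hr: mL/hr
  cc/hr: mL/hr
  mg/hr: mg/hr
  milliunits/kg/min: milliunits/kg/min
  mu/kg/min: milliunits/kg/min
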