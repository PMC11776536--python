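# Alignment between (liver parameter, direction) findings and canonical
# ontology effect tokens. Observations with an aligned token can be matched
# against ontology adverse-effect profiles; unaligned combinations get a
# generated token and label ("<direction> <parameter>").
alignments:
  - {parameter: ALP, direction: increase, token: increased-ALP, label: increased ALP}
  - {parameter: GGT, direction: increase, token: GGT-presence, label: presence of GGT}
  - {parameter: hepatic necrosis, direction: increase, token: necrosis, label: necrosis}
  - {parameter: bilirubin, direction: increase, token: increased-bilirubin, label: increased bilirubin}
  - {parameter: hepatic fat, direction: increase, token: increased-hepatic-fat, label: increased hepatic fat}
  - {parameter: triglycerides, direction: increase, token: increased-triglycerides, label: increased triglycerides}
  - {parameter: cholesterol, direction: increase, token: increased-cholesterol, label: increased cholesterol}
  - {parameter: hepatocellular hypertrophy, direction: increase, token: hepatocellular-hypertrophy, label: hepatocellular hypertrophy}
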