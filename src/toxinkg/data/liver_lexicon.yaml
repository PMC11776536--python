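# Liver-parameter lexicon: canonical tokens, synonyms as they appear across
# opinions (case-insensitive lookup), and enzyme EC numbers where they exist.
# Synonym sets must be pairwise disjoint; the loader enforces this.
# User-overridable; extending to other organs means broadening this file.
parameters:
  - canonical: ALT
    ec_number: EC 2.6.1.2
    synonyms:
      - alanine aminotransferase
      - serum glutamate-pyruvate transaminase
      - SGPT
      - GPT
      - ALAT
  - canonical: AST
    ec_number: EC 2.6.1.1
    synonyms:
      - aspartate aminotransferase
      - serum glutamate-oxaloacetate transaminase
      - SGOT
      - GOT
      - ASAT
  - canonical: ALP
    ec_number: EC 3.1.3.1
    synonyms:
      - alkaline phosphatase
      - AP
  - canonical: GGT
    ec_number: EC 2.3.2.1
    synonyms:
      - gamma-glutamyl transpeptidase
      - gamma-glutamyltransferase
      - gamma-GT
      - GGTP
  - canonical: sorbitol dehydrogenase
    ec_number: EC 1.1.1.14
    synonyms:
      - SDH
      - iditol dehydrogenase
  - canonical: cholesterol
    synonyms:
      - total cholesterol
      - serum cholesterol
  - canonical: triglycerides
    synonyms:
      - fasting triglycerides
      - serum triglycerides
  - canonical: phospholipids
    synonyms:
      - serum phospholipids
  - canonical: hepatic fat
    synonyms:
      - liver fat
      - hepatic lipid content
  - canonical: hepatocellular hypertrophy
    synonyms:
      - liver hypertrophy
      - hepatocyte hypertrophy
  - canonical: bilirubin
    synonyms:
      - total bilirubin
      - serum bilirubin
  - canonical: hepatic necrosis
    synonyms:
      - hepatocellular necrosis
      - liver necrosis
      - necrosis
  - canonical: total protein
    synonyms:
      - serum total protein
  - canonical: albumin
    synonyms:
      - serum albumin
  - canonical: HDL
    synonyms:
      - high-density lipoprotein
      - HDL cholesterol
  - canonical: LDL
    synonyms:
      - low-density lipoprotein
      - LDL cholesterol
  - canonical: necropsy and histopathology findings
    synonyms:
      - necropsy findings
      - histopathology findings
      - histopathology
      - necropsy
directions:
  increase: [increase, increased, increases, raise, raised, raises, higher, elevated, elevation]
  decrease: [decrease, decreased, decreases, lower, lowered, reduced, reduction]
  change: [change, changed, differ, different, difference, alter, altered, alteration]
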