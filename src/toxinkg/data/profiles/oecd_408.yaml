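# 90-day repeated-dose oral toxicity (rodent) profile.
# Concepts (capitalized) structure the hierarchy, at most three levels deep;
# value properties (lowercase) carry the data. A literal "/" inside a
# property name is escaped as "\/" in serialized paths.
guideline_id: OECD_408
endpoint: repeated-dose oral toxicity (90-day, rodent)
study_kind: repeated_dose
concepts:
  - name: Test method
    concepts:
      - name: Test substance
        properties:
          - name: test substance identification
          - name: purity
          - name: source of test substance
          - name: physico-chemical properties
          - name: batch number
          - name: homogeneity and stability
      - name: Test condition
        properties:
          - name: oral administration
            type: enum
            allowed_values: [gavage, diet, drinking water]
          - name: dose-volume ml/kg bw
            type: numeric
            unit: ml/kg bw
          - name: dose levels
            unit: mg/kg bw/day
          - name: repeated administration scheme
          - name: duration of exposure
          - name: time-points of observations
          - name: vehicle
      - name: Test animal
        properties:
          - name: species
          - name: sex
            type: enum
            allowed_values: [male, female, male and female]
          - name: strain
          - name: age value
            type: numeric
          - name: age unit
            type: enum
            allowed_values: [days, weeks, months, years]
          - name: body weight
          - name: number of animals per group
            type: numeric
          - name: housing and feeding conditions
  - name: Results
    concepts:
      - name: Clinical observations
        properties:
          - name: clinical and functional observations
          - name: moribund or dead animals prior to study termination
            type: boolean
          - name: mortality rate
      - name: Hematology
        properties:
          - name: hematology findings
      - name: Clinical biochemistry
        concepts:
          - name: Hepatocellular effect
            properties:
              - name: alt
              - name: ast
              - name: alp
              - name: ggt
              - name: total cholesterol
              - name: triglycerides
              - name: bilirubin
              - name: total protein
              - name: albumin
      - name: Pathology
        properties:
          - name: necropsy findings
          - name: histopathology findings
          - name: organ weights
  - name: Documentation
    properties:
      - name: study endpoints and methods
      - name: statistical methods
defaults:
  # Omitted scheme fields are treated as unintentional omissions in
  # guideline-conformant studies, not as non-compliance.
  Test method/Test condition/repeated administration scheme: 7 days/week
  Test method/Test condition/duration of exposure: 90 days
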