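# Acute oral toxicity profile. Smaller tree than the 90-day profile: no
# repeated-administration scheme, no liver-specific biochemistry block.
guideline_id: OECD_401
endpoint: acute oral toxicity
study_kind: acute
concepts:
  - name: Test method
    concepts:
      - name: Test substance
        properties:
          - name: test substance identification
          - name: purity
          - name: source of test substance
          - name: physico-chemical properties
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
            unit: mg/kg bw
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
  - name: Results
    concepts:
      - name: Clinical observations
        properties:
          - name: clinical and functional observations
          - name: moribund or dead animals prior to study termination
            type: boolean
          - name: mortality rate
      - name: Pathology
        properties:
          - name: necropsy findings
          - name: histopathology findings
  - name: Documentation
    properties:
      - name: study endpoints and methods
      - name: statistical methods
defaults:
  # single administration; a 14-day observation window is the guideline norm
  Test method/Test condition/duration of exposure: single administration, 14-day observation
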