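# Evidence mapping for the 21-question reliability checklist (5 criteria
# groups). Each question lists the guideline-profile paths consulted and a
# combinator:
#   any  - score 1 if at least one listed path resolves and carries a value
#   all  - score 1 if every listed path that resolves in the profile carries
#          a value (paths absent from a guideline's tree are ignored, so one
#          rulebook serves every shipped profile)
#   controls              - negative/positive-control rule (code)
#   administration_scheme - route-dependent scheme rule (code)
#   oecd_compliance       - satisfied by OECD-registered study design (code)
# "red" questions are mandatory for reliability categories 1 and 2.
# applies_to: all | repeated_dose_only | inhalation_or_repeated_dose
questions:
  - id: I.1
    group: I
    red: true
    text: Was the test substance identified?
    rule: any
    paths: [Test method/Test substance/test substance identification]
  - id: I.2
    group: I
    red: false
    text: Is the purity of the substance given?
    rule: any
    paths: [Test method/Test substance/purity]
  - id: I.3
    group: I
    red: false
    text: Is information on the source/origin of the substance given?
    rule: any
    paths: [Test method/Test substance/source of test substance]
  - id: I.4
    group: I
    red: false
    text: >-
      Is all information on the nature and/or physico-chemical properties of
      the test item given, which you deem indispensable for judging the data?
    rule: any
    paths: [Test method/Test substance/physico-chemical properties]
  - id: II.1
    group: II
    red: true
    text: Is the species given?
    rule: any
    paths: [Test method/Test animal/species]
  - id: II.2
    group: II
    red: false
    text: Is the sex of the test organism given?
    rule: any
    paths: [Test method/Test animal/sex]
  - id: II.3
    group: II
    red: false
    text: >-
      Is information given on the strain of test animal plus, if considered
      necessary to judge the study, other specifications?
    rule: any
    paths: [Test method/Test animal/strain]
  - id: II.4
    group: II
    red: false
    text: Is age or body weight of the test organisms at the start of the study given?
    rule: any
    paths:
      - Test method/Test animal/age value
      - Test method/Test animal/body weight
  - id: II.5
    group: II
    red: false
    applies_to: repeated_dose_only
    text: >-
      For repeated dose toxicity studies only: Is information given on the
      housing or feeding conditions?
    rule: any
    paths: [Test method/Test animal/housing and feeding conditions]
  - id: III.1
    group: III
    red: true
    text: Is the administration route given?
    rule: any
    paths: [Test method/Test condition/oral administration]
  - id: III.2
    group: III
    red: true
    text: Are doses administered or concentrations in application media given?
    rule: any
    paths: [Test method/Test condition/dose levels]
  - id: III.3
    group: III
    red: true
    text: >-
      Are frequency and duration of exposure as well as time-points of
      observations explained?
    rule: all
    paths:
      - Test method/Test condition/repeated administration scheme
      - Test method/Test condition/duration of exposure
      - Test method/Test condition/time-points of observations
  - id: III.4
    group: III
    red: true
    text: Were negative and positive controls included?
    rule: controls
    paths: [Test method/Test condition/dose levels]
  - id: III.5
    group: III
    red: true
    text: Is the number of animals per group given?
    rule: any
    paths: [Test method/Test animal/number of animals per group]
  - id: III.6
    group: III
    red: false
    text: Are sufficient details of the administration scheme given to judge the study?
    rule: administration_scheme
    paths:
      - Test method/Test condition/oral administration
      - Test method/Test substance/homogeneity and stability
      - Test method/Test condition/dose-volume ml\/kg bw
  - id: III.7
    group: III
    red: false
    applies_to: inhalation_or_repeated_dose
    text: >-
      For inhalation studies and repeated dose toxicity studies only: Were
      achieved concentrations analytically verified or was stability of the
      test substance otherwise ensured is made plausible?
    rule: any
    paths: [Test method/Test substance/homogeneity and stability]
  - id: IV.1
    group: IV
    red: false
    text: >-
      Are the study endpoint(s) and their method(s) of determination clearly
      described?
    rule: any
    paths: [Documentation/study endpoints and methods]
  - id: IV.2
    group: IV
    red: false
    text: >-
      Is the description of the study results for all endpoints investigated
      transparent and complete?
    rule: any
    paths:
      - Results/Clinical biochemistry/Hepatocellular effect/alt
      - Results/Clinical biochemistry/Hepatocellular effect/ast
      - Results/Pathology/histopathology findings
      - Results/Pathology/necropsy findings
      - Results/Hematology/hematology findings
      - Results/Clinical observations/clinical and functional observations
  - id: IV.3
    group: IV
    red: false
    text: >-
      Are the statistical methods applied for data analysis given and applied
      in a transparent manner?
    rule: any
    paths: [Documentation/statistical methods]
  - id: V.1
    group: V
    red: true
    text: >-
      Is the study design chosen appropriate for obtaining the
      substance-specific data aimed at?
    rule: oecd_compliance
    paths: []
  - id: V.2
    group: V
    red: false
    text: Are the quantitative study results reliable?
    rule: any
    paths:
      - Results/Clinical biochemistry/Hepatocellular effect/alt
      - Results/Pathology/histopathology findings
      - Results/Clinical observations/mortality rate
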