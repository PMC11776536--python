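{
  "table2_compounds.csv": "d757bffbf08f46ef9e6748d2eececafbe0450e179d7982546642e55d526023e3",
  "table2_effects.csv": "8f438fa804025c3fcb3b36233675799b254bfedb6ff5102985fde9256f325d6e",
  "corpus_categories.csv": "4e7a327ccd6e8c08a2e360c60ff5fe13b85e45cfbe3c2e59111cd1a936fdaf70",
  "case_study_observations.csv": "8b5521acb6f38c008ef0272ecf48a18670700859aeb501764e1bcb805176a087",
  "mini_ontology.ttl": "d5c1c31abdb9607a3ee43650ed5e8ef5aed53d85b0f3184d43a3ddf29a72bee2"
}
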