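# Declarative CSV-record -> RDF mapping rules (R2RML-inspired; no SQL
# layer). Each rule emits at most one quad per source row into the
# `internal` named graph. Object specs: {column: ...} literal from a row
# column (empty values emit nothing), {const_iri: ...} a fixed IRI,
# {iri_template: ...} an IRI built from row columns. Derived columns
# (parameter_slug, effect_token, effect_label, qualifier_list) are computed
# by the row builders before mapping.
namespaces:
  tox: https://toxinkg.example.org/
  toxv: https://toxinkg.example.org/vocab/
  rdf: http://www.w3.org/1999/02/22-rdf-syntax-ns#
  rdfs: http://www.w3.org/2000/01/rdf-schema#
rules:
  # compounds
  - {source: compounds, subject: "compound/{compound_id}", predicate: rdf:type,
     object: {const_iri: toxv:Compound}}
  - {source: compounds, subject: "compound/{compound_id}", predicate: rdfs:label,
     object: {column: ingredient_name}}
  - {source: compounds, subject: "compound/{compound_id}", predicate: toxv:casNumber,
     object: {column: cas_number}}
  - {source: compounds, subject: "compound/{compound_id}", predicate: toxv:useCategory,
     object: {column: use_category}}
  - {source: compounds, subject: "compound/{compound_id}", predicate: toxv:canonicalSmiles,
     object: {column: canonical_smiles}}
  # opinions
  - {source: opinions, subject: "opinion/{sccs_number}", predicate: rdf:type,
     object: {const_iri: toxv:Opinion}}
  - {source: opinions, subject: "opinion/{sccs_number}", predicate: toxv:year,
     object: {column: year, datatype: integer}}
  - {source: opinion_links, subject: "opinion/{sccs_number}", predicate: toxv:assesses,
     object: {iri_template: "compound/{compound_id}"}}
  # studies
  - {source: studies, subject: "study/{compound_id}/{study_id}", predicate: rdf:type,
     object: {const_iri: toxv:Study}}
  - {source: studies, subject: "study/{compound_id}/{study_id}", predicate: toxv:testSubjectOf,
     object: {iri_template: "compound/{compound_id}"}}
  - {source: studies, subject: "study/{compound_id}/{study_id}", predicate: toxv:guideline,
     object: {column: guideline_id}}
  # effect observations
  - {source: effects, subject: "observation/{compound_id}/{parameter_slug}/{direction}",
     predicate: rdf:type, object: {const_iri: toxv:Observation}}
  - {source: effects, subject: "observation/{compound_id}/{parameter_slug}/{direction}",
     predicate: toxv:subject, object: {iri_template: "compound/{compound_id}"}}
  - {source: effects, subject: "observation/{compound_id}/{parameter_slug}/{direction}",
     predicate: toxv:parameter, object: {column: parameter}}
  - {source: effects, subject: "observation/{compound_id}/{parameter_slug}/{direction}",
     predicate: toxv:direction, object: {column: direction}}
  - {source: effects, subject: "observation/{compound_id}/{parameter_slug}/{direction}",
     predicate: rdfs:label, object: {column: effect_label}}
  - {source: effects, subject: "observation/{compound_id}/{parameter_slug}/{direction}",
     predicate: toxv:effectToken, object: {column: effect_token}}
  - {source: effects, subject: "observation/{compound_id}/{parameter_slug}/{direction}",
     predicate: toxv:qualifiers, object: {column: qualifier_list}}
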