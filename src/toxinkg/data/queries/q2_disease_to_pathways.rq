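# Which biological processes, pathways or causal-activity models are
# impacted by a specific disease/toxic process?
PREFIX ont:  <https://toxinkg.example.org/ontology/vocab/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT DISTINCT ?entity ?label WHERE {
  %DISEASE% (ont:has_part|ont:associated_model|ont:has_part/ont:involves_process) ?entity .
  ?entity rdfs:label ?label .
}
ORDER BY ?label ?entity
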