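# Given observed adverse-effect tokens, which toxic processes/diseases may
# affect the subject? Subtypes inherit their ancestors' effects via
# rdfs:subClassOf*. Ranked by shared-effect count (descending), then label,
# then IRI.
PREFIX ont:  <https://toxinkg.example.org/ontology/vocab/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?process ?label (COUNT(DISTINCT ?token) AS ?shared) WHERE {
  VALUES ?token { %TOKENS% }
  ?effect ont:canonical_token ?token ;
          ont:has_context ?context .
  ?process rdfs:subClassOf* ?context ;
           a ont:ToxicProcess ;
           rdfs:label ?label .
}
GROUP BY ?process ?label
ORDER BY DESC(?shared) ?label ?process
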