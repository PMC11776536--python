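# Which gene or protein's functionality is hindered by a toxic process?
# Accepts a disease or a biological process: has_part* reaches the affected
# processes, involves_process their pathways, and gene products attach to
# those pathways.
PREFIX ont:  <https://toxinkg.example.org/ontology/vocab/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT DISTINCT ?gene ?label WHERE {
  %PROCESS% (ont:has_part*/ont:involves_process) ?pathway .
  ?gene ont:participates_in ?pathway ;
        rdfs:label ?label .
}
ORDER BY ?label ?gene
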