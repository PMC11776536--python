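# Miniature hepatotoxicity ontology fixture: toxic processes/diseases,
# adverse effects (with canonical effect tokens), biological processes,
# pathways, a causal-activity model and gene products. A stand-in for full
# ontology imports, scoped to the liver worked examples.
@prefix ont:  <https://toxinkg.example.org/ontology/vocab/> .
@prefix ent:  <https://toxinkg.example.org/ontology/entity/> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix skos: <http://www.w3.org/2004/02/skos/core#> .
@prefix xsd:  <http://www.w3.org/2001/XMLSchema#> .

### toxic processes / diseases
ent:cholestasis a ont:ToxicProcess ;
    rdfs:label "cholestasis" ;
    skos:altLabel "liver cholestasis" ;
    ont:has_part ent:bile-secretion-hypofunction .

ent:lipidosis a ont:ToxicProcess ;
    rdfs:label "lipidosis" .

ent:nafld a ont:ToxicProcess ;
    rdfs:label "NAFLD" ;
    skos:altLabel "non-alcoholic fatty liver disease" ;
    rdfs:subClassOf ent:lipidosis ;
    ont:has_part ent:lipid-biosynthesis-hyperfunction ;
    ont:associated_model ent:lipid-metabolism-cam .

### adverse effects (canonical tokens bridge to internal observations)
ent:increased-alp a ont:AdverseEffect ;
    rdfs:label "increased ALP" ;
    skos:altLabel "increasing blood ALP concentration" ;
    ont:canonical_token "increased-ALP" ;
    ont:has_context ent:cholestasis .

ent:ggt-presence a ont:AdverseEffect ;
    rdfs:label "presence of GGT" ;
    ont:canonical_token "GGT-presence" ;
    ont:has_context ent:cholestasis .

ent:necrosis a ont:AdverseEffect ;
    rdfs:label "necrosis" ;
    skos:altLabel "hepatocellular necrosis" ;
    ont:canonical_token "necrosis" ;
    ont:has_context ent:cholestasis .

ent:increased-bilirubin a ont:AdverseEffect ;
    rdfs:label "increased bilirubin" ;
    ont:canonical_token "increased-bilirubin" ;
    ont:has_context ent:cholestasis .

ent:increased-hepatic-fat a ont:AdverseEffect ;
    rdfs:label "increased hepatic fat" ;
    ont:canonical_token "increased-hepatic-fat" ;
    ont:has_context ent:nafld .

ent:increased-triglycerides a ont:AdverseEffect ;
    rdfs:label "increased triglycerides" ;
    ont:canonical_token "increased-triglycerides" ;
    ont:has_context ent:nafld .

ent:increased-cholesterol a ont:AdverseEffect ;
    rdfs:label "increased cholesterol" ;
    ont:canonical_token "increased-cholesterol" ;
    ont:has_context ent:lipidosis .

ent:hepatocellular-hypertrophy a ont:AdverseEffect ;
    rdfs:label "hepatocellular hypertrophy" ;
    ont:canonical_token "hepatocellular-hypertrophy" ;
    ont:has_context ent:lipidosis .

### biological processes affected by the diseases
ent:lipid-biosynthesis-hyperfunction a ont:BiologicalProcess ;
    rdfs:label "hyperfunction of lipid biosynthesis" ;
    ont:involves_process ent:fatty-acid-biosynthetic-process .

ent:bile-secretion-hypofunction a ont:BiologicalProcess ;
    rdfs:label "hypofunction of bile secretion" ;
    ont:involves_process ent:bile-acid-secretion .

### pathways
ent:fatty-acid-biosynthetic-process a ont:Pathway ;
    rdfs:label "fatty acid biosynthetic process" .

ent:bile-acid-secretion a ont:Pathway ;
    rdfs:label "bile acid secretion" .

### causal-activity model
ent:lipid-metabolism-cam a ont:Model ;
    rdfs:label "lipid metabolism causal activity model" .

### gene products
ent:acc1 a ont:GeneProduct ;
    rdfs:label "acetyl-CoA carboxylase 1" ;
    ont:participates_in ent:fatty-acid-biosynthetic-process .

ent:fasn a ont:GeneProduct ;
    rdfs:label "fatty acid synthase" ;
    ont:participates_in ent:fatty-acid-biosynthetic-process .

ent:bsep a ont:GeneProduct ;
    rdfs:label "bile salt export pump" ;
    ont:participates_in ent:bile-acid-secretion .
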