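# toxinkg

Structured curation, automated reliability scoring, hepatotoxicity
screening and RDF knowledge-graph construction for cosmetic-ingredient
safety data.

Regulatory safety assessments of cosmetic ingredients rest on historical
repeated-dose animal studies reported in scientific opinions — free-text
documents with inconsistent terminology. `toxinkg` gives that data a
machine-processable shape for toxicologists and risk assessors working on
animal-free (NAM/NGRA-style) assessment workflows:

- **Guideline profiling** (`toxinkg.study_model`): each OECD test guideline
  is decomposed into a tree of *concepts* (capitalized structural nodes, at
  most three levels) and *value properties* (typed lowercase fields with
  units, e.g. `dose-volume ml/kg bw`). Profiles for 90-day repeated-dose
  oral toxicity and acute oral toxicity ship as YAML data; study records
  address fields by slash-delimited paths validated against the profile.
- **Automated reliability scoring** (`toxinkg.toxrtool`): the 21-question
  EURL ECVAM ToxRTool checklist is answered from structured fields via a
  declarative evidence rulebook, mapped onto Klimisch categories
  (sum ≥ 18 → 1, 13–17 → 2, < 13 → 3) and revised by the mandatory "red"
  questions — a study failing any red question cannot be category 1 or 2.
  Guideline defaults (e.g. "7 days/week", "90 days") fill unintentional
  omissions and are flagged in the per-question provenance.
- **Liver-toxicant filters** (`toxinkg.liver_filter`): parameter synonyms
  (ALT = SGPT = GPT = ALAT = alanine aminotransferase ...) and direction
  keywords (increase/raise/higher; change/differ/alter) are normalized via
  a data-shipped lexicon; mixed findings ("increase/decrease") and
  qualifier flags (incidental, dermal, human, ...) are first-class.
- **Chemical identity** (`toxinkg.chem_id`): canonical SMILES (RDKit),
  CAS check digits, set-based Dice similarity 2|A∩B|/(|A|+|B|) with the
  ≥ 0.5 structural-alert assignment rule, and punctuation-tolerant fuzzy
  name search ("HC Blue No. 15" ≡ "HC Blue No.15").
- **Knowledge graph** (`toxinkg.kg_builder`): declarative CSV→RDF mapping
  rules build a quad store with named-graph provenance (`internal`,
  `ontology`, `external_links`, `inferred`); `owl:sameAs` links come from
  normalized-label matches, "is affected by" links are inferred by counting
  adverse effects shared between a test subject and a disease profile
  (subtypes inherit ancestors' effects), and three competency queries ship
  as SPARQL.
- **Fixtures** (`toxinkg.fixtures`): a packaged 53-ingredient liver-toxicant
  overview, corpus category counts, a miniature hepatotoxicity ontology,
  and a seeded generator of guideline-conformant synthetic studies.

## Worked example

```python
from toxinkg import fixtures, query, FilterQuery, score_study
from toxinkg.study_model import ProfileRegistry

# Liver screening over the packaged overview
ds = fixtures.load_table2()
print(len(query(ds, FilterQuery())))                      # 53
print(len(query(ds, FilterQuery(parameter="SGPT",
        exclude_qualifiers=fixtures.ALT_REFERENCE_EXCLUSIONS))))  # 18
print(len(query(ds, FilterQuery(parameter="ALP",
        direction="pure_increase"))))                     # 8

# Reliability scoring of a fully evidenced synthetic 90-day study
study = fixtures.generate_studies(fixtures.GeneratorConfig(seed=1, n_studies=1))[0]
result = score_study(study, ProfileRegistry.builtin())
print(result.sum, result.initial_category, result.revised_category)  # 21 1 1
```

The three screen counts are distinct compounds: 53 ingredients alter at
least one liver parameter; 18 affect ALT under the documented qualifier
policy (see `src/toxinkg/data/README.md`); 8 show a pure ALP increase. The
scoring triple is the checklist sum and the initial/revised Klimisch
categories — a fully evidenced guideline study is "reliable without
restriction".

The same operations are available from the shell:

```bash
toxinkg filter --parameter ALT --direction any --dataset @table2
toxinkg build-kg --dataset @kg --out kg.trig
toxinkg query --kind q1 --effects increased-ALP,GGT-presence,necrosis
```

## Layout

```
src/toxinkg/          library modules + data/ (profiles, lexicon, rulebook,
                      fixtures, ontology, mapping rules, SPARQL queries)
tests/                pytest suite (unit, property-based, end-to-end)
scripts/acceptance.py headline-quantity reproduction
docs/methods.md       models, rules and design choices in detail
```
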