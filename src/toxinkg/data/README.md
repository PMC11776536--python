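# Packaged fixture data

All files are plain text, immutable, and covered by `checksums.json`
(sha256; loaders verify on read).

## `table2_compounds.csv` / `table2_effects.csv`

Transcription of the published 53-ingredient liver-toxicant overview
(90-day repeated-dose studies): one row per compound, one effect row per
non-empty compound x parameter cell.

Transcription conventions, cell by cell:

- Directions: `Increase`/`Decrease` as printed; `Increase/decrease` (either
  order, with or without spaces) becomes the single direction `mixed`;
  `Different`, `Change` and `Altered` become `change`.
- Parenthetical notes become qualifier flags: `(non-OECD)` → `non_OECD`,
  `(inhalation)` → `inhalation`; the cholesterol cell for triclosan printed
  as "Increase (also <human marker>)/decrease" becomes `mixed` with flag
  `human`.
- The eight footnote symbols of the source legend map, in legend order, to
  the flags `doubtful_or_unrelated`, `not_histopath_supported`,
  `incidental`, `dermal`, `human`, `method_interference`,
  `sccs_conclusion_only`, `adaptive_compensatory`.
- CAS/EC/SMILES columns are left empty: the source table does not print
  them and no values are fabricated.

### Qualifier policy for the reference counts

The default filter policy excludes nothing; under it the any-parameter /
any-direction screen returns all 53 compounds, and the ALT screen returns
19.

The reference count of **18 ALT-affecting ingredients** is reproduced by
excluding the `sccs_conclusion_only` flag (an ALT finding mentioned only in
an assessment's conclusion, with no cited study behind it — the
o-phenylphenol ALT cell). Note this choice is not unique: excluding
`method_interference` (2-hydroxyethylamino-5-nitroanisole) or `non_OECD`
(butylphenyl methylpropional) instead would also leave 18 distinct
compounds. The package exposes the policy as data
(`fixtures.ALT_REFERENCE_EXCLUSIONS`) rather than hard-coding it into the
query engine.

The pure-increase ALP screen returns 8 compounds under the default
(no-exclusion) policy.

## `case_study_observations.csv`

The hepatocellular-necrosis histopathology observation for Basic Red 51
used by the worked cholestasis-linkage example. It is kept separate because
the overview table's necrosis cell for this compound is empty; the
observation comes from the underlying opinion's study record as illustrated
in the linkage example. `fixtures.load_kg_dataset()` merges it with the
overview.

## `corpus_categories.csv`

The seven use-category ingredient counts of the curated corpus
(62 + 9 + 5 + 2 + 2 + 4 + 4 = 88). Ingredients not among the 53 named ones
are generated as placeholder records (`is_placeholder=true`, no effect
entries) — synthetic stand-ins, never presented as real assessment content.

## `mini_ontology.ttl`

A miniature hepatotoxicity ontology (toxic processes, adverse effects with
canonical tokens, biological processes, pathways, one causal-activity
model, gene products). It stands in for full ontology imports and is scoped
to the shipped worked examples; the loader accepts any Turtle file of the
same vocabulary.

## Other data files

`profiles/*.yaml` (guideline profiles), `rulebook.yaml` (reliability
checklist evidence mapping), `liver_lexicon.yaml` (parameter/direction
lexicon), `kg_mapping.yaml` (CSV→RDF rules), `effect_alignment.yaml`
(finding → effect-token bridge) and `queries/*.rq` (competency queries) are
configuration shipped as data; they are user-overridable and not
checksummed.
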