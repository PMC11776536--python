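# Methods

This note records the models, rules, numerical choices and known
limitations behind `toxinkg`, in the package's own terms.

## Guideline-profiled data model

An OECD test-guideline profile is a tree of *concepts* — structural nodes
with capitalized names, at most three levels deep — whose leaves carry
*value properties*: lowercase, typed fields (`boolean` with exactly
{YES, NO}, `numeric`, `text`, `enum`) and optional units. Study records
address fields with slash-delimited paths; a literal `/` inside a property
name (units like `ml/kg bw`) is escaped as `\/` in serialized form, which
is the single unambiguous convention the path syntax needs. Ages are two
properties (numeric value + unit enum of days/weeks/months/years) so the
number stays computable.

Profiles are data (YAML), not code: the shipped files cover 90-day
repeated-dose oral toxicity and acute oral toxicity, and new endpoints
(toxicokinetics, skin absorption) are additive files. The shipped 90-day
profile covers every property the scoring rulebook consults plus the
liver-specific biochemistry block; it is deliberately extensible rather
than a complete transcription of the guideline, whose full property list
is longer than any single source document prints.

Studies without an OECD guideline (`guideline_id = "non-OECD"`) carry free
text and the generic reliability block only; they are validated for type
coherence and excluded from automated scoring — their assessment hinges on
expert comments the package does not attempt to interpret (no free-text
mining anywhere: a fact absent from structured fields does not exist for
the scorer).

## Reliability scoring

The checklist has 21 questions in five groups (4/5/7/3/2); eight are
mandatory ("red"): I.1, II.1, III.1–III.5, V.1. Group counts and the red
set are enforced at rulebook load. Two questions are conditional: II.5
applies to repeated-dose studies only, III.7 to repeated-dose or
inhalation studies; for acute studies they are skipped entirely (not
scored, not counted), and the 18/13 thresholds are applied to the same
scale without rescaling — matching established checklist practice, where
inapplicable questions simply cannot contribute points.

Evidence derivation is declarative: each question maps to profile paths
and a combinator (`any`/`all`). Paths that do not resolve in a given
profile are ignored, so one rulebook serves every shipped guideline. Three
rules are code, by design:

- **III.6 (administration scheme)**: gavage routes accept either
  homogeneity/stability data or a dose volume in ml/kg bw; diet and
  drinking-water routes require homogeneity/stability; an absent route
  scores 0.
- **III.4 (controls)**: the reliability block's control & recovery data
  satisfies the question; otherwise a "0" entry among the dose levels
  counts as the negative control; otherwise 0.
- **V.1 (design appropriateness)**: scored 1 for any study registered to
  an OECD guideline — the scorer's scope is exactly those studies, and
  guideline conformance is what the question asks about at this level of
  structure. This is a presence heuristic, recorded in the answer note.

The remaining mappings (IV.2, V.2 in particular) are presence checks over
results-bearing paths; they are data and user-overridable, not claims
about how a human assessor weighs result quality.

**Defaults.** A guideline-conformant study that omits scheme fields is
assumed to have omitted them unintentionally; per-profile defaults (90-day
profile: repeated administration scheme "7 days/week", duration of
exposure "90 days") fill such gaps before scoring. Defaults only ever add
evidence (scores without defaults are ≤ scores with), and every answer
resting on a default is flagged so rendered output can distinguish
source-derived from assumed evidence.

**Categories.** The initial category is a pure threshold map: sum ≥ 18 →
1, 13–17 → 2, < 13 → 3 (domain checked, 0–21). Revision: if every
applicable red question scores 1 the initial category stands; a red
failure forbids categories 1 and 2 under the default policy
(`red_fail_policy="three"`). The literature also states a softer reading —
category "2 or 3, depending on the sum" — which is implemented as
`sum_capped_two` (revised = max(initial, 2)) behind an explicit switch
rather than silently reconciled; the two readings disagree only for a
red-failing study with sum ≥ 13. A third reading ("all reds pass ⇒
category 1 outright") contradicts the thresholds and is not implemented.

## Liver-toxicant filters

The lexicon (YAML, user-overridable) maps each canonical parameter to its
synonym set (case-insensitive, pairwise disjoint — enforced at load) and
carries enzyme EC numbers. Direction keywords map to three classes
(increase, decrease, change); a compound token like "Increase/decrease"
becomes the distinct direction `mixed`. `mixed` is its own direction so a
`pure_increase` query cannot double-count an ambivalent finding; the plain
`increase`/`decrease` query directions include `mixed`, `any` includes
everything.

Qualifier flags transcribe source-table footnotes
(doubtful_or_unrelated, not_histopath_supported, incidental, dermal,
human, method_interference, sccs_conclusion_only, adaptive_compensatory)
plus parenthetical notes (non_OECD, inhalation). The default query
excludes nothing — counts reflect raw table presence — and exclusion is an
explicit, configurable query parameter. The packaged overview's reference
counts and the documented ALT policy are described in
`src/toxinkg/data/README.md`, including the fact that three different
single-flag exclusions would reproduce the 18-compound ALT reference
count; the shipped choice (`sccs_conclusion_only`) excludes the one ALT
finding backed by no cited study.

## Chemical identity

Canonicalization delegates to RDKit behind a small contract (idempotent;
one string per molecule; parse failures and polymer-flagged inputs raise
typed errors — the two polymer ingredients in the corpus have no
meaningful small-molecule SMILES). Fingerprints are Morgan (radius 2)
sparse keys treated as plain sets; the Dice similarity
2|A∩B|/(|A|+|B|) is implemented in-repo as set algebra so the ≥ 0.5
alert-assignment rule is testable with synthetic feature sets,
independent of any chemistry engine. Set-based (unweighted) Dice is the
documented choice; a count-weighted variant would need information the
alert-profile fixtures do not carry. Alert assignments are sorted by
descending similarity with the alert name as tie-break and labelled
preliminary indicators; the live profiler service adapter is an interface
stub, with profile fixtures supplied by the caller.

Name search normalizes case, punctuation and the "No."/"No"/"No.15"
variants (the standalone token "no" is elided, so "HC Blue 15" and
"HC Blue No. 15" coincide). Proportional mode keeps the best-scoring
fraction of the index plus every substring match — so "yellow" always
surfaces every name containing "yellow" — while hard mode applies a plain
similarity threshold. Similarity is the stdlib normalized edit-ratio;
substring matches are floored at 0.5 + ratio/2 so they outrank incidental
near-misses.

CAS numbers are validated with the standard positional check-digit rule;
failures are recorded as warnings, not fatal errors, because legacy
registry numbers occur in curated source data.

## Ingest

The corpus travels as four CSVs (compounds, opinions, studies, effects),
one logical record per row. Study field maps and embedded tables are
linearized into one cell with a fixed dialect — cells `;`, rows `|`,
backslash escapes — chosen once and documented so the format is bit-exact
round-trippable (`write_dataset` → `read_dataset` is the identity on
sorted content, and row order never affects the result). Invalid rows are
flagged and retained, never dropped; within a study, repeated identical
mentions of a field collapse to one, while conflicting repeats are kept
side by side with a conflict flag. Multiple opinions per ingredient
resolve to the most recent year (`Dataset.latest_opinion`). The curation
accuracy metric is integer-rounded percent (floor(x+0.5), avoiding
banker's rounding): 948/990 → 96.

## Knowledge graph

Mapping rules are R2RML-inspired declarative data (source kind, subject
IRI template, predicate, object spec) without a SQL layer; one rule emits
at most one quad per source row, and rules referencing unknown columns
fail loudly naming the rule. IRIs are minted deterministically: compounds
by CAS when present, else the slugged name; studies by compound + study
id; observations by compound + parameter + direction.

Provenance is named-graph separation: dataset-derived quads in
`internal`, the loaded ontology in `ontology`, label-match links in
`external_links`, reasoning output in `inferred`. The `ontology` graph is
an addition to the three dataset-facing graphs so competency queries can
traverse fixture quads in-store; the separation invariant (no link or
inference predicate inside `internal`) is checked on demand and in tests.
Serialization is TriG and N-Quads, the latter line-sorted for diffable
output; both round-trip the quad set exactly.

`sameAs` linking matches rdfs:labels case-insensitively with collapsed
whitespace; ambiguous multi-matches are all emitted with a warning
(linking errors are treated as noncritical and are auditable in the
separate graph). The bridge from findings to ontology effect tokens is a
small alignment table — e.g. (ALP, increase) → `increased-ALP`,
(GGT, increase) → `GGT-presence` — with generated tokens for unaligned
combinations.

"Is affected by" inference counts effect tokens shared between a test
subject's observations and each disease/toxic-process profile, where a
subtype inherits its ancestors' effects through the is_a closure. The
count is annotated on the link as likelihood evidence. Counting is at the
level of the opinion's test subject (the compound in the packaged corpus,
where subjects and opinions are 1:1); study-level aggregation is a noted
variant, not implemented. `min_shared` defaults to 2 — a single shared
generic effect (e.g. "increased cholesterol" alone) is weak evidence —
and is exposed as a parameter and CLI flag.

The worked cholestasis case links one hair dye's three observations
(increased ALP, presence of GGT, hepatocellular necrosis) to cholestasis
at shared count 3. The necrosis observation comes from the underlying
study's histopathology and ships as a separate case-study CSV because the
overview table's necrosis cell for that compound is empty;
`load_kg_dataset()` merges the two.

## Synthetic data

The study generator emulates guideline-conformant 90-day (and acute) oral
studies as a curator would enter them: every checklist question answerable
from structured fields, gavage dosing with a 0/50/150/450 mg/kg bw/day
design, rodent test system, concurrent control and recovery groups. It is
seeded and byte-reproducible; `completeness` thins fields drawn from an
explicit defect menu, enabling targeted failure cases (omit `species` →
red II.1 fails → revised category 3). What it does not emulate: narrative
free text, inter-curator variation, partial tables, non-OECD designs —
so green scoring tests demonstrate the rule engine's correctness on
structured records, not robustness to messy real-world opinions.

The corpus fixture names the 53 ingredients with liver findings; the
remaining 35 of the 88-ingredient corpus are placeholder records, clearly
flagged and effect-free, present only so category totals are testable.

## Numerical and procedural choices

- Thresholds 18/13, the ≥ 0.5 Dice rule and the 948/990 accuracy example
  are fixed inputs of the domain, not tunables.
- Percentages round half-up to integers; Dice is exact rational
  arithmetic on set sizes.
- Ordering is deterministic everywhere a list is returned: hits by
  ingredient name, alerts by (−similarity, name), q1 by (−shared count,
  label, IRI), N-Quads lexicographic.
- Fixture CSV/Turtle files carry sha256 checksums verified at load.
- Problem sizes in tests and the reproduction script are the natural ones
  for the packaged corpus (53 compounds, 135 findings, 22 sums × 256 red
  patterns, 20 synthetic studies) — small enough to run exhaustively.

## Known limitations

- The scorer sees only structured fields; information buried in narrative
  (sex of animals, purity stated once under physico-chemical properties)
  scores 0 unless curated into fields.
- The alert-assignment path uses caller-supplied profile fixtures; no
  live profiler service is wired in.
- The ontology fixture is a ~30-node miniature scoped to the shipped
  worked examples; the loader accepts richer Turtle files of the same
  vocabulary, but no full external ontology import ships with the
  package.
- Mapping rules are R2RML-inspired, not spec-conformant R2RML.
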