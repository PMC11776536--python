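"""Packaged datasets and a seeded synthetic-study generator.

Ships, as plain-text package data with recorded checksums:

* the 53-ingredient liver-toxicant overview (compounds + effect entries
  with directions and qualifier flags),
* the corpus category counts (62 hair dyes, 9 preservatives/disinfectants,
  5 UV filters, 2 fragrances, 2 solvents, 4 multiple-use, 4 other = 88),
* the single-compound case-study observation set used in the cholestasis
  linkage example,
* the miniature hepatotoxicity ontology (Turtle).

Ingredients beyond the 53 named ones are placeholder records
(``is_placeholder=True``, no effect entries): they keep corpus-level counts
testable without fabricating findings.

The generator produces guideline-conformant synthetic study records:
``completeness=1`` yields fully evidenced records (checklist sum 21);
lower completeness omits fields from a defect menu, enabling targeted
red-question failure cases.
"""

from __future__ import annotations

import hashlib
import json
import random
import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConfigError, IngestError
from .ingest import Dataset
from .liver_filter import EffectEntry, default_lexicon
from .study_model import CompoundRecord, ReliabilityBlock, StudyRecord

_DATA = resources.files("toxinkg") / "data"

CHECKSUMMED_FILES = (
    "table2_compounds.csv",
    "table2_effects.csv",
    "corpus_categories.csv",
    "case_study_observations.csv",
    "mini_ontology.ttl",
)

#: the documented qualifier-exclusion policy under which the packaged
#: overview reproduces the reference count of 18 ALT-affecting ingredients
#: (see data/README.md; the default query policy excludes nothing)
ALT_REFERENCE_EXCLUSIONS = frozenset({"sccs_conclusion_only"})


def _read_data(name: str, verify: bool = True) -> str:
    text = (_DATA / name).read_text()
    if verify:
        expected = _checksums().get(name)
        digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
        if expected is not None and digest != expected:
            raise IngestError(f"fixture {name} failed its checksum (got {digest})")
    return text


def _checksums() -> dict[str, str]:
    return json.loads((_DATA / "checksums.json").read_text())


def _effects_from_csv(text: str) -> list[EffectEntry]:
    lexicon = default_lexicon()
    frame = pd.read_csv(pd.io.common.StringIO(text), dtype=str, keep_default_na=False)
    entries = []
    for row in frame.to_dict("records"):
        canonical = lexicon.normalize_parameter(row["parameter"])
        if canonical is None:
            raise IngestError(f"fixture effect parameter {row['parameter']!r} unknown")
        entries.append(
            EffectEntry(
                compound_id=row["compound_id"],
                parameter=canonical,
                direction=row["direction"],
                qualifiers=frozenset(
                    q for q in row.get("qualifiers", "").split(";") if q
                ),
                source=row.get("source", ""),
            )
        )
    return entries


def _compounds_from_csv(text: str) -> list[CompoundRecord]:
    frame = pd.read_csv(pd.io.common.StringIO(text), dtype=str, keep_default_na=False)
    return [
        CompoundRecord(
            compound_id=row["compound_id"],
            ingredient_name=row["ingredient_name"],
            inci_name=row.get("inci_name", ""),
            cas_number=row.get("cas_number", ""),
            ec_number=row.get("ec_number", ""),
            smiles=row.get("smiles", ""),
            use_category=row.get("use_category", "other"),
            function=row.get("function", ""),
            is_polymer=row.get("is_polymer", "") == "true",
            is_placeholder=row.get("is_placeholder", "") == "true",
        )
        for row in frame.to_dict("records")
    ]


def load_table2() -> Dataset:
    """The packaged liver-toxicant overview: 53 compounds, each with at
    least one effect entry."""
    return Dataset(
        compounds=_compounds_from_csv(_read_data("table2_compounds.csv")),
        effects=_effects_from_csv(_read_data("table2_effects.csv")),
    )


def load_case_study_observations() -> list[EffectEntry]:
    """Histopathology observation(s) from the worked cholestasis case
    (hepatocellular necrosis for Basic Red 51), kept separate from the
    overview table they complement."""
    return _effects_from_csv(_read_data("case_study_observations.csv"))


def load_kg_dataset() -> Dataset:
    """Overview dataset plus the case-study observations — the input used
    for knowledge-graph construction and linkage examples."""
    ds = load_table2()
    ds.effects = ds.effects + load_case_study_observations()
    return ds


@dataclass
class CorpusMetadata:
    category_counts: dict[str, int]
    compounds: list[CompoundRecord]

    @property
    def total(self) -> int:
        return sum(self.category_counts.values())


def load_corpus_metadata() -> CorpusMetadata:
    """Per-category ingredient counts plus a name list: the 53 named
    ingredients and clearly flagged placeholder stand-ins for the rest."""
    frame = pd.read_csv(
        pd.io.common.StringIO(_read_data("corpus_categories.csv")),
        dtype={"use_category": str, "count": int},
    )
    counts = dict(zip(frame["use_category"], frame["count"]))
    named = _compounds_from_csv(_read_data("table2_compounds.csv"))
    per_cat: dict[str, int] = {}
    for compound in named:
        per_cat[compound.use_category] = per_cat.get(compound.use_category, 0) + 1
    compounds = list(named)
    for category, target in counts.items():
        have = per_cat.get(category, 0)
        if have > target:
            raise IngestError(
                f"category {category!r}: {have} named ingredients exceed the "
                f"recorded count {target}"
            )
        slug = category.replace("/", "-").replace(" ", "-").lower()
        for i in range(target - have):
            compounds.append(
                CompoundRecord(
                    compound_id=f"placeholder-{slug}-{i + 1:02d}",
                    ingredient_name=f"Placeholder {category} ingredient {i + 1:02d}",
                    use_category=category,
                    function="synthetic stand-in (no findings)",
                    is_placeholder=True,
                )
            )
    return CorpusMetadata(category_counts=counts, compounds=compounds)


def export_fixtures(out_dir: str | Path) -> list[str]:
    """Copy the packaged fixture files into *out_dir*; returns the names."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = [*CHECKSUMMED_FILES, "checksums.json", "README.md"]
    for name in names:
        with resources.as_file(_DATA / name) as src:
            shutil.copy(src, out / name)
    return names


# -- synthetic study generator ------------------------------------------

#: short defect names -> profile paths (targeted omissions for scoring tests)
DEFECT_PATHS = {
    "species": "Test method/Test animal/species",
    "sex": "Test method/Test animal/sex",
    "strain": "Test method/Test animal/strain",
    "purity": "Test method/Test substance/purity",
    "identification": "Test method/Test substance/test substance identification",
    "route": "Test method/Test condition/oral administration",
    "dose levels": "Test method/Test condition/dose levels",
    "duration of exposure": "Test method/Test condition/duration of exposure",
    "administration scheme": "Test method/Test condition/repeated administration scheme",
    "homogeneity and stability": "Test method/Test substance/homogeneity and stability",
    "dose volume": "Test method/Test condition/dose-volume ml\\/kg bw",
    "animals per group": "Test method/Test animal/number of animals per group",
    "statistical methods": "Documentation/statistical methods",
}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_studies: int = 10
    completeness: float = 1.0
    guideline_mix: dict[str, float] = field(default_factory=lambda: {"OECD_408": 1.0})
    defect_menu: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.completeness <= 1.0:
            raise ConfigError(f"completeness {self.completeness} outside [0, 1]")
        if self.n_studies < 0:
            raise ConfigError("n_studies must be non-negative")
        for name in self.defect_menu:
            if name not in DEFECT_PATHS and "/" not in name:
                raise ConfigError(f"unknown defect {name!r}")


_FULL_FIELDS_408 = {
    "Test method/Test substance/test substance identification": "synthetic ingredient",
    "Test method/Test substance/purity": ">= 98%",
    "Test method/Test substance/source of test substance": "supplied by sponsor",
    "Test method/Test substance/physico-chemical properties": "white powder; log Pow 1.2",
    "Test method/Test substance/batch number": "B-001",
    "Test method/Test substance/homogeneity and stability": "verified in vehicle",
    "Test method/Test condition/oral administration": "gavage",
    "Test method/Test condition/dose-volume ml\\/kg bw": "10",
    "Test method/Test condition/dose levels": "0; 50; 150; 450",
    "Test method/Test condition/repeated administration scheme": "7 days/week",
    "Test method/Test condition/duration of exposure": "90 days",
    "Test method/Test condition/time-points of observations": "weekly",
    "Test method/Test condition/vehicle": "corn oil",
    "Test method/Test animal/species": "rat",
    "Test method/Test animal/sex": "male and female",
    "Test method/Test animal/strain": "Wistar",
    "Test method/Test animal/age value": "6",
    "Test method/Test animal/age unit": "weeks",
    "Test method/Test animal/body weight": "120-140 g",
    "Test method/Test animal/number of animals per group": "10",
    "Test method/Test animal/housing and feeding conditions": "standard housing, ad libitum diet",
    "Results/Clinical observations/clinical and functional observations": "no treatment-related findings",
    "Results/Clinical observations/moribund or dead animals prior to study termination": "NO",
    "Results/Clinical observations/mortality rate": "0%",
    "Results/Hematology/hematology findings": "unremarkable",
    "Results/Clinical biochemistry/Hepatocellular effect/alt": "within control range",
    "Results/Clinical biochemistry/Hepatocellular effect/ast": "within control range",
    "Results/Pathology/necropsy findings": "no gross lesions",
    "Results/Pathology/histopathology findings": "no treatment-related lesions",
    "Results/Pathology/organ weights": "liver weight unchanged at all doses",
    "Documentation/study endpoints and methods": "per guideline protocol",
    "Documentation/statistical methods": "ANOVA with Dunnett post hoc",
}

# paths absent from the acute profile tree are dropped automatically
_FULL_FIELDS_401 = {
    path: value
    for path, value in _FULL_FIELDS_408.items()
    if "repeated administration scheme" not in path
    and "housing and feeding" not in path
    and "Hematology" not in path
    and "Hepatocellular" not in path
    and "organ weights" not in path
}
_FULL_FIELDS_401["Test method/Test condition/duration of exposure"] = (
    "single administration, 14-day observation"
)

_FIELD_SETS = {"OECD_408": _FULL_FIELDS_408, "OECD_401": _FULL_FIELDS_401}


def generate_studies(cfg: GeneratorConfig) -> list[StudyRecord]:
    """Seeded, reproducible synthetic study records (same config -> same
    output)."""
    rng = random.Random(cfg.seed)
    guidelines = sorted(cfg.guideline_mix)
    weights = [cfg.guideline_mix[g] for g in guidelines]
    menu_paths = [DEFECT_PATHS.get(name, name) for name in cfg.defect_menu]

    records: list[StudyRecord] = []
    for i in range(cfg.n_studies):
        guideline = rng.choices(guidelines, weights=weights, k=1)[0]
        base = _FIELD_SETS.get(guideline, _FULL_FIELDS_408)
        fields = dict(base)
        for path in menu_paths:
            if cfg.completeness < 1.0 and rng.random() >= cfg.completeness:
                fields.pop(path, None)
        records.append(
            StudyRecord(
                study_id=f"SYN-{cfg.seed}-{i + 1:03d}",
                compound_id=f"synthetic-compound-{i + 1:03d}",
                guideline_id=guideline,
                fields=fields,
                provenance={path: "paper" for path in fields},
                reliability=ReliabilityBlock(
                    study_year=1995 + rng.randrange(25),
                    glp_status=True,
                    ref_in_dossier=f"ref {i + 1}",
                    control_recovery_group="concurrent control and recovery groups",
                ),
            )
        )
    return records
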