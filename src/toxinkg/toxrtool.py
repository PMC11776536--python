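"""Automated reliability scoring of OECD-compliant toxicity studies.

Implements the EURL ECVAM ToxRTool checklist — 21 questions in five criteria
groups, each scored 0/1 — and maps the resulting sum onto Klimisch
categories: sum >= 18 -> category 1, 13..17 -> 2, < 13 -> 3.  "Red"
questions are mandatory: a study failing any applicable red question cannot
be category 1 or 2.  Because the literature also describes a softer revision
("category 2 or 3, depending on the sum"), both readings are available via
``red_fail_policy``:

* ``"three"`` (default): any red failure revises the category to 3.
* ``"sum_capped_two"``: a red failure caps the category at 2 (i.e. the
  revised category is max(initial, 2)).

Answers are derived from structured fields only; evidence buried in
free-text narrative is never mined (a question without a structured field
scores 0).  Guideline defaults (e.g. a 90-day study's "7 days/week"
administration scheme) may fill omitted scheme fields; answers derived from
defaults are flagged so the provenance stays visible.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import ContractError, NotScorableError, PathResolutionError
from .study_model import (
    GuidelineProfile,
    ProfileRegistry,
    StudyRecord,
    ValueProperty,
)

GROUPS = ("I", "II", "III", "IV", "V")
RED_FAIL_POLICIES = ("three", "sum_capped_two")

_CONTROL_BLOCK_PATH = "Reliability/control group & recovery group"


@dataclass(frozen=True)
class Question:
    """One checklist question with its evidence-derivation rule."""

    id: str
    group: str
    text: str
    red: bool
    rule: str
    paths: tuple[str, ...]
    applies_to: str = "all"  # all | repeated_dose_only | inhalation_or_repeated_dose

    @property
    def weight_class(self) -> str:
        return "red" if self.red else "normal"

    def applicable(self, study_kind: str, route: str | None = None) -> bool:
        if self.applies_to == "repeated_dose_only":
            return study_kind == "repeated_dose"
        if self.applies_to == "inhalation_or_repeated_dose":
            return study_kind == "repeated_dose" or route == "inhalation"
        return True


@dataclass
class QuestionAnswer:
    question_id: str
    score: int
    evidence_paths: list[str] = field(default_factory=list)
    used_default: bool = False
    note: str = ""

    def to_json_dict(self) -> dict:
        return {
            "id": self.question_id,
            "score": self.score,
            "evidence": list(self.evidence_paths),
            "used_default": self.used_default,
            "note": self.note,
        }


@dataclass
class ReliabilityResult:
    study_id: str
    answers: list[QuestionAnswer]
    sum: int
    initial_category: int
    revised_category: int
    defaults_applied: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "sum": self.sum,
            "initial": self.initial_category,
            "revised": self.revised_category,
            "defaults_applied": list(self.defaults_applied),
            "answers": [a.to_json_dict() for a in self.answers],
        }


class Rulebook:
    """The declarative question -> evidence-paths mapping, shipped as data."""

    def __init__(self, questions: list[Question]):
        self.questions = list(questions)
        self.by_id = {q.id: q for q in self.questions}
        counts = {g: sum(1 for q in self.questions if q.group == g) for g in GROUPS}
        expected = {"I": 4, "II": 5, "III": 7, "IV": 3, "V": 2}
        if counts != expected:
            raise ContractError(f"rulebook question counts {counts} != {expected}")

    @classmethod
    def from_dict(cls, data: dict) -> "Rulebook":
        questions = [
            Question(
                id=q["id"],
                group=q["group"],
                text=q["text"].strip(),
                red=bool(q["red"]),
                rule=q["rule"],
                paths=tuple(q.get("paths", ())),
                applies_to=q.get("applies_to", "all"),
            )
            for q in data["questions"]
        ]
        return cls(questions)

    @classmethod
    def builtin(cls) -> "Rulebook":
        text = (resources.files("toxinkg") / "data" / "rulebook.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    def red_ids(self) -> list[str]:
        return [q.id for q in self.questions if q.red]


# -- evidence helpers ----------------------------------------------------


def _resolved_property(profile: GuidelineProfile, path: str) -> str | None:
    """Canonical path if *path* names a value property of *profile*, else None."""
    try:
        node = profile.resolve(path)
    except PathResolutionError:
        return None
    return profile.canonical_path(path) if isinstance(node, ValueProperty) else None

def _value(study: StudyRecord, canonical: str):
    value = study.get(canonical)
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    return value


def _dose_levels_include_zero(text_value) -> bool:
    tokens = re.split(r"[;,]", str(text_value))
    for tok in tokens:
        m = re.search(r"-?\d+(?:\.\d+)?", tok)
        if m and float(m.group()) == 0.0:
            return True
    return False


def apply_defaults(
    study: StudyRecord, profile: GuidelineProfile
) -> tuple[StudyRecord, list[str]]:
    """Return a copy of *study* with the profile's defaults filled in.

    Only paths absent from the record are filled; added values carry
    provenance ``"default"``.
    """
    out = copy.deepcopy(study)
    applied: list[str] = []
    for path, value in profile.defaults.items():
        canonical = profile.canonical_path(path)
        if _value(out, canonical) is None:
            out.fields[canonical] = value
            out.provenance[canonical] = "default"
            applied.append(canonical)
    return out, sorted(applied)


# -- answer derivation ---------------------------------------------------


def derive_answers(
    study: StudyRecord,
    profile: GuidelineProfile,
    rulebook: Rulebook | None = None,
) -> list[QuestionAnswer]:
    """Derive one 0/1 answer per applicable checklist question.

    Assumes defaults have already been applied if wanted (see
    :func:`apply_defaults`); answers resting on default-provenance fields
    are flagged ``used_default``.
    """
    if not study.is_oecd:
        raise NotScorableError(
            f"study {study.study_id!r}: automated scoring covers OECD-compliant "
            "studies only"
        )
    rulebook = rulebook or Rulebook.builtin()
    route_path = _resolved_property(profile, "Test method/Test condition/oral administration")
    route = str(_value(study, route_path)) if route_path and _value(study, route_path) else None

    answers: list[QuestionAnswer] = []
    for question in rulebook.questions:
        if not question.applicable(profile.study_kind, route):
            continue
        answers.append(_answer(question, study, profile, route))
    return answers


def _answer(
    question: Question, study: StudyRecord, profile: GuidelineProfile, route: str | None
) -> QuestionAnswer:
    canonical = [
        c for c in (_resolved_property(profile, p) for p in question.paths) if c
    ]
    present = [c for c in canonical if _value(study, c) is not None]
    used_default = any(study.provenance.get(c) == "default" for c in present)

    if question.rule == "any":
        score = 1 if present else 0
        return QuestionAnswer(question.id, score, present, used_default)

    if question.rule == "all":
        score = 1 if canonical and len(present) == len(canonical) else 0
        return QuestionAnswer(question.id, score, present, used_default)

    if question.rule == "controls":
        block = study.reliability.control_recovery_group
        if block:
            return QuestionAnswer(
                question.id, 1, [_CONTROL_BLOCK_PATH], False,
                "control & recovery group data present",
            )
        if present and _dose_levels_include_zero(_value(study, present[0])):
            return QuestionAnswer(
                question.id, 1, present, used_default,
                'dose levels include a "0" dose (negative control)',
            )
        return QuestionAnswer(question.id, 0, present, used_default)

    if question.rule == "administration_scheme":
        homog = _resolved_property(
            profile, "Test method/Test substance/homogeneity and stability"
        )
        volume = _resolved_property(
            profile, "Test method/Test condition/dose-volume ml\\/kg bw"
        )
        homog_ok = homog is not None and _value(study, homog) is not None
        volume_ok = volume is not None and _value(study, volume) is not None
        evidence = [p for p, ok in ((homog, homog_ok), (volume, volume_ok)) if ok]
        dflt = any(study.provenance.get(c) == "default" for c in evidence)
        if route == "gavage":
            score = 1 if (homog_ok or volume_ok) else 0
            note = "gavage route: homogeneity/stability or dose-volume accepted"
        elif route in ("diet", "drinking water"):
            score = 1 if homog_ok else 0
            evidence = [homog] if homog_ok else []
            note = f"{route} route: homogeneity and stability required"
        else:
            score, evidence, note = 0, [], "administration route not given"
        return QuestionAnswer(question.id, score, evidence, dflt, note)

    if question.rule == "oecd_compliance":
        return QuestionAnswer(
            question.id, 1, [], False,
            f"design follows registered guideline {study.guideline_id}",
        )

    raise ContractError(f"unknown rule {question.rule!r} for question {question.id}")


# -- category assignment -------------------------------------------------


def initial_category(total: int) -> int:
    """Map a checklist sum to the initial Klimisch category (>=18 -> 1,
    13..17 -> 2, <13 -> 3)."""
    if not isinstance(total, int) or not 0 <= total <= 21:
        raise ContractError(f"sum must be an integer in 0..21, got {total!r}")
    if total >= 18:
        return 1
    if total >= 13:
        return 2
    return 3


def revise_category(
    answers: list[QuestionAnswer],
    initial: int,
    rulebook: Rulebook | None = None,
    red_fail_policy: str = "three",
) -> int:
    """Apply the mandatory-question revision to the initial category.

    All applicable red questions scored 1 -> the initial category stands.
    Any red failure forbids categories 1 and 2 (policy ``"three"``), or caps
    the category at 2 (policy ``"sum_capped_two"``).
    """
    if red_fail_policy not in RED_FAIL_POLICIES:
        raise ContractError(f"unknown red_fail_policy {red_fail_policy!r}")
    rulebook = rulebook or Rulebook.builtin()
    red_failed = any(
        a.score == 0 for a in answers if rulebook.by_id[a.question_id].red
    )
    if not red_failed:
        return initial
    return 3 if red_fail_policy == "three" else max(initial, 2)


def score_study(
    study: StudyRecord,
    profiles: GuidelineProfile | ProfileRegistry | None = None,
    rulebook: Rulebook | None = None,
    use_defaults: bool = True,
    red_fail_policy: str = "three",
) -> ReliabilityResult:
    """Answer derivation + threshold mapping + red-question revision."""
    if profiles is None:
        profiles = ProfileRegistry.builtin()
    if isinstance(profiles, ProfileRegistry):
        profile = profiles.get(study.guideline_id)
        if profile is None:
            raise NotScorableError(
                f"study {study.study_id!r}: guideline {study.guideline_id!r} "
                "is not registered"
            )
    else:
        profile = profiles
    rulebook = rulebook or Rulebook.builtin()

    defaults_applied: list[str] = []
    if use_defaults:
        study, defaults_applied = apply_defaults(study, profile)

    answers = derive_answers(study, profile, rulebook)
    total = sum(a.score for a in answers)
    initial = initial_category(total)
    revised = revise_category(answers, initial, rulebook, red_fail_policy)
    return ReliabilityResult(
        study_id=study.study_id,
        answers=answers,
        sum=total,
        initial_category=initial,
        revised_category=revised,
        defaults_applied=defaults_applied,
    )
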