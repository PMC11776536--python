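"""Reliability scoring: answer derivation, thresholds, red-question revision."""

import copy
import itertools

import pytest

from toxinkg.errors import ContractError, NotScorableError
from toxinkg.fixtures import GeneratorConfig, generate_studies
from toxinkg.study_model import ReliabilityBlock, StudyRecord
from toxinkg.toxrtool import (
    QuestionAnswer,
    Rulebook,
    apply_defaults,
    derive_answers,
    initial_category,
    revise_category,
    score_study,
)

RED_IDS = ["I.1", "II.1", "III.1", "III.2", "III.3", "III.4", "III.5", "V.1"]


def _answers(rulebook, red_pattern, normal_passes):
    """Construct a full 21-answer list with the given red scores and number
    of passing normal questions."""
    reds = dict(zip(RED_IDS, red_pattern))
    answers, normals_left = [], normal_passes
    for question in rulebook.questions:
        if question.red:
            score = reds[question.id]
        else:
            score = 1 if normals_left > 0 else 0
            normals_left -= 1 if score else 0
        answers.append(QuestionAnswer(question.id, score))
    return answers


class TestRulebookStructure:
    def test_twenty_one_questions_in_expected_groups(self, rulebook):
        counts = {}
        for question in rulebook.questions:
            counts[question.group] = counts.get(question.group, 0) + 1
        assert counts == {"I": 4, "II": 5, "III": 7, "IV": 3, "V": 2}

    def test_red_set_is_the_mandatory_eight(self, rulebook):
        assert rulebook.red_ids() == sorted(RED_IDS)


class TestInitialCategory:
    @pytest.mark.parametrize("total,expected", [(18, 1), (21, 1), (13, 2),
                                                (17, 2), (12, 3), (0, 3)])
    def test_printed_thresholds(self, total, expected):
        assert initial_category(total) == expected

    def test_exhaustive_against_enumerated_rule(self):
        for total in range(22):
            if total >= 18:
                expected = 1
            elif total >= 13:
                expected = 2
            else:
                expected = 3
            assert initial_category(total) == expected

    @pytest.mark.parametrize("bad", [-1, 22, 3.5])
    def test_out_of_range_sum_is_a_contract_error(self, bad):
        with pytest.raises(ContractError):
            initial_category(bad)


class TestReviseCategory:
    def test_all_reds_pass_keeps_initial(self, rulebook):
        answers = _answers(rulebook, [1] * 8, 12)  # sum 20
        assert revise_category(answers, 1, rulebook) == 1

    def test_red_failure_default_policy_forbids_one_and_two(self, rulebook):
        answers = _answers(rulebook, [0] + [1] * 7, 13)  # sum 20, one red failed
        assert revise_category(answers, 1, rulebook, "three") == 3

    def test_red_failure_alternative_policy_caps_at_two(self, rulebook):
        answers = _answers(rulebook, [0] + [1] * 7, 13)
        assert revise_category(answers, 1, rulebook, "sum_capped_two") == 2

    def test_exhaustive_red_patterns_against_brute_force(self, rulebook):
        """All 2^8 red patterns x feasible normal-pass counts, both policies,
        compared with a direct enumeration of the stated rules."""
        for red_pattern in itertools.product([0, 1], repeat=8):
            for normal_passes in range(14):
                answers = _answers(rulebook, red_pattern, normal_passes)
                total = sum(a.score for a in answers)
                assert total == sum(red_pattern) + normal_passes
                initial = initial_category(total)
                red_failed = 0 in red_pattern
                # independent enumeration of both stated readings
                if not red_failed:
                    expected_three = expected_capped = initial
                else:
                    expected_three = 3
                    expected_capped = 2 if total >= 13 else 3
                assert revise_category(answers, initial, rulebook, "three") == expected_three
                assert revise_category(answers, initial, rulebook, "sum_capped_two") == expected_capped

    def test_revised_never_better_than_initial(self, rulebook):
        for red_pattern in [(1,) * 8, (0,) + (1,) * 7, (0,) * 8]:
            for normal_passes in (0, 7, 13):
                answers = _answers(rulebook, red_pattern, normal_passes)
                initial = initial_category(sum(a.score for a in answers))
                for policy in ("three", "sum_capped_two"):
                    assert revise_category(answers, initial, rulebook, policy) >= initial


class TestDeriveAnswers:
    def _get(self, answers, qid):
        return next(a for a in answers if a.question_id == qid)

    def test_gavage_with_dose_volume_but_no_homogeneity(self, profile_408,
                                                        rulebook, complete_study):
        study = copy.deepcopy(complete_study)
        del study.fields["Test method/Test substance/homogeneity and stability"]
        answers = derive_answers(study, profile_408, rulebook)
        assert self._get(answers, "III.6").score == 1

    def test_dietary_study_lacking_homogeneity_scores_zero(self, profile_408,
                                                           rulebook, complete_study):
        study = copy.deepcopy(complete_study)
        study.fields["Test method/Test condition/oral administration"] = "diet"
        del study.fields["Test method/Test substance/homogeneity and stability"]
        answers = derive_answers(study, profile_408, rulebook)
        assert self._get(answers, "III.6").score == 0

    def test_dietary_study_with_homogeneity_scores_one(self, profile_408,
                                                       rulebook, complete_study):
        study = copy.deepcopy(complete_study)
        study.fields["Test method/Test condition/oral administration"] = "diet"
        answers = derive_answers(study, profile_408, rulebook)
        assert self._get(answers, "III.6").score == 1

    def test_zero_dose_level_counts_as_negative_control(self, profile_408, rulebook):
        study = StudyRecord(
            study_id="s", compound_id="c", guideline_id="OECD_408",
            fields={"Test method/Test condition/dose levels": "0; 50; 150; 450"},
        )
        answers = derive_answers(study, profile_408, rulebook)
        assert self._get(answers, "III.4").score == 1

    def test_control_block_satisfies_controls_question(self, profile_408, rulebook):
        study = StudyRecord(
            study_id="s", compound_id="c", guideline_id="OECD_408",
            reliability=ReliabilityBlock(control_recovery_group="present"),
        )
        answers = derive_answers(study, profile_408, rulebook)
        assert self._get(answers, "III.4").score == 1

    def test_no_controls_evidence_scores_zero(self, profile_408, rulebook):
        study = StudyRecord(
            study_id="s", compound_id="c", guideline_id="OECD_408",
            fields={"Test method/Test condition/dose levels": "50; 150; 450"},
        )
        answers = derive_answers(study, profile_408, rulebook)
        assert self._get(answers, "III.4").score == 0

    def test_missing_duration_satisfied_by_default(self, profile_408, rulebook,
                                                   complete_study):
        study = copy.deepcopy(complete_study)
        del study.fields["Test method/Test condition/duration of exposure"]
        study, applied = apply_defaults(study, profile_408)
        assert "Test method/Test condition/duration of exposure" in applied
        answers = derive_answers(study, profile_408, rulebook)
        iii3 = self._get(answers, "III.3")
        assert iii3.score == 1 and iii3.used_default

    def test_non_oecd_study_is_not_scorable(self, profile_408, rulebook):
        study = StudyRecord(study_id="s", compound_id="c", guideline_id="non-OECD")
        with pytest.raises(NotScorableError):
            derive_answers(study, profile_408, rulebook)

    def test_acute_studies_skip_repeated_dose_questions(self, profile_401,
                                                        rulebook, complete_study):
        study = copy.deepcopy(complete_study)
        study.guideline_id = "OECD_401"
        answers = derive_answers(study, profile_401, rulebook)
        ids = {a.question_id for a in answers}
        assert "II.5" not in ids and "III.7" not in ids
        assert len(answers) == 19


class TestScoreStudy:
    def test_fully_specified_study_is_category_one(self, registry, complete_study):
        result = score_study(complete_study, registry)
        assert (result.sum, result.initial_category, result.revised_category) == (21, 1, 1)

    def test_category_two_constructed_by_hand_count(self, registry, complete_study):
        """Strip normal-question evidence until exactly 13 questions pass
        (all reds intact): initial and revised category 2."""
        study = copy.deepcopy(complete_study)
        for path in [
            "Test method/Test substance/purity",
            "Test method/Test substance/source of test substance",
            "Test method/Test substance/physico-chemical properties",
            "Test method/Test animal/sex",
            "Test method/Test animal/strain",
            "Test method/Test animal/age value",
            "Test method/Test animal/body weight",
            "Test method/Test animal/housing and feeding conditions",
            "Documentation/statistical methods",
        ]:
            del study.fields[path]
        # II.4 loses both age and body weight (one question); I.2-I.4,
        # II.2, II.3, II.5 and IV.3 lose their only evidence:
        # 8 normal questions fail -> sum 13, all reds intact
        result = score_study(study, registry)
        assert result.sum == 13
        assert (result.initial_category, result.revised_category) == (2, 2)

    def test_missing_species_fails_red_and_revises_to_three(self, registry):
        (study,) = generate_studies(
            GeneratorConfig(seed=5, n_studies=1, completeness=0.0,
                            defect_menu=["species"])
        )
        result = score_study(study, registry)
        assert result.sum == 20
        assert result.initial_category == 1
        assert result.revised_category == 3

    def test_determinism(self, registry, complete_study):
        first = score_study(complete_study, registry)
        second = score_study(complete_study, registry)
        assert first.to_json_dict() == second.to_json_dict()

    def test_defaults_only_ever_add_evidence(self, registry):
        cfg = GeneratorConfig(
            seed=7, n_studies=6, completeness=0.4,
            defect_menu=["duration of exposure", "administration scheme",
                         "purity", "sex"],
        )
        for study in generate_studies(cfg):
            with_defaults = score_study(study, registry, use_defaults=True)
            without = score_study(study, registry, use_defaults=False)
            assert without.sum <= with_defaults.sum

    def test_flipping_any_answer_up_never_worsens_categories(self, rulebook):
        """Monotonicity over constructed answer sets: raising one answer
        0 -> 1 never increases either category number."""
        for red_pattern in [(1,) * 8, (0,) + (1,) * 7, (1, 0) * 4]:
            for normal_passes in (3, 10, 13):
                answers = _answers(rulebook, red_pattern, normal_passes)
                total = sum(a.score for a in answers)
                base_initial = initial_category(total)
                base_revised = revise_category(answers, base_initial, rulebook)
                for i, answer in enumerate(answers):
                    if answer.score == 1:
                        continue
                    flipped = copy.deepcopy(answers)
                    flipped[i].score = 1
                    new_initial = initial_category(total + 1)
                    new_revised = revise_category(flipped, new_initial, rulebook)
                    assert new_initial <= base_initial
                    assert new_revised <= base_revised
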