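"""Per-source detection, text scanning, adjudication and source attribution."""

from __future__ import annotations

import re

import pandas as pd
import pytest

from conftest import make_bundle
from litcomorbid.errors import AdjudicationError
from litcomorbid.phenotype import (
    PhenotypeCall,
    adjudicate,
    attribute_sources,
    combine_sources,
    detect_drug_cases,
    detect_icd_cases,
    scan_documents,
    text_cases_from_adjudication,
    text_cases_from_matches,
)
from litcomorbid._text import fold_text


def one_patient_bundle(diagnoses=(), prescriptions=(), text=""):
    return make_bundle(
        patients=[("P1", "female", 40, True)],
        encounters=[("P1", "2005-06-01", "gastroenterology", "inpatient")],
        documents=[("P1-D0", "P1", "2005-06-01", text, "letter")] if text else [],
        diagnoses=[("P1", "", c, "2005-06-01") for c in diagnoses],
        prescriptions=[("P1", "2005-06-01", c) for c in prescriptions],
    )


class TestStructuredDetection:
    def test_descendant_code_detected(self, mappings):
        b = one_patient_bundle(diagnoses=["E10.9"])
        assert detect_icd_cases(b, mappings, {"P1"}) == {("P1", "D003922")}

    def test_no_diagnoses_no_detection(self, mappings):
        b = one_patient_bundle()
        assert detect_icd_cases(b, mappings, {"P1"}) == set()

    def test_code_matching_two_diseases_emits_two_pairs(self):
        from litcomorbid.terminology import parse_mapping_config

        m = parse_mapping_config(
            "diseases:\n"
            "  - {dui: D000001, name: A, icd: ['E05*']}\n"
            "  - {dui: D000002, name: B, icd: ['E050']}\n"
        )
        b = one_patient_bundle(diagnoses=["E050"])
        assert detect_icd_cases(b, m, {"P1"}) == {("P1", "D000001"), ("P1", "D000002")}

    def test_insulin_prescription_flags_type1_diabetes(self, mappings):
        b = one_patient_bundle(prescriptions=["A10AB05"])
        assert detect_drug_cases(b, mappings, {"P1"}) == {("P1", "D003922")}

    def test_disease_without_atc_never_drug_detected(self, mappings):
        # dermatitis herpetiformis has no drug marker
        assert not mappings["D003874"].atc
        b = one_patient_bundle(prescriptions=["A10AB05", "H03AA01"])
        duis = {d for _, d in detect_drug_cases(b, mappings, {"P1"})}
        assert "D003874" not in duis

    def test_dates_are_irrelevant_chronic_disease_rule(self, mappings):
        early = one_patient_bundle(diagnoses=["E10.9"])
        late = one_patient_bundle(diagnoses=["E10.9"])
        late.diagnoses["date"] = "2014-12-31"
        assert detect_icd_cases(early, mappings, {"P1"}) == detect_icd_cases(late, mappings, {"P1"})


class TestScanDocuments:
    def test_french_diabetes_mention_found(self, mappings):
        b = one_patient_bundle(text="Suivi pour diabète de type 1 depuis l'enfance.")
        hits = [m for m in scan_documents(b, mappings, {"P1"}) if m.dui == "D003922"]
        assert len(hits) == 1
        assert hits[0].snippet == "diabete"

    def test_empty_document_no_matches(self, mappings):
        b = one_patient_bundle(text="")
        assert scan_documents(b, mappings, {"P1"}) == []

    def test_repeated_term_yields_distinct_spans(self, mappings):
        text = "lupus suspecté puis lupus confirmé"
        b = one_patient_bundle(text=text)
        hits = [m for m in scan_documents(b, mappings, {"P1"}) if m.dui == "D008180"]
        folded, _ = fold_text(text)
        expected = [(m.start(), m.end()) for m in re.finditer(r"\blupus\b", folded)]
        assert sorted(m.span for m in hits) == expected

    def test_snippet_equals_folded_substring_and_orig_span_maps_back(self, mappings):
        text = "Thyroïdite de Hashimoto évoquée."
        b = one_patient_bundle(text=text)
        hits = scan_documents(b, mappings, {"P1"})
        assert hits
        folded, _ = fold_text(text)
        for m in hits:
            assert m.snippet == folded[m.span[0] : m.span[1]]
            o0, o1 = m.orig_span
            assert fold_text(text[o0:o1])[0].lower() == m.snippet.lower()

    def test_fuzzy_matches_single_edit_token(self, mappings):
        # truncated token "thyroidi" is one edit from the pattern literal
        # "thyroidit" and is not caught by the strict regex
        b = one_patient_bundle(text="antecedent de thyroidi")
        hits = [m for m in scan_documents(b, mappings, {"P1"}) if m.dui == "D013967"]
        assert hits and hits[0].pattern_label.endswith("~1")


class TestAdjudication:
    MATCHES = None

    @pytest.fixture()
    def matches(self, mappings):
        b = one_patient_bundle(text="lupus probable")
        return scan_documents(b, mappings, {"P1"})

    def votes(self, v1, v2):
        return pd.DataFrame(
            {
                "patient_id": ["P1", "P1"],
                "dui": ["D008180", "D008180"],
                "reviewer_id": ["r1", "r2"],
                "vote": [v1, v2],
            }
        )

    @pytest.mark.parametrize(
        "v1,v2,policy,expected",
        [
            ("approve", "approve", "consensus", "case"),
            ("reject", "reject", "consensus", "non_case"),
            ("approve", "reject", "consensus", "unresolved"),
            ("approve", "reject", "any_approve", "case"),
            ("reject", "approve", "single_reader", "non_case"),
        ],
    )
    def test_policies(self, matches, v1, v2, policy, expected):
        items = adjudicate(matches, self.votes(v1, v2), policy)
        assert [i.resolution for i in items] == [expected]

    def test_vote_without_match_is_an_error(self, matches):
        votes = pd.DataFrame(
            {"patient_id": ["P1"], "dui": ["D009157"], "reviewer_id": ["r1"], "vote": ["approve"]}
        )
        with pytest.raises(AdjudicationError):
            adjudicate(matches, votes, "consensus")

    def test_unresolved_items_excluded_from_text_cases(self, matches):
        items = adjudicate(matches, self.votes("approve", "reject"), "consensus")
        assert text_cases_from_adjudication(items) == set()
        assert text_cases_from_matches(matches) == {("P1", "D008180")}


class TestCombineAndAttribute:
    def test_sources_reflect_detectors(self):
        calls = combine_sources(
            icd_cases={("P1", "D1")},
            drug_cases={("P1", "D1")},
            text_cases={("P2", "D1")},
            cohort={"P1", "P2", "P3"},
            panel_duis=["D1"],
        )
        by_pid = {c.patient_id: c for c in calls}
        assert by_pid["P1"].sources == {"icd", "drug"} and by_pid["P1"].present
        assert by_pid["P2"].sources == {"text"}
        assert not by_pid["P3"].present and by_pid["P3"].sources == frozenset()

    def test_present_flag_consistency_enforced(self):
        with pytest.raises(ValueError):
            PhenotypeCall("P1", "D1", present=True, sources=frozenset())

    def test_published_type1_diabetes_partition(self):
        """3 text-only, 4 structured-only, 10 both out of 17 gives the
        published 17.6 / 23.5 / 58.8 percent split."""
        calls = (
            [PhenotypeCall(f"T{i}", "D1", True, frozenset({"text"})) for i in range(3)]
            + [PhenotypeCall(f"S{i}", "D1", True, frozenset({"icd"})) for i in range(4)]
            + [PhenotypeCall(f"B{i}", "D1", True, frozenset({"text", "icd"})) for i in range(10)]
        )
        (a,) = attribute_sources(calls)
        assert (a.n_text_only, a.n_structured_only, a.n_both, a.n_total) == (3, 4, 10, 17)
        pt, ps, pb = a.proportions()
        assert (round(pt * 100, 1), round(ps * 100, 1), round(pb * 100, 1)) == (17.6, 23.5, 58.8)

    def test_all_text_only(self):
        calls = [PhenotypeCall(f"P{i}", "D1", True, frozenset({"text"})) for i in range(5)]
        (a,) = attribute_sources(calls)
        assert a.proportions() == (1.0, 0.0, 0.0)

    def test_zero_cases_has_null_proportions(self):
        calls = [PhenotypeCall("P1", "D1", False, frozenset())]
        (a,) = attribute_sources(calls)
        assert a.n_total == 0 and a.proportions() == (None, None, None)

    def test_partition_sums_to_case_count_on_synthetic_run(self, mappings):
        from litcomorbid.synth import default_config, generate_bundle

        bundle, _ = generate_bundle(default_config(seed=5, n_patients=200))
        cohort = set(bundle.patients["patient_id"])
        icd = detect_icd_cases(bundle, mappings, cohort)
        drug = detect_drug_cases(bundle, mappings, cohort)
        text = text_cases_from_matches(scan_documents(bundle, mappings, cohort))
        calls = combine_sources(icd, drug, text, cohort, list(mappings))
        n_cases = {d: sum(1 for c in calls if c.dui == d and c.present) for d in mappings}
        for a in attribute_sources(calls):
            assert a.n_text_only + a.n_structured_only + a.n_both == n_cases[a.dui]

    def test_adding_a_source_never_unmakes_a_case(self):
        base = combine_sources(set(), set(), {("P1", "D1")}, {"P1"}, ["D1"])
        more = combine_sources({("P1", "D1")}, set(), {("P1", "D1")}, {"P1"}, ["D1"])
        assert base[0].present and more[0].present
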