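import dataclasses

import pytest
import yaml

from embryofuse import reporter
from embryofuse.phantom import CLASSES
from embryofuse.reporter import (DuplicateEntryError, IncompleteKBError,
                                 KnowledgeBaseError, generate_report,
                                 load_knowledge, retrieve, validate_report)


def _dump_kb(tmp_path, entries):
    path = tmp_path / "kb.yaml"
    path.write_text(yaml.safe_dump({"entries": entries}))
    return path


def _raw_entries():
    raw = yaml.safe_load(reporter.default_kb_path().read_text())
    return raw["entries"]


class TestLoadKnowledge:
    def test_bundled_kb_has_one_entry_per_class(self, kb):
        assert set(kb) == set(CLASSES)

    def test_missing_stage_rejected(self, tmp_path):
        entries = [e for e in _raw_entries() if e["stage_key"] != "3cells"]
        with pytest.raises(IncompleteKBError):
            load_knowledge(_dump_kb(tmp_path, entries))

    def test_duplicate_stage_rejected(self, tmp_path):
        entries = _raw_entries()
        entries.append(dict(entries[0]))
        with pytest.raises(DuplicateEntryError):
            load_knowledge(_dump_kb(tmp_path, entries))

    def test_typical_forbidden_overlap_rejected(self, tmp_path):
        entries = _raw_entries()
        entries[1]["forbidden_terms"] = list(entries[1]["forbidden_terms"]) + [
            entries[1]["typical_features"][0]]
        with pytest.raises(KnowledgeBaseError):
            load_knowledge(_dump_kb(tmp_path, entries))


class TestRetrieve:
    def test_exact_key_only(self, kb):
        entries = retrieve(kb, "2cells", top_k=1)
        assert len(entries) == 1 and entries[0].stage_key == "2cells"

    def test_no_fabricated_neighbors_without_hook(self, kb):
        assert len(retrieve(kb, "2cells", top_k=3)) == 1

    def test_similarity_hook_appends(self, kb):
        def hook(knowledge, label, k):
            return [knowledge["3cells"], knowledge["4cells"]]

        entries = retrieve(kb, "2cells", top_k=2, similarity_hook=hook)
        assert [e.stage_key for e in entries] == ["2cells", "3cells"]

    def test_unknown_label_fails_closed(self, kb):
        with pytest.raises(KeyError):
            retrieve(kb, "8cells")


class TestGenerateReport:
    def test_three_sections_cite_source_tag(self, kb):
        report = generate_report({"label": "4cells", "probability": 0.97},
                                 retrieve(kb, "4cells"))
        assert report.observation and report.confidence and report.consensus_alignment
        assert kb["4cells"].source_tag in report.consensus_alignment

    @pytest.mark.parametrize("prob,tier", [(0.97, "High"), (0.9, "High"),
                                           (0.85, "Moderate"), (0.7, "Moderate"),
                                           (0.5, "Low")])
    def test_confidence_tiers(self, kb, prob, tier):
        report = generate_report({"label": "1cell", "probability": prob},
                                 retrieve(kb, "1cell"))
        assert report.confidence_tier == tier

    def test_grade_only_when_mapping_configured(self, kb):
        entries = retrieve(kb, "4cells")
        assert generate_report({"label": "4cells", "probability": 0.97}, entries).grade is None
        graded = generate_report({"label": "4cells", "probability": 0.97}, entries,
                                 grade_map=lambda p: "A" if p >= 0.9 else "B")
        assert graded.grade == "A"

    def test_determinism_without_hook(self, kb):
        entries = retrieve(kb, "more")
        a = generate_report({"label": "more", "probability": 0.8}, entries)
        b = generate_report({"label": "more", "probability": 0.8}, entries)
        assert a == b

    def test_empty_entries_and_bad_probability_rejected(self, kb):
        with pytest.raises(ValueError):
            generate_report({"label": "1cell", "probability": 0.9}, [])
        with pytest.raises(ValueError):
            generate_report({"label": "1cell", "probability": 1.4},
                            retrieve(kb, "1cell"))

    def test_observation_vocabulary_is_closed(self, kb):
        for label in CLASSES:
            entry = kb[label]
            report = generate_report({"label": label, "probability": 0.95}, [entry])
            listed = report.observation.split(": ", 1)[1].rstrip(".")
            for feature in listed.split(", "):
                assert feature in entry.typical_features


class TestGuardrail:
    def test_all_classes_generate_clean_reports(self, kb):
        for label in CLASSES:
            report = generate_report({"label": label, "probability": 0.95},
                                     retrieve(kb, label))
            assert validate_report(report, label, kb) == []

    def test_two_cell_report_never_mentions_inner_cell_mass(self, kb):
        report = generate_report({"label": "2cells", "probability": 0.95},
                                 retrieve(kb, "2cells"))
        assert "inner cell mass" not in report.to_text().lower()

    def test_injected_forbidden_term_is_flagged(self, kb):
        report = generate_report({"label": "2cells", "probability": 0.95},
                                 retrieve(kb, "2cells"))
        tampered = dataclasses.replace(
            report, observation=report.observation + " A distinct Inner Cell Mass is visible.")
        assert "forbidden term: inner cell mass" in validate_report(tampered, "2cells", kb)

    def test_word_boundary_matching_avoids_substrings(self, kb):
        report = generate_report({"label": "more", "probability": 0.95},
                                 retrieve(kb, "more"))
        # "more" forbids "polar body"; "bipolar bodywork" must not trip it
        tampered = dataclasses.replace(
            report, observation=report.observation + " bipolar bodywork")
        assert validate_report(tampered, "more", kb) == []

    def test_missing_section_is_flagged(self, kb):
        report = generate_report({"label": "4cells", "probability": 0.5},
                                 retrieve(kb, "4cells"))
        hollow = dataclasses.replace(report, consensus_alignment="")
        assert "missing section: consensus_alignment" in validate_report(hollow, "4cells", kb)

    def test_generator_hook_output_still_validated(self, kb):
        def hallucinating_hook(report, entry):
            return dataclasses.replace(
                report, observation="The inner cell mass looks compact.")

        report = generate_report({"label": "2cells", "probability": 0.95},
                                 retrieve(kb, "2cells"), generator_hook=hallucinating_hook)
        assert validate_report(report, "2cells", kb) == ["forbidden term: inner cell mass"]
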