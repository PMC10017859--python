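"""Record ingestion, schema flattening, dedup and partitioning."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semharm import (
    QuestionRecord,
    ValueKind,
    distinct_questions,
    flatten_json_schema,
    load_question_records,
    partition_records,
)
from semharm.corpus_io import (
    MalformedRowError,
    MissingColumnError,
    SchemaFormatError,
    normalize_text,
)

CSV_HEADER = "form_id,field_path,field_name\n"


class TestLoadRecords:
    def test_single_row_preserves_path_and_name(self):
        src = io.StringIO(CSV_HEADER + 'F1,economic/Education/,What Is The Highest Grade You Have Completed\n')
        (rec,) = load_question_records(src)
        assert rec.field_path == "economic/Education/"
        assert rec.field_name == "What Is The Highest Grade You Have Completed"
        assert rec.form_id == "F1"

    def test_empty_stream_yields_empty_list(self):
        assert load_question_records(io.StringIO("")) == []

    def test_missing_field_name_names_row(self):
        src = io.StringIO(CSV_HEADER + "F1,p/,q1\nF1,p/,\n")
        with pytest.raises(MalformedRowError, match="row 1.*field_name"):
            load_question_records(src)

    def test_missing_mandatory_column_named(self):
        with pytest.raises(MissingColumnError, match="field_name"):
            load_question_records(io.StringIO("form_id,field_path\nF1,p/\n"))

    def test_jsonl_round_trip_order(self, tmp_path):
        lines = "\n".join(
            '{"form_id": "F1", "field_path": "a/", "field_name": "q%d"}' % i for i in range(5)
        )
        recs = load_question_records(io.StringIO(lines))
        assert [r.field_name for r in recs] == [f"q{i}" for i in range(5)]

    def test_optional_fields_absent_not_empty(self):
        src = io.StringIO("form_id,field_path,field_name,site_id\nF1,p/,q,\n")
        (rec,) = load_question_records(src)
        assert rec.site_id is None


class TestFlattenSchema:
    def test_nested_sections_become_path(self):
        schema = {
            "type": "object",
            "properties": {
                "economic": {
                    "type": "object",
                    "properties": {
                        "Education": {
                            "type": "object",
                            "properties": {
                                "What Is The Highest Grade You Have Completed": {"type": "string"}
                            },
                        }
                    },
                }
            },
        }
        (rec,) = flatten_json_schema(schema, "F1")
        assert rec.field_path == "economic/Education/"
        assert rec.field_name == "What Is The Highest Grade You Have Completed"
        assert rec.value_kind is ValueKind.FREE_TEXT

    def test_root_level_property_has_empty_path(self):
        (rec,) = flatten_json_schema(
            {"type": "object", "properties": {"note": {"type": "string"}}}, "F1"
        )
        assert rec.field_path == ""

    def test_enum_and_array_typing(self):
        schema = {
            "type": "object",
            "properties": {
                "color": {"type": "string", "enum": ["red", "green", "blue"]},
                "symptoms": {"type": "array", "items": {"type": "string"}},
            },
        }
        recs = flatten_json_schema(schema, "F1")
        assert len(recs) == 2
        assert recs[0].value_kind is ValueKind.CHOICE
        assert len(recs[0].allowed_values) == 3
        assert recs[1].value_kind is ValueKind.MULTI_ANSWER

    def test_non_object_root_rejected(self):
        with pytest.raises(SchemaFormatError):
            flatten_json_schema({"type": "string"}, "F1")

    def test_unsupported_leaf_skipped(self, caplog):
        schema = {"type": "object", "properties": {"flag": {"type": "boolean"}, "ok": {"type": "number"}}}
        recs = flatten_json_schema(schema, "F1")
        assert [r.field_name for r in recs] == ["ok"]

    @given(
        st.dictionaries(
            st.text(alphabet="abcdefg", min_size=1, max_size=4),
            st.recursive(
                st.just({"type": "string"}),
                lambda leaf: st.builds(
                    lambda props: {"type": "object", "properties": props},
                    st.dictionaries(st.text(alphabet="hijkl", min_size=1, max_size=4), leaf, max_size=3),
                ),
                max_leaves=6,
            ),
            min_size=1,
            max_size=3,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_paths_reconstruct_section_hierarchy(self, props):
        """Flattened field paths, re-nested, reproduce the schema's hierarchy."""
        schema = {"type": "object", "properties": props}
        recs = flatten_json_schema(schema, "F")

        def leaves(node, prefix):
            out = set()
            for name, sub in node.get("properties", {}).items():
                if sub.get("type") == "object":
                    out |= leaves(sub, prefix + name + "/")
                else:
                    out.add((prefix, name))
            return out

        assert {(r.field_path, r.field_name) for r in recs} == leaves(schema, "")


class TestDistinctQuestions:
    def test_worked_example_counts(self, education_records):
        assert distinct_questions(education_records, "path_and_text")[1] == 3
        assert distinct_questions(education_records, "text_only")[1] == 2

    def test_empty_and_idempotent(self, education_records):
        assert distinct_questions([], "path_and_text")[1] == 0
        assert distinct_questions([], "text_only")[1] == 0
        copies = [education_records[0]] * 100
        assert distinct_questions(copies, "path_and_text")[1] == 1
        assert distinct_questions(copies, "text_only")[1] == 1

    def test_normalization_merges_case_and_whitespace(self):
        recs = [
            QuestionRecord("a", "F", "p/", "Highest  Grade completed"),
            QuestionRecord("b", "F", "p/", "highest grade COMPLETED "),
        ]
        assert distinct_questions(recs, "text_only")[1] == 1

    @given(
        st.lists(
            st.tuples(st.sampled_from(["p1/", "p2/", "p3/"]), st.sampled_from(["qa", "qb", "qc", "qd"])),
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_text_only_never_exceeds_path_and_text(self, pairs):
        recs = [QuestionRecord(f"r{i}", "F", p, q) for i, (p, q) in enumerate(pairs)]
        assert distinct_questions(recs, "text_only")[1] <= distinct_questions(recs, "path_and_text")[1]


class TestPartition:
    def test_study_sizes(self):
        ids = [f"q{i}" for i in range(3582)]
        part = partition_records(ids, train_size=1937, seed=0)
        assert len(part.train_ids) == 1937
        assert len(part.test_ids) == 1645
        assert not part.train_ids & part.test_ids
        assert part.train_ids | part.test_ids == set(ids)

    def test_deterministic_for_fixed_seed(self):
        ids = [str(i) for i in range(50)]
        assert partition_records(ids, 20, seed=9) == partition_records(ids, 20, seed=9)

    @pytest.mark.parametrize("bad", [0, 10, 11])
    def test_train_size_bounds(self, bad):
        with pytest.raises(ValueError):
            partition_records([str(i) for i in range(10)], bad, seed=0)


def test_normalize_text_is_minimal():
    assert normalize_text("  A   B\tc ") == "a b c"
    assert normalize_text("don't!") == "don't!"  # no punctuation stripping
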