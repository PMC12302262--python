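"""ICSR data model, CSV readers, duplicate merging and term counting."""

import logging

import pytest

from oralpv.icsr import (
    COVARIATES,
    FormatError,
    ICSRCollection,
    ICSRRecord,
    merge_duplicates,
    read_icsr_table,
    write_icsr_table,
)

from conftest import multi_collection, record, single_collection

SINGLE_HEADER = "report_id,sex,age_group,vaccine_type,schedule,year,term\n"
MULTI_HEADER = (
    "report_id,sex,age_group,vaccine_type,schedule,year,vaccine_class,"
    "term1,term2,term3,term4,term5\n"
)


def test_read_single_term_csv(tmp_path):
    p = tmp_path / "db.csv"
    p.write_text(
        SINGLE_HEADER
        + "r1,female,18to59,mrna,primer,2021,ageusia\n"
        + "r2,male,over59,viral_vector,booster,2022,dry mouth\n"
        + "r3,female,7to17,mrna,primer,2023,Oral Herpes\n"
    )
    c = read_icsr_table(p, "single_term")
    assert c.n_total == 3
    assert c.dialect == "single_term"
    assert c.term_case_count("oral herpes") == 1  # normalized on read
    assert all(r.vaccine_class == "covid19" for r in c.records)


def test_unknown_enum_value_maps_to_missing(tmp_path, caplog):
    p = tmp_path / "db.csv"
    p.write_text(SINGLE_HEADER + "r1,unknown,18to59,mrna,primer,2021,ageusia\n")
    with caplog.at_level(logging.WARNING):
        c = read_icsr_table(p, "single_term")
    assert next(c.records).sex == "missing"
    assert any("unknown sex" in m for m in caplog.messages)


def test_malformed_rows_rejected_with_row_numbers(tmp_path, caplog):
    p = tmp_path / "db.csv"
    p.write_text(
        SINGLE_HEADER
        + "r1,female,18to59,mrna,primer,2021,ageusia\n"
        + "r2,female,18to59,mrna,primer,not_a_year,ageusia\n"
        + ",female,18to59,mrna,primer,2021,ageusia\n"
    )
    with caplog.at_level(logging.WARNING):
        c = read_icsr_table(p, "single_term")
    assert c.n_total == 1
    assert any("rejected 2 malformed rows" in m and "[3, 4]" in m for m in caplog.messages)


@pytest.mark.parametrize(
    "content,match",
    [
        ("", "empty file"),
        ("report_id,sex\nr1,female\n", "missing required column"),
        (SINGLE_HEADER, "no data rows"),
    ],
)
def test_format_errors(tmp_path, content, match):
    p = tmp_path / "bad.csv"
    p.write_text(content)
    with pytest.raises(FormatError, match=match):
        read_icsr_table(p, "single_term")


def test_six_term_columns_is_a_format_error(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text(
        MULTI_HEADER.rstrip() + ",term6\n"
        + "r1,female,18to59,mrna,primer,2021,covid19,a,b,c,d,e,f\n"
    )
    with pytest.raises(FormatError, match="unexpected columns"):
        read_icsr_table(p, "multi_term")


def test_multi_term_round_trip(tmp_path):
    c = multi_collection(
        [
            record("r1", ("ageusia", "headache"), vclass="covid19"),
            record("r2", ("headache",), vclass="comparator"),
        ]
    )
    p = tmp_path / "db2.csv"
    write_icsr_table(c, p)
    c2 = read_icsr_table(p, "multi_term")
    assert c2.n_total == 2
    assert c2.term_case_count("ageusia") == 1
    assert list(c2.frame["vaccine_class"]) == ["covid19", "comparator"]


def test_single_term_dialect_enforced():
    with pytest.raises(ValueError, match="exactly one term"):
        single_collection([record("r1", ("a", "b"))])
    with pytest.raises(ValueError, match="exceeds"):
        ICSRRecord("r", "female", "18to59", "mrna", "primer", 2021, "covid19", tuple("abcdef"))
    with pytest.raises(ValueError, match="no terms"):
        ICSRRecord("r", "female", "18to59", "mrna", "primer", 2021, "covid19", ())


class TestMergeDuplicates:
    def test_non_missing_value_wins(self):
        c = single_collection(
            [record("r1", "ageusia", sex="missing"), record("r1", "ageusia", sex="female")]
        )
        merged = merge_duplicates(c)
        assert merged.n_total == 1
        assert next(merged.records).sex == "female"

    def test_first_occurrence_breaks_conflicts(self):
        c = single_collection(
            [record("r1", "ageusia", sex="male"), record("r1", "ageusia", sex="female")]
        )
        assert next(merge_duplicates(c).records).sex == "male"

    def test_term_union_preserves_first_seen_order(self):
        c = multi_collection(
            [record("r1", ("a", "b")), record("r1", ("b", "c"))]
        )
        merged = merge_duplicates(c)
        assert next(merged.records).terms == ("a", "b", "c")

    def test_single_term_truncates_to_primary(self):
        c = ICSRCollection.from_records(
            [record("r1", "ageusia"), record("r1", "dry mouth")], "single_term"
        )
        assert next(merge_duplicates(c).records).terms == ("ageusia",)

    def test_idempotent(self):
        c = multi_collection(
            [record("r1", ("a", "b")), record("r1", ("c",)), record("r2", ("a",))]
        )
        once = merge_duplicates(c)
        twice = merge_duplicates(once)
        assert once.frame.equals(twice.frame)

    def test_duplicate_free_collection_unchanged(self):
        c = single_collection([record("r1", "a"), record("r2", "b")])
        assert merge_duplicates(c).frame.equals(c.frame)


class TestTermCounting:
    def test_single_term_scopes_coincide(self):
        c = single_collection([record(f"r{i}", "ageusia") for i in range(5)])
        assert c.term_case_count("ageusia", "any_position") == 5
        assert c.term_case_count("ageusia", "primary_only") == 5

    def test_multi_term_scope_distinction(self):
        c = multi_collection([record("r1", ("x", "y"))])
        assert c.term_case_count("x", "any_position") == 1
        assert c.term_case_count("x", "primary_only") == 1
        assert c.term_case_count("y", "any_position") == 1
        assert c.term_case_count("y", "primary_only") == 0

    def test_absent_term_counts_zero(self):
        c = single_collection([record("r1", "a")])
        assert c.term_case_count("x") == 0

    def test_unknown_scope_rejected(self):
        c = single_collection([record("r1", "a")])
        with pytest.raises(ValueError):
            c.term_case_count("a", "everywhere")


def test_covariate_counts_sum_to_n_total():
    c = single_collection(
        [
            record("r1", "a", sex="missing"),
            record("r2", "a", sex="male", age="missing"),
            record("r3", "b", vtype="missing", year=2022),
        ]
    )
    for variable in (*COVARIATES, "age3"):
        assert c.covariate_counts(variable).sum() == c.n_total


def test_age3_regrouping():
    c = single_collection(
        [
            record("r1", "a", age="under2"),
            record("r2", "a", age="2to6"),
            record("r3", "a", age="7to17"),
            record("r4", "a", age="18to59"),
            record("r5", "a", age="over59"),
            record("r6", "a", age="missing"),
        ]
    )
    counts = c.covariate_counts("age3")
    assert counts["minors"] == 3 and counts["adults"] == 1 and counts["seniors"] == 1
    assert counts["missing"] == 1
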