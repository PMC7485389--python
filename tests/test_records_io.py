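import pytest
from hypothesis import given, strategies as st

from comorbnet.records_io import (
    AgeBracket,
    DischargeRecord,
    RecordSet,
    default_age_brackets,
    parse_code_range,
    parse_records,
    prevalence_summary,
    stratify_by_age,
    validate_icd10,
)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("i49.8", "I49.8"),
        ("  I10.X ", "I10.X"),
        ("N18.9", "N18.9"),
        ("Q24.8", "Q24.8"),
        ("a00", "A00"),
    ],
)
def test_validate_accepts_and_normalizes(raw, expected):
    chk = validate_icd10(raw)
    assert chk.accepted and chk.code == expected


@pytest.mark.parametrize("raw", ["1234", "", "I1", "I10.XX", "I1O.X", "ii10", "I10-"])
def test_validate_rejects_malformed(raw):
    chk = validate_icd10(raw)
    assert not chk.accepted and chk.reason is not None


@given(st.from_regex(r"[A-Za-z][0-9]{2}(\.[A-Za-z0-9])?", fullmatch=True))
def test_validate_idempotent_on_accepted(code):
    first = validate_icd10(code)
    assert first.accepted
    again = validate_icd10(first.code)
    assert again.accepted and again.code == first.code


class TestParseRecords:
    def test_groups_rows_by_record_id(self, records_tsv):
        path = records_tsv([("r1", 50, "F", "I10.X"), ("r1", 50, "F", "N18.9")])
        rs = parse_records(path)
        assert rs.n_records == 1
        assert rs.records[0].codes == {"I10.X", "N18.9"}

    def test_blank_age_excluded_as_incomplete(self, records_tsv):
        path = records_tsv(
            [("r1", 50, "F", "I10.X"), ("r2", "", "M", "I25.8"), ("r3", 3, "F", "Q24.8")]
        )
        rs = parse_records(path)
        assert rs.n_records == 2
        assert rs.exclusions == {"incomplete": 1}

    def test_invalid_only_code_drops_record(self, records_tsv):
        path = records_tsv([("r1", 50, "F", "NOPE"), ("r2", 50, "F", "I10.X")])
        rs = parse_records(path)
        assert rs.n_records == 1
        assert rs.exclusions["non_existing_code"] == 1

    def test_negative_age_excluded(self, records_tsv):
        rs = parse_records(records_tsv([("r1", -4, "F", "I10.X"), ("r2", 4, "F", "I10.X")]))
        assert rs.n_records == 1 and rs.exclusions["invalid_age"] == 1

    def test_missing_column_is_fatal(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("record_id\tage\ticd10\nr1\t5\tI10.X\n")
        with pytest.raises(ValueError, match="sex"):
            parse_records(p)

    def test_empty_file_is_fatal(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("record_id\tage\tsex\ticd10\n")
        with pytest.raises(ValueError):
            parse_records(p)

    def test_exclusion_accounting(self, records_tsv):
        rows = [
            ("r1", 50, "F", "I10.X"),
            ("r2", "", "F", "I10.X"),
            ("r3", 9, "M", "???"),
            ("r4", -1, "M", "I25.8"),
            ("r5", 20, "x", "N18.9"),
        ]
        rs = parse_records(records_tsv(rows))
        assert rs.n_records + sum(rs.exclusions.values()) == 5
        assert rs.records[-1].sex == "unknown"  # odd sex retained, not excluded


class TestStratify:
    @pytest.mark.parametrize("age,label", [(0, "0-10"), (10, "0-10"), (11, "11-20"),
                                           (95, "91-100"), (104, "91-100")])
    def test_bracket_assignment(self, age, label):
        rs = RecordSet([DischargeRecord("r", age, "female", frozenset({"I10.X"}))])
        strata = stratify_by_age(rs)
        assert strata[label].n_records == 1

    @given(st.lists(st.integers(min_value=0, max_value=120), min_size=1, max_size=40))
    def test_partition_is_disjoint_and_exhaustive(self, ages):
        rs = RecordSet(
            [DischargeRecord(f"r{i}", a, "male", frozenset({"I10.X"})) for i, a in enumerate(ages)]
        )
        strata = stratify_by_age(rs)
        assert sum(s.n_records for s in strata.values()) == rs.n_records
        ids = [r.record_id for s in strata.values() for r in s]
        assert len(ids) == len(set(ids))

    def test_bad_brackets_rejected(self):
        rs = RecordSet([DischargeRecord("r", 5, "male", frozenset({"I10.X"}))])
        with pytest.raises(ValueError):
            stratify_by_age(rs, [AgeBracket("0-10", 0, 10), AgeBracket("12+", 12, None)])


class TestPrevalence:
    def test_single_record_cell_is_100_percent(self):
        rs = RecordSet([DischargeRecord("r", 3, "female", frozenset({"Q24.8"}))])
        df = prevalence_summary(rs, ["Q20-Q28"])
        assert len(df) == 1
        assert df.iloc[0]["percent"] == 100.0

    def test_no_intersection_is_zero(self):
        rs = RecordSet([DischargeRecord("r", 3, "female", frozenset({"I10.X"}))])
        df = prevalence_summary(rs, ["Q20-Q28"])
        assert df.iloc[0]["percent"] == 0.0

    def test_malformed_range_fatal(self):
        with pytest.raises(ValueError):
            parse_code_range("Q28-Q20")
        with pytest.raises(ValueError):
            parse_code_range("Q20")

    def test_planted_prevalence_recovered(self):
        # 90% of young records carry a Q-range code by construction
        import numpy as np

        rng = np.random.default_rng(5)
        recs = []
        for i in range(400):
            codes = {"Q24.8"} if rng.random() < 0.9 else {"I10.X"}
            recs.append(DischargeRecord(f"r{i}", int(rng.integers(0, 11)), "female",
                                        frozenset(codes)))
        df = prevalence_summary(RecordSet(recs), ["Q20-Q28"])
        cell = df[(df.bracket == "0-10") & (df.group == "Q20-Q28")]
        assert abs(cell.iloc[0]["percent"] - 90.0) < 5.0  # binomial error at n=400

    def test_default_brackets_cover_everything(self):
        brackets = default_age_brackets()
        assert brackets[0].lo == 0 and brackets[-1].hi is None
        assert len(brackets) == 10
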