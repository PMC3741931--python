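"""Cohort ingestion, discretization, population filtering, encoding."""

from __future__ import annotations

import pytest

import clinrules as cr
from clinrules.cohort import MISSING, DEFAULT_SCHEME, op_group
from clinrules.synthetic import SyntheticConfig


def _record(**overrides) -> cr.PatientRecord:
    base = dict(
        patient_id="P1",
        age=55.0,
        primary_site="Tongue",
        laterality=1,
        grade=2,
        nodes_examined=3,
        clinical_stage=2,
        pathologic_stage=1,
        clinical_tumor_size=2.5,
        pathology_tumor_size=1.8,
        treatment_sequence=("OP",),
        survival_months=48.0,
        vital_status="alive",
    )
    base.update(overrides)
    return cr.PatientRecord(**base)


RAW_HEADER = (
    "patient_id,age,primary_site,laterality,grade,nodes_examined,"
    "clinical_stage,pathologic_stage,clinical_tumor_size,pathology_tumor_size,"
    "treatment_sequence,survival_months,vital_status\n"
)


def _raw_row(pid: str, survival: str = "40") -> str:
    return f"{pid},55,Tongue,1,2,3,2,1,2.5,1.8,OP->RT,{survival},dead\n"


class TestReadCohort:
    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text(RAW_HEADER + _raw_row("P1") + _raw_row("P2") + _raw_row("P3"))
        records = cr.read_cohort(path)
        assert len(records) == 3
        assert records[0].treatment_sequence == ("OP", "RT")

    def test_malformed_survival_drops_row(self, tmp_path, caplog):
        path = tmp_path / "cohort.csv"
        path.write_text(RAW_HEADER + _raw_row("P1") + _raw_row("P2", survival="abc") + _raw_row("P3"))
        with caplog.at_level("WARNING", logger="clinrules.cohort"):
            records = cr.read_cohort(path)
        assert [r.patient_id for r in records] == ["P1", "P3"]
        assert any("dropping row 2" in msg for msg in caplog.messages)

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            cr.read_cohort(tmp_path / "nope.csv")

    def test_missing_mandatory_column_fatal(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text("patient_id,age\nP1,55\n")
        with pytest.raises(ValueError, match="mandatory column"):
            cr.read_cohort(path)

    def test_schema_mapping(self, tmp_path):
        header = RAW_HEADER.replace("survival_months", "fu_months")
        path = tmp_path / "cohort.csv"
        path.write_text(header + _raw_row("P1"))
        records = cr.read_cohort(path, schema={"survival_months": "fu_months"})
        assert records[0].survival_months == 40.0

    def test_synthetic_cohort_round_trip(self, tmp_path):
        records = cr.generate_cohort(SyntheticConfig(seed=3))
        path = tmp_path / "synthetic.csv"
        cr.write_cohort(records, path)
        assert cr.read_cohort(path) == records


class TestDiscretize:
    @pytest.mark.parametrize(
        "age, expected",
        [(29.9, "<30"), (30, "30~50"), (45, "30~50"), (50, "30~50"),
         (50.5, "50~70"), (70, "50~70"), (71, ">70")],
    )
    def test_age_bins(self, age, expected):
        assert DEFAULT_SCHEME.age_group(age) == expected

    @pytest.mark.parametrize(
        "size, expected",
        [(1.9, "<2 cm"), (2.0, "2~4 cm"), (4.0, "2~4 cm"), (4.1, ">4 cm"),
         (None, MISSING)],
    )
    def test_size_bins(self, size, expected):
        assert DEFAULT_SCHEME.size_group(size) == expected

    @pytest.mark.parametrize(
        "n, expected",
        [(0, "<5"), (4, "<5"), (5, "5~10"), (10, "5~10"), (11, ">10")],
    )
    def test_node_bins(self, n, expected):
        assert DEFAULT_SCHEME.nodes_group(n) == expected

    @pytest.mark.parametrize(
        "seq, expected",
        [(("OP",), "01"), (("OP", "IA"), "02"), (("OP", "RT"), "03"),
         (("OP", "RT", "CT"), "03"), (("OP", "CT+IV"), "03"),
         (("OP", "IA", "CT"), MISSING)],
    )
    def test_op_group_codes(self, seq, expected):
        assert op_group(seq) == expected

    def test_discretized_row(self):
        table = cr.discretize([_record()])
        row = table.iloc[0]
        assert row["age_group"] == "50~70"
        assert row["grade"] == "02"
        assert row["laterality"] == "01"
        assert row["clinical_stage_group"] == "early"
        assert row["clinical_size_group"] == "2~4 cm"
        assert row["pathology_size_group"] == "<2 cm"
        assert row["group"] == "OP"
        assert bool(row["survived_gt36"]) is True
        assert row["five_year_survivor"] == MISSING  # alive, censored at 48 mo

    def test_missing_values_marked(self):
        table = cr.discretize([_record(clinical_stage=None, clinical_tumor_size=None)])
        assert table.iloc[0]["clinical_stage_group"] == MISSING
        assert table.iloc[0]["clinical_size_group"] == MISSING

    def test_deterministic(self):
        recs = [_record(), _record(patient_id="P2", age=28)]
        assert cr.discretize(recs).equals(cr.discretize(recs))


class TestStageGroup:
    @pytest.mark.parametrize("stage, expected", [(0, "early"), (1, "early"),
                                                 (2, "early"), (3, "early"),
                                                 (4, "late")])
    def test_mapping(self, stage, expected):
        assert cr.stage_group(stage) == expected

    @pytest.mark.parametrize("stage", [-1, 5])
    def test_out_of_range(self, stage):
        with pytest.raises(ValueError):
            cr.stage_group(stage)


class TestFilterPopulation:
    def test_strata_sizes(self):
        records = cr.generate_cohort(SyntheticConfig(seed=0))
        table = cr.discretize(records)
        assert len(cr.filter_population(table, "survived_gt36")) == 271
        assert len(cr.filter_population(table, "not_survived_gt36")) == 222
        assert cr.filter_population(table, "all").equals(table)

    def test_unknown_predicate_fatal(self):
        table = cr.discretize([_record()])
        with pytest.raises(ValueError, match="predicate"):
            cr.filter_population(table, "survivors")

    def test_empty_cohort(self):
        table = cr.discretize([])
        assert len(cr.filter_population(table, "survived_gt36")) == 0


class TestEncodeTransactions:
    def test_single_record(self):
        table = cr.discretize([_record()])
        db = cr.encode_transactions(table, ["grade", "group"])
        assert db.N == 1
        assert db.labels(sorted(db.transactions[0])) == ("grade=02", "group=OP")

    def test_missing_record_dropped(self):
        table = cr.discretize([_record(), _record(patient_id="P2", clinical_stage=None)])
        db = cr.encode_transactions(table, ["grade", "clinical_stage_group"])
        assert db.N == 1

    def test_empty_attribute_list_fatal(self):
        table = cr.discretize([_record()])
        with pytest.raises(ValueError):
            cr.encode_transactions(table, [])

    def test_unknown_attribute_fatal(self):
        table = cr.discretize([_record()])
        with pytest.raises(KeyError):
            cr.encode_transactions(table, ["grade", "histology"])

    def test_item_ids_stable_and_ordered(self):
        table = cr.discretize([_record(), _record(patient_id="P2", grade=1)])
        db1 = cr.encode_transactions(table, ["grade", "group"])
        db2 = cr.encode_transactions(table, ["grade", "group"])
        assert db1.id_to_item == db2.id_to_item
        # attribute order first, then value order within attribute
        assert db1.id_to_item == ("grade=01", "grade=02", "group=OP")

    def test_fixture_population_size(self, fixture_db):
        assert fixture_db.N == 271
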