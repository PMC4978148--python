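"""Required / recommended / heuristic rule classes over dataset trees."""

import json

import pytest

from bidslite.core_model import (
    ISSUE_CATALOGUE,
    BidsFile,
    EntitySet,
    MetadataMap,
    Severity,
    Table,
)
from bidslite.dataset import DatasetError
from bidslite.fixtures import DefectSpec, FixtureSpec, generate_dataset, inject_defect
from bidslite.rules_engine import (
    RuleSet,
    check_required,
    check_tables,
    report_json,
    report_text,
    validate_dataset,
)


def codes(issues):
    return sorted(i.code for i in issues)


def _events_file():
    return BidsFile(
        relpath="sub-01/func/sub-01_task-x_events.tsv",
        entity_set=EntitySet({"sub": "01", "task": "x"}, "events", ".tsv"),
        datatype="func",
    )


class TestCheckTables:
    def test_events_missing_both_compulsory_columns(self, rules):
        t = Table(columns=["trial_type", "response"], rows=[])
        issues = check_tables(_events_file(), t, rules)
        assert codes(issues) == ["EVENTS_MISSING_REQUIRED_COLUMN"] * 2

    def test_participants_missing_compulsory_column(self, rules):
        f = BidsFile(
            relpath="participants.tsv",
            entity_set=EntitySet({}, "participants", ".tsv"),
            datatype="root-level",
        )
        t = Table(columns=["age", "sex"], rows=[])
        issues = check_tables(f, t, rules)
        assert codes(issues) == ["PARTICIPANTS_MISSING_REQUIRED_COLUMN"]

    def test_complete_events_header_passes(self, rules):
        t = Table(columns=["onset", "duration"], rows=[["0.5", "1.0"]])
        assert check_tables(_events_file(), t, rules) == []

    def test_non_numeric_onset_is_error(self, rules):
        t = Table(columns=["onset", "duration"], rows=[["soon", "1.0"]])
        assert codes(check_tables(_events_file(), t, rules)) == ["INVALID_NUMERIC_CELL"]

    def test_negative_duration_is_error(self, rules):
        t = Table(columns=["onset", "duration"], rows=[["0.5", "-1.0"]])
        assert codes(check_tables(_events_file(), t, rules)) == ["INVALID_NUMERIC_CELL"]


class TestCheckRequired:
    def test_bold_with_empty_metadata(self, rules):
        f = BidsFile(
            relpath="sub-01/func/sub-01_task-x_bold.nii.gz",
            entity_set=EntitySet({"sub": "01", "task": "x"}, "bold", ".nii.gz"),
            datatype="func",
        )
        issues = check_required(f, MetadataMap(), rules)
        assert codes(issues) == ["MISSING_REQUIRED_FIELD"] * 2  # TaskName, TR

    def test_physio_without_sampling_frequency(self, rules):
        f = BidsFile(
            relpath="sub-01/func/sub-01_task-x_physio.tsv.gz",
            entity_set=EntitySet({"sub": "01", "task": "x"}, "physio", ".tsv.gz"),
            datatype="func",
        )
        resolved = MetadataMap.from_pairs({"StartTime": 0.0})
        issues = check_required(f, resolved, rules)
        assert codes(issues) == ["MISSING_REQUIRED_FIELD"]
        assert "SamplingFrequency" in issues[0].message


class TestValidateDataset:
    def test_valid_fixture_has_no_issues(self, valid_dataset):
        root, _ = valid_dataset
        assert validate_dataset(root) == []

    def test_unreadable_root_is_fatal_not_an_issue(self, tmp_path):
        with pytest.raises(DatasetError):
            validate_dataset(tmp_path / "nope")

    def test_empty_dataset_missing_subject_error(self, tmp_path):
        root = tmp_path / "ds"
        root.mkdir()
        issues = validate_dataset(root)
        assert "MISSING_SUBJECT" in codes(issues)

    def test_deleted_dataset_description_single_error(self, defect_dataset):
        (defect_dataset / "dataset_description.json").unlink()
        issues = validate_dataset(defect_dataset)
        assert codes(issues) == ["MISSING_REQUIRED_FILE"]
        assert issues[0].severity is Severity.ERROR

    def test_dataset_description_missing_version_field(self, defect_dataset):
        p = defect_dataset / "dataset_description.json"
        pairs = json.loads(p.read_text())
        del pairs["BIDSVersion"]
        p.write_text(json.dumps(pairs))
        issues = validate_dataset(defect_dataset)
        assert codes(issues) == ["MISSING_REQUIRED_FIELD"]

    def test_absent_slice_timing_warns_only(self, defect_dataset):
        for sidecar in sorted(defect_dataset.glob("sub-*/func/*_bold.json")):
            pairs = json.loads(sidecar.read_text())
            del pairs["SliceTiming"]
            sidecar.write_text(json.dumps(pairs))
        issues = validate_dataset(defect_dataset)
        assert {i.code for i in issues} == {"MISSING_RECOMMENDED_FIELD"}
        assert all(i.severity is Severity.WARNING for i in issues)

    def test_dwi_without_bval_is_error(self, tmp_path):
        root = tmp_path / "ds"
        generate_dataset(FixtureSpec(n_subjects=1, include_dwi=True, seed=3), root)
        (root / "sub-01/dwi/sub-01_dwi.bval").unlink()
        issues = validate_dataset(root)
        assert codes(issues) == ["MISSING_REQUIRED_FILE"]
        assert ".bval" in issues[0].message

    def test_resting_run_exempt_from_events_requirement(self, tmp_path):
        root = tmp_path / "ds"
        generate_dataset(
            FixtureSpec(n_subjects=1, tasks=(("rest", 1, 2.0, 5),), seed=4), root
        )
        assert not list(root.glob("sub-01/func/*_events.tsv"))
        assert validate_dataset(root) == []

    def test_non_rest_run_without_events_is_error(self, tmp_path):
        root = tmp_path / "ds"
        generate_dataset(FixtureSpec(n_subjects=1, seed=5), root)
        (root / "sub-01/func/sub-01_task-stopsignal_events.tsv").unlink()
        issues = validate_dataset(root)
        assert codes(issues) == ["MISSING_REQUIRED_FILE"]

    def test_folder_entity_mismatch_is_error(self, defect_dataset):
        src = defect_dataset / "sub-01/anat/sub-01_T1w.nii.gz"
        src.rename(defect_dataset / "sub-01/anat/sub-02_T1w.nii.gz")
        issues = validate_dataset(defect_dataset)
        assert "SUBJECT_FOLDER_MISMATCH" in codes(issues)

    def test_derivatives_folder_exempt(self, defect_dataset):
        d = defect_dataset / "derivatives/sub-01/ses-pre"
        d.mkdir(parents=True)
        (d / "mask.nii.gz").write_bytes(b"anything")
        assert validate_dataset(defect_dataset) == []

    def test_suspicious_tr_in_milliseconds(self, defect_dataset):
        sidecar = defect_dataset / "sub-01/func/sub-01_task-stopsignal_bold.json"
        pairs = json.loads(sidecar.read_text())
        pairs["RepetitionTime"] = 2000
        sidecar.write_text(json.dumps(pairs))
        issues = validate_dataset(defect_dataset)
        assert "SUSPICIOUS_UNITS" in codes(issues)

    def test_nifti_json_tr_conflict(self, defect_dataset):
        inject_defect(defect_dataset, DefectSpec("nifti_json_mismatch",
                                                 subject="01", task="stopsignal"))
        issues = validate_dataset(defect_dataset)
        assert codes(issues) == ["NIFTI_JSON_CONFLICT"]

    def test_missing_scan_names_the_subject(self, defect_dataset):
        inject_defect(defect_dataset, DefectSpec("remove_scan", subject="03",
                                                 task="stopsignal"))
        issues = validate_dataset(defect_dataset)
        assert codes(issues) == ["MISSING_SCAN"]
        assert "sub-03" in issues[0].message

    def test_severity_partition_over_defect_battery(self, tmp_path):
        """Every emitted issue's severity matches the catalogue's fixed
        severity for its code, across a defect-rich dataset."""
        root = tmp_path / "ds"
        generate_dataset(FixtureSpec(seed=6), root)
        for kind in ("drop_required_field", "na_uppercase", "tr_milliseconds",
                     "add_unknown_file"):
            inject_defect(root, DefectSpec(kind, subject="01", task="stopsignal"))
        issues = validate_dataset(root)
        assert issues
        for i in issues:
            assert i.severity is ISSUE_CATALOGUE[i.code]

    def test_error_monotonicity_under_deletion(self, defect_dataset):
        """Deleting files/keys never decreases the required-class ERROR count."""
        def n_errors(root):
            return sum(1 for i in validate_dataset(root)
                       if i.severity is Severity.ERROR)
        before = n_errors(defect_dataset)
        inject_defect(defect_dataset, DefectSpec("drop_required_field",
                                                 subject="01", task="stopsignal"))
        mid = n_errors(defect_dataset)
        (defect_dataset / "dataset_description.json").unlink()
        after = n_errors(defect_dataset)
        assert before <= mid <= after
        assert after > before

    def test_issues_sorted_and_deterministic(self, defect_dataset):
        inject_defect(defect_dataset, DefectSpec("tr_milliseconds",
                                                 subject="01", task="stopsignal"))
        a = validate_dataset(defect_dataset)
        b = validate_dataset(defect_dataset)
        assert a == b
        assert a == sorted(a, key=lambda i: (i.path, i.code, i.message))


class TestReports:
    def test_json_report_schema(self, defect_dataset):
        (defect_dataset / "dataset_description.json").unlink()
        issues = validate_dataset(defect_dataset)
        rep = report_json(issues)
        assert rep["summary"] == {"errors": 1, "warnings": 0}
        assert rep["issues"][0]["code"] == "MISSING_REQUIRED_FILE"
        json.dumps(rep)  # serializable

    def test_text_report_summary_line(self, valid_dataset):
        root, _ = valid_dataset
        text = report_text(validate_dataset(root))
        assert text.endswith("0 errors, 0 warnings")


class TestRuleSet:
    def test_default_ruleset_loads_from_data_file(self):
        rs = RuleSet.default()
        assert rs.required_fields["bold"] == ["TaskName", "RepetitionTime"]
        assert rs.required_columns["participants"] == ["participant_id"]

    def test_extensible_suffix_vocabulary(self, tmp_path):
        rs = RuleSet.from_mapping({"extra_suffixes": ["sbref"]})
        assert "sbref" in rs.suffix_vocabulary()
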