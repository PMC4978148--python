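"""Four-level metadata inheritance: candidate enumeration and per-key merge."""

import itertools
import json

import pytest

from bidslite.core_model import BidsFile, EntitySet
from bidslite.dataset import index_dataset
from bidslite.inheritance import candidate_paths, find_companion, resolve_metadata
from bidslite.sidecar_io import MetadataError


def _bold(relpath, entities):
    return BidsFile(
        relpath=relpath,
        entity_set=EntitySet(entities, "bold", ".nii.gz"),
        datatype="func",
    )


class TestCandidatePaths:
    def test_session_run_yields_four_levels(self):
        f = _bold(
            "sub-01/ses-pre/func/sub-01_ses-pre_task-x_bold.nii.gz",
            {"sub": "01", "ses": "pre", "task": "x"},
        )
        cands = candidate_paths(f)
        assert [level for level, _ in cands] == [
            "dataset", "subject", "session", "acquisition",
        ]
        assert dict(cands) == {
            "dataset": "task-x_bold.json",
            "subject": "sub-01/sub-01_task-x_bold.json",
            "session": "sub-01/ses-pre/sub-01_ses-pre_task-x_bold.json",
            "acquisition": "sub-01/ses-pre/func/sub-01_ses-pre_task-x_bold.json",
        }

    def test_no_session_yields_three_levels(self):
        f = _bold("sub-01/func/sub-01_task-x_bold.nii.gz", {"sub": "01", "task": "x"})
        assert len(candidate_paths(f)) == 3

    def test_dataset_level_task_sidecar_name(self):
        f = _bold("sub-03/func/sub-03_task-nback_bold.nii.gz",
                  {"sub": "03", "task": "nback"})
        assert candidate_paths(f)[0] == ("dataset", "task-nback_bold.json")

    def test_sidecar_kind_selects_suffix_and_extension(self):
        f = _bold("sub-01/func/sub-01_task-x_bold.nii.gz", {"sub": "01", "task": "x"})
        cands = candidate_paths(f, suffix="events", extension=".tsv")
        assert cands[-1][1] == "sub-01/func/sub-01_task-x_events.tsv"


def _make_tree(root, layers):
    """Write JSON sidecars for the given {level: pairs} assignment."""
    paths = {
        "dataset": "task-x_bold.json",
        "subject": "sub-01/sub-01_task-x_bold.json",
        "session": "sub-01/ses-pre/sub-01_ses-pre_task-x_bold.json",
        "acquisition": "sub-01/ses-pre/func/sub-01_ses-pre_task-x_bold.json",
    }
    (root / "sub-01/ses-pre/func").mkdir(parents=True, exist_ok=True)
    img = root / "sub-01/ses-pre/func/sub-01_ses-pre_task-x_bold.nii.gz"
    img.write_bytes(b"")  # placeholder: resolution only needs the name
    for level, pairs in layers.items():
        p = root / paths[level]
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(pairs))
    return _bold(
        "sub-01/ses-pre/func/sub-01_ses-pre_task-x_bold.nii.gz",
        {"sub": "01", "ses": "pre", "task": "x"},
    )


class TestResolve:
    def test_lower_level_overrides_per_key(self, tmp_path):
        f = _make_tree(tmp_path, {
            "dataset": {"TaskName": "nback", "RepetitionTime": 2.0},
            "acquisition": {"RepetitionTime": 3.0},
        })
        model = index_dataset(tmp_path)
        resolved = resolve_metadata(f, model)
        assert resolved.pairs == {"TaskName": "nback", "RepetitionTime": 3.0}
        assert resolved.provenance == {
            "TaskName": "dataset", "RepetitionTime": "acquisition",
        }

    def test_subject_override_applies_only_to_that_subject(self, tmp_path):
        (tmp_path / "task-nback_bold.json").write_text('{"RepetitionTime": 2.0}')
        for sub in ("01", "03"):
            d = tmp_path / f"sub-{sub}/func"
            d.mkdir(parents=True)
            (d / f"sub-{sub}_task-nback_bold.nii.gz").write_bytes(b"")
        (tmp_path / "sub-03/sub-03_task-nback_bold.json").write_text(
            '{"RepetitionTime": 2.5}')
        model = index_dataset(tmp_path)
        f1 = _bold("sub-01/func/sub-01_task-nback_bold.nii.gz",
                   {"sub": "01", "task": "nback"})
        f3 = _bold("sub-03/func/sub-03_task-nback_bold.nii.gz",
                   {"sub": "03", "task": "nback"})
        assert resolve_metadata(f1, model).get("RepetitionTime") == 2.0
        assert resolve_metadata(f3, model).get("RepetitionTime") == 2.5

    def test_no_sidecars_resolves_empty(self, tmp_path):
        f = _make_tree(tmp_path, {})
        model = index_dataset(tmp_path)
        assert resolve_metadata(f, model).pairs == {}

    def test_single_sidecar_is_identity(self, tmp_path):
        f = _make_tree(tmp_path, {"subject": {"EchoTime": 0.03, "A": 1}})
        model = index_dataset(tmp_path)
        resolved = resolve_metadata(f, model)
        assert resolved.pairs == {"EchoTime": 0.03, "A": 1}
        assert set(resolved.provenance.values()) == {"subject"}

    def test_unparseable_candidate_aborts_resolution(self, tmp_path):
        f = _make_tree(tmp_path, {"dataset": {"A": 1}})
        (tmp_path / "sub-01/sub-01_task-x_bold.json").write_text("{broken")
        model = index_dataset(tmp_path)
        with pytest.raises(MetadataError):
            resolve_metadata(f, model)

    def test_exhaustive_agreement_with_bruteforce_merge(self, tmp_path):
        """Resolver output equals a brute-force per-key merge over every
        assignment of 2 keys to presence/absence at each of 4 levels."""
        levels = ("dataset", "subject", "session", "acquisition")
        keys = ("RepetitionTime", "TaskName")
        values = {  # distinct value per (key, level) so the winner is visible
            ("RepetitionTime", lv): float(i + 1) for i, lv in enumerate(levels)
        } | {("TaskName", lv): f"task@{lv}" for lv in levels}
        n_checked = 0
        for mask in itertools.product([False, True], repeat=2 * len(levels)):
            layers: dict[str, dict] = {}
            for i, (key, lv) in enumerate(itertools.product(keys, levels)):
                if mask[i]:
                    layers.setdefault(lv, {})[key] = values[(key, lv)]
            root = tmp_path / f"case{n_checked}"
            root.mkdir()
            f = _make_tree(root, layers)
            resolved = resolve_metadata(f, index_dataset(root))
            # brute force: per key, the lowest defining level wins
            expected = {}
            for key in keys:
                for lv in levels:  # highest to lowest; later wins
                    if key in layers.get(lv, {}):
                        expected[key] = values[(key, lv)]
            assert resolved.pairs == expected
            n_checked += 1
        assert n_checked == 256

    def test_monotone_growth_down_the_hierarchy(self, tmp_path):
        """Adding a lower-level sidecar never removes keys."""
        f = _make_tree(tmp_path, {"dataset": {"A": 1, "B": 2}})
        model = index_dataset(tmp_path)
        before = set(resolve_metadata(f, model).pairs)
        (tmp_path / "sub-01/sub-01_task-x_bold.json").write_text('{"B": 9, "C": 3}')
        after = set(resolve_metadata(f, index_dataset(tmp_path)).pairs)
        assert before <= after


class TestCompanions:
    def test_most_specific_existing_companion_wins(self, tmp_path):
        (tmp_path / "sub-01/dwi").mkdir(parents=True)
        f = BidsFile(
            relpath="sub-01/dwi/sub-01_dwi.nii.gz",
            entity_set=EntitySet({"sub": "01"}, "dwi", ".nii.gz"),
            datatype="dwi",
        )
        (tmp_path / "dwi.bval").write_text("0\n")
        model = index_dataset(tmp_path)
        assert find_companion(f, model, extension=".bval") == "dwi.bval"
        (tmp_path / "sub-01/dwi/sub-01_dwi.bval").write_text("0\n")
        model = index_dataset(tmp_path)
        assert find_companion(f, model, extension=".bval") == "sub-01/dwi/sub-01_dwi.bval"
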