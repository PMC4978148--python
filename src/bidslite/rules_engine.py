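"""The validation rule engine.

Three rule classes, mirroring how dataset curation tools in this field
report problems:

* **required** — a missing compulsory file, field or column is an ERROR
  (e.g. every functional run needs TaskName, RepetitionTime and an events
  table unless it is a resting-state scan; diffusion runs need .bval and
  .bvec; the dataset needs dataset_description.json and at least one
  subject folder).
* **recommended** — a missing recommended field (SliceTiming,
  PhaseEncodingDirection, EffectiveEchoSpacing, EchoTime) is a WARNING.
* **heuristic** — WARNINGs for suspicious patterns: miscoded missing
  values ('NA' instead of 'n/a'), wrong units (a RepetitionTime of 2000 is
  milliseconds, not seconds), scans present for most subjects but absent
  for some, acquisition parameters that differ across subjects for the
  same task, files that do not fit the naming standard, and conflicts
  between the JSON sidecar and the NIfTI header.

Rule tables live in a versioned data file (``data/rules.json``) so the
vocabulary can be extended without code changes.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional

from .core_model import (
    DatasetModel,
    BidsFile,
    Issue,
    MetadataMap,
    Severity,
    Table,
    MISSING,
    MissingValue,
    issue_sort_key,
    new_issue,
)
from .dataset import DatasetError, index_dataset
from .filename_grammar import DEFAULT_SUFFIXES, DATATYPE_SUFFIXES
from .inheritance import find_companion, resolve_metadata
from .sidecar_io import (
    GradientError,
    MetadataError,
    NiftiError,
    read_gradients,
    read_nifti_header,
)
from .tabular_io import TsvError, read_tsv

__all__ = [
    "RuleSet",
    "validate_dataset",
    "check_required",
    "check_recommended",
    "check_tables",
    "heuristic_checks",
    "report_text",
    "report_json",
]


@dataclass
class RuleSet:
    """Validation rule tables, normally loaded from the packaged data file."""

    required_fields: dict[str, list[str]] = field(default_factory=dict)
    recommended_fields: dict[str, list[str]] = field(default_factory=dict)
    required_companions: dict[str, list[dict]] = field(default_factory=dict)
    required_columns: dict[str, list[str]] = field(default_factory=dict)
    numeric_columns: dict[str, list[str]] = field(default_factory=dict)
    required_root_files: list[str] = field(default_factory=list)
    dataset_description_required_fields: list[str] = field(default_factory=list)
    na_heuristic_tokens: list[str] = field(default_factory=list)
    suspicious_units: dict[str, list[float]] = field(default_factory=dict)
    missing_scan_threshold: float = 0.5
    consistency_fields: list[str] = field(default_factory=list)
    tr_conflict_tolerance_s: float = 1e-3
    extra_suffixes: list[str] = field(default_factory=list)
    extra_datatype_suffixes: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    version: str = "1.0.0"

    @classmethod
    def default(cls) -> "RuleSet":
        with resources.files("bidslite.data").joinpath("rules.json").open("rb") as fh:
            return cls.from_mapping(json.load(fh))

    @classmethod
    def from_file(cls, path: str | Path) -> "RuleSet":
        with open(path, "rb") as fh:
            return cls.from_mapping(json.load(fh))

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RuleSet":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})

    def suffix_vocabulary(self) -> frozenset:
        return DEFAULT_SUFFIXES | frozenset(self.extra_suffixes)

    def datatype_suffixes(self) -> dict:
        merged = {k: dict(v) for k, v in DATATYPE_SUFFIXES.items()}
        for dt, suffixes in self.extra_datatype_suffixes.items():
            merged.setdefault(dt, {}).update(
                {s: tuple(exts) for s, exts in suffixes.items()}
            )
        return merged


def _is_number(value: Any) -> bool:
    return isinstance(value, (int, float)) and not isinstance(value, bool) and math.isfinite(value)


def _numeric_cell(cell: Any) -> Optional[float]:
    if isinstance(cell, MissingValue):
        return None
    try:
        return float(str(cell))
    except ValueError:
        raise ValueError(str(cell)) from None


def check_required(
    f: BidsFile,
    resolved: MetadataMap,
    rules: RuleSet,
    model: Optional[DatasetModel] = None,
) -> list[Issue]:
    """Required-field and required-companion checks for one data file.

    Emits one ERROR per missing required metadata field and one per
    missing companion file.  Functional runs whose TaskName begins with
    'rest' (case-insensitive) are exempt from the events-file requirement.
    """
    issues: list[Issue] = []
    suffix = f.entity_set.suffix if f.entity_set else ""
    for key in rules.required_fields.get(suffix, []):
        if key not in resolved:
            issues.append(new_issue(
                "MISSING_REQUIRED_FIELD", Severity.ERROR, f.relpath,
                f"required metadata field {key!r} is not defined at any level",
            ))
    if model is not None:
        task = resolved.get("TaskName")
        for comp in rules.required_companions.get(suffix, []):
            prefix = comp.get("unless_task_prefix")
            if prefix and isinstance(task, str) and task.lower().startswith(prefix.lower()):
                continue
            found = find_companion(
                f, model, suffix=comp.get("suffix"), extension=comp["extension"]
            )
            if found is None:
                kind = (comp.get("suffix") or suffix) + comp["extension"]
                issues.append(new_issue(
                    "MISSING_REQUIRED_FILE", Severity.ERROR, f.relpath,
                    f"required companion file ({kind}) not found at any level",
                ))
    return issues


def check_recommended(f: BidsFile, resolved: MetadataMap, rules: RuleSet) -> list[Issue]:
    """One WARNING per missing recommended metadata field."""
    issues: list[Issue] = []
    suffix = f.entity_set.suffix if f.entity_set else ""
    for key in rules.recommended_fields.get(suffix, []):
        if key not in resolved:
            issues.append(new_issue(
                "MISSING_RECOMMENDED_FIELD", Severity.WARNING, f.relpath,
                f"recommended metadata field {key!r} is not defined at any level",
            ))
    return issues


def check_tables(f: BidsFile, t: Table, rules: RuleSet) -> list[Issue]:
    """Compulsory-column and numeric-cell checks for one TSV table."""
    issues: list[Issue] = []
    suffix = f.entity_set.suffix if f.entity_set else ""
    code = ("PARTICIPANTS_MISSING_REQUIRED_COLUMN" if suffix == "participants"
            else "EVENTS_MISSING_REQUIRED_COLUMN")
    for col in rules.required_columns.get(suffix, []):
        if col not in t.columns:
            issues.append(new_issue(
                code, Severity.ERROR, f.relpath,
                f"compulsory column {col!r} is missing",
            ))
    for col in rules.numeric_columns.get(suffix, []):
        if col not in t.columns:
            continue
        for i, cell in enumerate(t.column(col)):
            try:
                value = _numeric_cell(cell)
            except ValueError:
                issues.append(new_issue(
                    "INVALID_NUMERIC_CELL", Severity.ERROR, f.relpath,
                    f"column {col!r} row {i + 1}: {cell!r} is not a number",
                ))
                continue
            if value is not None and value < 0:
                issues.append(new_issue(
                    "INVALID_NUMERIC_CELL", Severity.ERROR, f.relpath,
                    f"column {col!r} row {i + 1}: {value} is negative",
                ))
    return issues


def _group_key(f: BidsFile) -> tuple[str, str, Optional[str]]:
    es = f.entity_set
    return (f.datatype, es.suffix, es.get("task"))


def heuristic_checks(
    model: DatasetModel,
    rules: RuleSet,
    resolved_cache: Optional[Mapping[str, MetadataMap]] = None,
) -> list[Issue]:
    """The heuristic WARNING battery over a fully indexed dataset."""
    issues: list[Issue] = []
    if resolved_cache is None:
        resolved_cache = {
            f.relpath: resolve_metadata(f, model) for f in _data_files(model)
        }

    # miscoded missing values in any TSV table
    na_tokens = set(rules.na_heuristic_tokens)
    for relpath, f in sorted(model.files.items()):
        if f.entity_set is None or f.entity_set.extension not in (".tsv", ".tsv.gz"):
            continue
        try:
            t = read_tsv((model.root / relpath).read_bytes())
        except (TsvError, OSError, UnicodeDecodeError):
            continue  # surfaced elsewhere as INVALID_SIDECAR
        for ri, row in enumerate(t.rows):
            for ci, cell in enumerate(row):
                if isinstance(cell, str) and cell in na_tokens:
                    issues.append(new_issue(
                        "NA_NOT_LOWERCASE", Severity.WARNING, relpath,
                        f"cell {t.columns[ci]!r} row {ri + 1} is {cell!r}; "
                        "missing values must be coded as 'n/a'",
                    ))

    # suspicious units on resolved numeric fields
    for relpath, resolved in sorted(resolved_cache.items()):
        for key, (lo, hi) in rules.suspicious_units.items():
            value = resolved.get(key)
            if _is_number(value) and not (lo <= value <= hi):
                issues.append(new_issue(
                    "SUSPICIOUS_UNITS", Severity.WARNING, relpath,
                    f"{key} = {value} is outside the plausible range "
                    f"[{lo}, {hi}] — check the units",
                    evidence={key: value},
                ))

    # missing scans: a scan most subjects have but some lack
    imaging = [f for f in _data_files(model) if f.entity_set.extension in (".nii", ".nii.gz")]
    if len(model.subjects) > 1:
        groups: dict[tuple, set[str]] = {}
        for f in imaging:
            groups.setdefault(_group_key(f), set()).add(f.entity_set.entities["sub"])
        for key in sorted(groups, key=lambda k: (k[0], k[1], k[2] or "")):
            have = groups[key]
            frac = len(have) / len(model.subjects)
            absent = sorted(set(model.subjects) - have)
            if absent and frac > rules.missing_scan_threshold:
                datatype, suffix, task = key
                desc = f"{datatype}/{suffix}" + (f" (task {task})" if task else "")
                issues.append(new_issue(
                    "MISSING_SCAN", Severity.WARNING, ".",
                    f"{desc} present for {len(have)}/{len(model.subjects)} subjects "
                    f"but missing for: {', '.join('sub-' + s for s in absent)}",
                ))

    # inconsistent acquisition parameters across subjects for the same task
    by_group: dict[tuple, dict[str, dict]] = {}
    for f in imaging:
        resolved = resolved_cache.get(f.relpath)
        if resolved is None:
            continue
        sub = f.entity_set.entities.get("sub", "")
        for key in rules.consistency_fields:
            value = resolved.get(key)
            if value is None:
                continue
            if not (_is_number(value) or isinstance(value, list)):
                continue
            by_group.setdefault(_group_key(f), {}).setdefault(key, {})[sub] = value
    for gkey in sorted(by_group, key=lambda k: (k[0], k[1], k[2] or "")):
        for key in sorted(by_group[gkey]):
            per_sub = by_group[gkey][key]
            if len(per_sub) < 2:
                continue
            distinct = {json.dumps(v) for v in per_sub.values()}
            if len(distinct) > 1:
                datatype, suffix, task = gkey
                desc = f"{datatype}/{suffix}" + (f" (task {task})" if task else "")
                issues.append(new_issue(
                    "INCONSISTENT_PARAMETER", Severity.WARNING, ".",
                    f"{key} differs across subjects for {desc}: "
                    + ", ".join(f"sub-{s}={per_sub[s]}" for s in sorted(per_sub)),
                ))

    # files that do not fit the standard
    for relpath, reason in sorted(model.not_in_spec):
        if reason == "folder_mismatch":
            continue  # surfaced as SUBJECT_FOLDER_MISMATCH error elsewhere
        issues.append(new_issue(
            "NOT_IN_SPEC", Severity.WARNING, relpath,
            f"file does not fit the naming standard ({reason})",
        ))

    # NIfTI header vs resolved JSON conflicts
    for f in imaging:
        resolved = resolved_cache.get(f.relpath)
        try:
            hdr = read_nifti_header((model.root / f.relpath).read_bytes())
        except (NiftiError, OSError):
            continue  # unreadable image surfaced as INVALID_SIDECAR elsewhere
        if hdr.ndim >= 4 and hdr.n_volumes is not None and hdr.n_volumes < 1:
            issues.append(new_issue(
                "NIFTI_JSON_CONFLICT", Severity.WARNING, f.relpath,
                f"header reports {hdr.n_volumes} volumes; event/volume "
                "bookkeeping is impossible",
            ))
        header_tr = hdr.tr_seconds()
        json_tr = resolved.get("RepetitionTime") if resolved else None
        if header_tr is not None and _is_number(json_tr):
            if abs(header_tr - float(json_tr)) > rules.tr_conflict_tolerance_s:
                issues.append(new_issue(
                    "NIFTI_JSON_CONFLICT", Severity.WARNING, f.relpath,
                    f"header repetition interval {header_tr:.6g} s conflicts "
                    f"with sidecar RepetitionTime {json_tr} s",
                    evidence={"header_tr_s": header_tr, "json_tr_s": json_tr},
                ))
    return issues


def _data_files(model: DatasetModel) -> list[BidsFile]:
    """Imaging and continuous-recording data files subject to metadata rules."""
    out = []
    for relpath in sorted(model.files):
        f = model.files[relpath]
        es = f.entity_set
        if es is None or f.datatype not in ("anat", "func", "dwi", "fmap"):
            continue
        if es.extension in (".nii", ".nii.gz"):
            out.append(f)
        elif es.suffix in ("physio", "stim") and es.extension in (".tsv.gz", ".tsv"):
            out.append(f)
    return out


def validate_dataset(root: str | Path, rules: Optional[RuleSet] = None) -> list[Issue]:
    """Validate a dataset tree; returns Issues sorted by (path, code).

    An unreadable root raises :class:`DatasetError` (fatal, distinct from
    Issues).  ``derivatives/`` is exempt from all rules.
    """
    rules = rules or RuleSet.default()
    model = index_dataset(root)
    issues: list[Issue] = []

    if not model.subjects:
        issues.append(new_issue(
            "MISSING_SUBJECT", Severity.ERROR, ".",
            "a dataset needs at least one subject directory (sub-<label>)",
        ))

    for name in rules.required_root_files:
        if not (model.root / name).is_file():
            issues.append(new_issue(
                "MISSING_REQUIRED_FILE", Severity.ERROR, name,
                f"required dataset-level file {name!r} is missing",
            ))
    if (model.root / "dataset_description.json").is_file():
        if model.dataset_description is None:
            issues.append(new_issue(
                "INVALID_SIDECAR", Severity.ERROR, "dataset_description.json",
                "dataset_description.json could not be parsed",
            ))
        else:
            for key in rules.dataset_description_required_fields:
                if key not in model.dataset_description:
                    issues.append(new_issue(
                        "MISSING_REQUIRED_FIELD", Severity.ERROR,
                        "dataset_description.json",
                        f"required field {key!r} is missing",
                    ))

    for relpath, reason in model.not_in_spec:
        if reason == "folder_mismatch":
            issues.append(new_issue(
                "SUBJECT_FOLDER_MISMATCH", Severity.ERROR, relpath,
                "filename entities disagree with the enclosing subject/session folder",
            ))

    # resolve metadata once per data file
    resolved_cache: dict[str, MetadataMap] = {}
    for f in _data_files(model):
        try:
            resolved_cache[f.relpath] = resolve_metadata(f, model)
        except MetadataError as exc:
            issues.append(new_issue(
                "INVALID_SIDECAR", Severity.ERROR, f.relpath,
                f"a metadata sidecar for this file failed to parse: {exc}",
            ))
            continue
        issues.extend(check_required(f, resolved_cache[f.relpath], rules, model))
        issues.extend(check_recommended(f, resolved_cache[f.relpath], rules))

    # tables
    for relpath in sorted(model.files):
        f = model.files[relpath]
        es = f.entity_set
        if es is None or es.extension not in (".tsv", ".tsv.gz"):
            continue
        if es.suffix not in rules.required_columns and es.suffix not in rules.numeric_columns:
            continue
        try:
            t = read_tsv((model.root / relpath).read_bytes())
        except (TsvError, UnicodeDecodeError) as exc:
            issues.append(new_issue(
                "INVALID_SIDECAR", Severity.ERROR, relpath,
                f"table failed to parse: {exc}",
            ))
            continue
        issues.extend(check_tables(f, t, rules))

    # diffusion gradient sanity
    for f in _data_files(model):
        es = f.entity_set
        if es.suffix != "dwi" or es.extension not in (".nii", ".nii.gz"):
            continue
        bval = find_companion(f, model, extension=".bval")
        bvec = find_companion(f, model, extension=".bvec")
        if bval and bvec:
            try:
                gt = read_gradients(
                    (model.root / bval).read_bytes(), (model.root / bvec).read_bytes()
                )
            except GradientError as exc:
                issues.append(new_issue(
                    "INVALID_SIDECAR", Severity.ERROR, f.relpath,
                    f"gradient table failed to parse: {exc}",
                ))
            else:
                bad = gt.irregular_directions()
                if bad:
                    issues.append(new_issue(
                        "SUSPICIOUS_GRADIENT", Severity.WARNING, bvec,
                        f"gradient directions {bad} are neither unit-norm nor zero",
                    ))

    issues.extend(heuristic_checks(model, rules, resolved_cache))
    return sorted(issues, key=issue_sort_key)


def report_text(issues: list[Issue]) -> str:
    """Line-oriented human-readable report."""
    lines = [
        f"{i.severity.value:7s} {i.code:32s} {i.path}: {i.message}" for i in issues
    ]
    n_err = sum(1 for i in issues if i.severity is Severity.ERROR)
    n_warn = len(issues) - n_err
    lines.append(f"{n_err} errors, {n_warn} warnings")
    return "\n".join(lines)


def report_json(issues: list[Issue]) -> dict:
    """Machine-readable report with a summary block."""
    n_err = sum(1 for i in issues if i.severity is Severity.ERROR)
    return {
        "issues": [i.to_dict() for i in issues],
        "summary": {"errors": n_err, "warnings": len(issues) - n_err},
    }
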