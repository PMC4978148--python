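"""Core domain types shared by every bidslite module.

These are plain in-memory values: filename entity sets, metadata
dictionaries with provenance, tabular data with an explicit missing-value
marker, diffusion gradient tables, NIfTI-1 header summaries, validation
issues and the indexed dataset model.  No I/O happens here.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

__all__ = [
    "ENTITY_ORDER",
    "DATATYPES",
    "Severity",
    "ISSUE_CATALOGUE",
    "BidsError",
    "ContractViolation",
    "MISSING",
    "MissingValue",
    "EntitySet",
    "BidsFile",
    "MetadataMap",
    "Table",
    "GradientTable",
    "NiftiHeaderSummary",
    "Issue",
    "DatasetModel",
    "new_issue",
    "issue_sort_key",
]

#: Canonical entity order used when composing filenames.  The parser accepts
#: entities in any order; the composer always emits this order.
ENTITY_ORDER = ("sub", "ses", "task", "acq", "run")

#: Subject-level datatype folders recognized in BIDS 1.0.0 raw data.
DATATYPES = ("anat", "func", "dwi", "fmap")

_LABEL_RE = re.compile(r"^[A-Za-z0-9]+$")

#: Numeric metadata keys that must be finite numbers when present
#: (all carry units of seconds except SamplingFrequency, in Hz).
NUMERIC_METADATA_KEYS = (
    "RepetitionTime",
    "StartTime",
    "EchoTime",
    "EffectiveEchoSpacing",
    "SamplingFrequency",
)


class BidsError(Exception):
    """Base class for all structured bidslite errors."""


class ContractViolation(BidsError):
    """An API precondition was violated by the caller."""


class Severity(str, Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


#: The published issue catalogue.  Every issue code has a fixed severity:
#: required-class rules always emit ERROR, recommended and heuristic rules
#: always emit WARNING.
ISSUE_CATALOGUE: Mapping[str, Severity] = {
    # required-class (ERROR)
    "MISSING_SUBJECT": Severity.ERROR,
    "MISSING_REQUIRED_FILE": Severity.ERROR,
    "MISSING_REQUIRED_FIELD": Severity.ERROR,
    "EVENTS_MISSING_REQUIRED_COLUMN": Severity.ERROR,
    "PARTICIPANTS_MISSING_REQUIRED_COLUMN": Severity.ERROR,
    "INVALID_NUMERIC_CELL": Severity.ERROR,
    "SUBJECT_FOLDER_MISMATCH": Severity.ERROR,
    "INVALID_SIDECAR": Severity.ERROR,
    # recommended / heuristic (WARNING)
    "MISSING_RECOMMENDED_FIELD": Severity.WARNING,
    "NA_NOT_LOWERCASE": Severity.WARNING,
    "SUSPICIOUS_UNITS": Severity.WARNING,
    "MISSING_SCAN": Severity.WARNING,
    "INCONSISTENT_PARAMETER": Severity.WARNING,
    "NOT_IN_SPEC": Severity.WARNING,
    "NIFTI_JSON_CONFLICT": Severity.WARNING,
    "SUSPICIOUS_GRADIENT": Severity.WARNING,
    "AMBIGUOUS_SIDECAR": Severity.WARNING,
}


class MissingValue:
    """Singleton marker for a missing tabular cell.

    Distinct from the literal string ``"n/a"`` so that readers stay
    non-lossy: only an exact lowercase ``n/a`` cell maps to this marker,
    and it serializes back to ``n/a``.
    """

    _instance: Optional["MissingValue"] = None

    def __new__(cls) -> "MissingValue":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"

    def __reduce__(self):
        return (MissingValue, ())


MISSING = MissingValue()


@dataclass
class EntitySet:
    """Parsed key-value components of a BIDS filename.

    ``entities`` is an ordered mapping from entity key (``sub``, ``ses``,
    ``task``, ``acq``, ``run``) to its alphanumeric label; ``suffix`` is the
    final underscore-delimited token before the extension (``bold``,
    ``T1w``, ``events``, ...) and ``extension`` includes the leading dot
    (``.nii.gz`` counts as a single extension).
    """

    entities: dict[str, str]
    suffix: str
    extension: str

    def __post_init__(self) -> None:
        for key, label in self.entities.items():
            if key not in ENTITY_ORDER:
                raise ContractViolation(f"unknown entity key: {key!r}")
            if not label or not _LABEL_RE.match(label):
                raise ContractViolation(
                    f"entity label must be non-empty alphanumeric: {key}-{label!r}"
                )
        if not self.suffix:
            raise ContractViolation("suffix must be non-empty")
        if not self.extension:
            raise ContractViolation("extension must be non-empty")

    def get(self, key: str, default: Optional[str] = None) -> Optional[str]:
        return self.entities.get(key, default)

    def with_changes(
        self,
        *,
        drop: Sequence[str] = (),
        suffix: Optional[str] = None,
        extension: Optional[str] = None,
    ) -> "EntitySet":
        """Return a copy with some entities removed and/or suffix/extension swapped."""
        ents = {k: v for k, v in self.entities.items() if k not in drop}
        return EntitySet(
            entities=ents,
            suffix=self.suffix if suffix is None else suffix,
            extension=self.extension if extension is None else extension,
        )

    @staticmethod
    def run_matches(a: Optional[str], b: Optional[str]) -> bool:
        """Numeric comparison of run labels: run-1 matches run-01."""
        if a is None or b is None:
            return a == b
        if a.isdigit() and b.isdigit():
            return int(a) == int(b)
        return a == b


@dataclass
class BidsFile:
    """One indexed file of a dataset, identified by its entity set."""

    relpath: str
    entity_set: Optional[EntitySet]
    datatype: str  # anat | func | dwi | fmap | root-level | meta | derivatives
    size_bytes: int = 0

    def __post_init__(self) -> None:
        if ".." in self.relpath.split("/") or "\\" in self.relpath:
            raise ContractViolation(f"relpath must be normalized POSIX: {self.relpath!r}")
        if self.size_bytes < 0:
            raise ContractViolation("size_bytes must be non-negative")


#: Inheritance levels in hierarchical order, highest first.
LEVELS = ("dataset", "subject", "session", "acquisition")


@dataclass
class MetadataMap:
    """Key -> value acquisition metadata with per-key provenance level.

    Values may be numbers, strings, booleans, arrays or nested mappings;
    ``provenance`` records at which hierarchy level (dataset, subject,
    session, acquisition) each key's winning value was defined.
    """

    pairs: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.pairs:
            if key not in self.provenance:
                raise ContractViolation(f"provenance missing for key {key!r}")
        for key in NUMERIC_METADATA_KEYS:
            if key in self.pairs:
                v = self.pairs[key]
                if isinstance(v, bool) or not isinstance(v, (int, float)) or not math.isfinite(v):
                    raise ContractViolation(f"{key} must be a finite number, got {v!r}")

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, Any], level: str = "acquisition") -> "MetadataMap":
        if level not in LEVELS:
            raise ContractViolation(f"unknown provenance level {level!r}")
        return cls(pairs=dict(pairs), provenance={k: level for k in pairs})

    def get(self, key: str, default: Any = None) -> Any:
        return self.pairs.get(key, default)

    def __contains__(self, key: str) -> bool:
        return key in self.pairs

    def merged_with(self, lower: "MetadataMap") -> "MetadataMap":
        """Per-key merge where ``lower`` (a lower hierarchy level) overrides."""
        pairs = dict(self.pairs)
        prov = dict(self.provenance)
        pairs.update(lower.pairs)
        prov.update(lower.provenance)
        return MetadataMap(pairs=pairs, provenance=prov)


@dataclass
class Table:
    """An ordered-column table with an explicit missing-value marker.

    Cells are strings or :data:`MISSING`; the reader performs no type
    inference so the representation is lossless.
    """

    columns: list[str]
    rows: list[list[Any]]

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns) or any(not c for c in self.columns):
            raise ContractViolation("column names must be unique and non-empty")
        for i, row in enumerate(self.rows):
            if len(row) != len(self.columns):
                raise ContractViolation(
                    f"row {i} has {len(row)} cells, expected {len(self.columns)}"
                )

    def column(self, name: str) -> list[Any]:
        idx = self.columns.index(name)
        return [row[idx] for row in self.rows]


#: Tolerances for diffusion gradient direction norms: printed tables carry
#: about four significant digits, so a unit vector is accepted within 0.01.
BVEC_UNIT_TOL = 0.01
BVEC_ZERO_TOL = 1e-6


@dataclass
class GradientTable:
    """Diffusion b-values and gradient directions (3 x n)."""

    bvals: list[float]
    bvecs: list[list[float]]  # 3 rows x n columns

    def __post_init__(self) -> None:
        if len(self.bvecs) != 3:
            raise ContractViolation("bvecs must have exactly 3 rows")
        n = len(self.bvals)
        if any(len(row) != n for row in self.bvecs):
            raise ContractViolation("bvals length must equal number of bvec columns")

    @property
    def n(self) -> int:
        return len(self.bvals)

    def irregular_directions(self) -> list[int]:
        """Indices of columns whose norm is neither ~1 nor exactly 0."""
        bad = []
        for j in range(self.n):
            norm = math.sqrt(sum(self.bvecs[i][j] ** 2 for i in range(3)))
            if norm > BVEC_ZERO_TOL and abs(norm - 1.0) > BVEC_UNIT_TOL:
                bad.append(j)
        return bad


# NIfTI-1 xyzt_units temporal codes
NIFTI_UNITS_SEC = 8
NIFTI_UNITS_MSEC = 16
NIFTI_UNITS_USEC = 24


@dataclass
class NiftiHeaderSummary:
    """The handful of NIfTI-1 header fields the validator cross-checks."""

    ndim: int
    dim: tuple[int, ...]       # per-axis extents, dim[1:ndim+1]
    pixdim: tuple[float, ...]  # grid spacings; pixdim[4] is the volume TR
    time_unit_code: int
    datatype_code: int

    def __post_init__(self) -> None:
        if not 2 <= self.ndim <= 7:
            raise ContractViolation(f"ndim must be in [2, 7], got {self.ndim}")
        if any(d <= 0 for d in self.dim[: self.ndim]):
            raise ContractViolation(f"extents must be positive: {self.dim}")

    @property
    def n_volumes(self) -> Optional[int]:
        if self.ndim >= 4:
            return self.dim[3]
        return None

    def tr_seconds(self) -> Optional[float]:
        """Volume repetition interval converted to seconds per the unit code."""
        if self.ndim < 4 or len(self.pixdim) < 5:
            return None
        tr = float(self.pixdim[4])
        if self.time_unit_code == NIFTI_UNITS_MSEC:
            return tr / 1e3
        if self.time_unit_code == NIFTI_UNITS_USEC:
            return tr / 1e6
        return tr  # seconds, or unknown units taken as seconds


@dataclass(frozen=True)
class Issue:
    """One validation finding."""

    code: str
    severity: Severity
    path: str
    message: str
    evidence: Optional[tuple[tuple[str, Any], ...]] = None

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "code": self.code,
            "severity": self.severity.value,
            "path": self.path,
            "message": self.message,
        }
        if self.evidence is not None:
            d["evidence"] = dict(self.evidence)
        return d


def new_issue(
    code: str,
    severity: Severity | str,
    path: str,
    message: str,
    evidence: Optional[Mapping[str, Any]] = None,
) -> Issue:
    """Create an Issue, enforcing that the code is in the catalogue and the
    severity matches the catalogue's fixed severity for that code."""
    if code not in ISSUE_CATALOGUE:
        raise ContractViolation(f"unknown issue code {code!r}")
    sev = Severity(severity)
    if sev is not ISSUE_CATALOGUE[code]:
        raise ContractViolation(
            f"severity {sev.value} does not match catalogue severity "
            f"{ISSUE_CATALOGUE[code].value} for {code}"
        )
    ev = tuple(sorted(evidence.items())) if evidence else None
    return Issue(code=code, severity=sev, path=path, message=message, evidence=ev)


def issue_sort_key(issue: Issue) -> tuple[str, str, str]:
    """Total deterministic ordering of issues by (path, code, message)."""
    return (issue.path, issue.code, issue.message)


@dataclass
class DatasetModel:
    """Indexed view of a dataset tree.

    ``files`` maps POSIX relpath -> :class:`BidsFile` for every recognized
    file outside ``derivatives/``; ``not_in_spec`` lists paths that do not
    fit the naming standard together with the classifier's reason.
    """

    root: Path
    subjects: list[str] = field(default_factory=list)
    sessions: dict[str, list[str]] = field(default_factory=dict)
    files: dict[str, BidsFile] = field(default_factory=dict)
    not_in_spec: list[tuple[str, str]] = field(default_factory=list)
    derivative_paths: list[str] = field(default_factory=list)
    dataset_description: Optional[MetadataMap] = None
    participants: Optional[Table] = None

    def files_matching(
        self,
        *,
        entities: Optional[Mapping[str, str]] = None,
        suffix: Optional[str] = None,
        extension: Optional[str] = None,
        datatype: Optional[str] = None,
    ) -> list[BidsFile]:
        """Query indexed files by entity values, suffix, extension, datatype.

        Run labels compare numerically (run-1 matches run-01)."""
        out = []
        for relpath in sorted(self.files):
            f = self.files[relpath]
            if f.entity_set is None:
                continue
            if datatype is not None and f.datatype != datatype:
                continue
            if suffix is not None and f.entity_set.suffix != suffix:
                continue
            if extension is not None and f.entity_set.extension != extension:
                continue
            if entities:
                ok = True
                for k, v in entities.items():
                    have = f.entity_set.get(k)
                    if k == "run":
                        if not EntitySet.run_matches(have, v):
                            ok = False
                            break
                    elif have != v:
                        ok = False
                        break
                if not ok:
                    continue
            out.append(f)
        return out
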