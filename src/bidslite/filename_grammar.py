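"""Parsing, composing and classifying BIDS filenames.

A BIDS filename is a series of ``key-value`` entities separated by
underscores, a suffix token and a file extension, e.g.
``sub-01_task-stopsignal_bold.nii.gz``.  The parser accepts entities in any
order; the composer always emits the canonical order sub, ses, task, acq,
run.  ``classify_path`` maps any dataset-relative path to either a
:class:`~bidslite.core_model.BidsFile` or a :class:`NotInSpec` marker — it
is a total function and never raises.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

from .core_model import (
    DATATYPES,
    ENTITY_ORDER,
    BidsError,
    BidsFile,
    ContractViolation,
    EntitySet,
)

__all__ = [
    "KNOWN_EXTENSIONS",
    "DEFAULT_SUFFIXES",
    "DATATYPE_SUFFIXES",
    "FilenameParseError",
    "NotInSpec",
    "parse_filename",
    "compose_filename",
    "classify_path",
]

#: Recognized extensions, longest-match-first so ``.nii.gz`` and ``.tsv.gz``
#: parse as single extensions.
KNOWN_EXTENSIONS = (".nii.gz", ".tsv.gz", ".nii", ".json", ".tsv", ".bval", ".bvec")

#: Suffix vocabulary shipped by default; extensible via a RuleSet.
DEFAULT_SUFFIXES = frozenset(
    {"T1w", "T2w", "inplaneT2", "bold", "dwi", "events", "physio", "stim",
     "magnitude", "phasediff"}
)

#: Which suffixes live in which datatype folder, and with which extensions.
DATATYPE_SUFFIXES: Mapping[str, Mapping[str, tuple[str, ...]]] = {
    "anat": {
        "T1w": (".nii", ".nii.gz", ".json"),
        "T2w": (".nii", ".nii.gz", ".json"),
        "inplaneT2": (".nii", ".nii.gz", ".json"),
    },
    "func": {
        "bold": (".nii", ".nii.gz", ".json"),
        "events": (".tsv", ".json"),
        "physio": (".tsv.gz", ".tsv", ".json"),
        "stim": (".tsv.gz", ".tsv", ".json"),
    },
    "dwi": {
        "dwi": (".nii", ".nii.gz", ".json", ".bval", ".bvec"),
    },
    "fmap": {
        "magnitude": (".nii", ".nii.gz", ".json"),
        "phasediff": (".nii", ".nii.gz", ".json"),
    },
}

#: Extensions that mark inheritable metadata files when found above the
#: datatype folder (dataset root, subject or session folder).
_SIDECAR_EXTENSIONS = (".json", ".tsv", ".tsv.gz", ".bval", ".bvec")

_ROOT_LITERALS = {
    "dataset_description.json": ("dataset_description", ".json"),
    "participants.tsv": ("participants", ".tsv"),
    "participants.json": ("participants", ".json"),
}
_ROOT_DOCS = {"README", "CHANGES"}

_SUB_DIR_RE = re.compile(r"^sub-([A-Za-z0-9]+)$")
_SES_DIR_RE = re.compile(r"^ses-([A-Za-z0-9]+)$")
_TOKEN_RE = re.compile(r"^[A-Za-z0-9]+$")


class FilenameParseError(BidsError):
    """A filename does not follow the entity grammar.

    Carries the offending token in ``token``."""

    def __init__(self, message: str, token: str = ""):
        super().__init__(message)
        self.token = token


@dataclass(frozen=True)
class NotInSpec:
    """Marker for a path that does not fit the naming standard.

    ``reason`` distinguishes plain unknown files (surfaced as a WARNING)
    from folder/entity disagreements (surfaced as an ERROR)."""

    relpath: str
    reason: str


def _split_extension(name: str) -> tuple[str, str]:
    for ext in KNOWN_EXTENSIONS:
        if name.endswith(ext) and len(name) > len(ext):
            return name[: -len(ext)], ext
    raise FilenameParseError(f"no recognizable extension in {name!r}", token=name)


def parse_filename(name: str) -> EntitySet:
    """Parse a bare filename into an :class:`EntitySet`.

    Raises :class:`FilenameParseError` on missing suffix/extension,
    duplicate or unknown entity keys, or empty/invalid labels.
    """
    if "/" in name or "\\" in name:
        raise ContractViolation("parse_filename expects a bare filename")
    stem, ext = _split_extension(name)
    tokens = stem.split("_")
    suffix = tokens[-1]
    if not suffix or "-" in suffix:
        raise FilenameParseError(f"missing suffix token in {name!r}", token=suffix)
    if not _TOKEN_RE.match(suffix):
        raise FilenameParseError(f"invalid suffix {suffix!r}", token=suffix)
    entities: dict[str, str] = {}
    for tok in tokens[:-1]:
        key, sep, label = tok.partition("-")
        if not sep:
            raise FilenameParseError(f"token {tok!r} is not key-value", token=tok)
        if key not in ENTITY_ORDER:
            raise FilenameParseError(f"unknown entity key {key!r}", token=tok)
        if key in entities:
            raise FilenameParseError(f"duplicate entity key {key!r}", token=tok)
        if not label or not _TOKEN_RE.match(label):
            raise FilenameParseError(f"invalid label in token {tok!r}", token=tok)
        entities[key] = label
    return EntitySet(entities=entities, suffix=suffix, extension=ext)


def compose_filename(es: EntitySet) -> str:
    """Compose the canonical filename for an entity set.

    Entities are emitted in canonical order regardless of the order they
    were parsed in; ``parse_filename(compose_filename(es))`` reproduces
    ``es`` up to that canonicalization.
    """
    parts = [f"{k}-{es.entities[k]}" for k in ENTITY_ORDER if k in es.entities]
    parts.append(es.suffix)
    return "_".join(parts) + es.extension


def classify_path(
    relpath: str,
    *,
    suffixes: Optional[frozenset] = None,
    datatype_suffixes: Optional[Mapping[str, Mapping[str, Sequence[str]]]] = None,
) -> Union[BidsFile, NotInSpec]:
    """Classify a dataset-relative POSIX path.  Total: never raises.

    Recognized root-level names, inheritable sidecars at dataset/subject/
    session level, and subject-tree files whose folder, entities and suffix
    agree become :class:`BidsFile`; everything else becomes
    :class:`NotInSpec`.  Files under ``derivatives/`` are indexed with
    datatype ``derivatives`` and exempt from all rules.
    """
    suffixes = suffixes if suffixes is not None else DEFAULT_SUFFIXES
    dt_map = datatype_suffixes if datatype_suffixes is not None else DATATYPE_SUFFIXES
    relpath = relpath.replace("\\", "/").lstrip("/")
    parts = relpath.split("/")
    if any(p in ("", ".", "..") for p in parts):
        return NotInSpec(relpath, "path is not normalized")

    if parts[0] == "derivatives":
        return BidsFile(relpath=relpath, entity_set=None, datatype="derivatives")

    if len(parts) == 1:
        name = parts[0]
        if name in _ROOT_LITERALS:
            suffix, ext = _ROOT_LITERALS[name]
            es = EntitySet(entities={}, suffix=suffix, extension=ext)
            return BidsFile(relpath=relpath, entity_set=es, datatype="root-level")
        if name in _ROOT_DOCS:
            return BidsFile(relpath=relpath, entity_set=None, datatype="root-level")
        try:
            es = parse_filename(name)
        except FilenameParseError:
            return NotInSpec(relpath, "unparseable filename")
        if "sub" in es.entities or "ses" in es.entities:
            return NotInSpec(relpath, "subject-specific file at dataset root")
        if es.suffix not in suffixes or es.extension not in _SIDECAR_EXTENSIONS:
            return NotInSpec(relpath, "unknown root-level file")
        return BidsFile(relpath=relpath, entity_set=es, datatype="root-level")

    m_sub = _SUB_DIR_RE.match(parts[0])
    if not m_sub:
        return NotInSpec(relpath, "not inside a subject folder")
    sub_label = m_sub.group(1)

    ses_label: Optional[str] = None
    rest = parts[1:]
    if rest and _SES_DIR_RE.match(rest[0]):
        ses_label = _SES_DIR_RE.match(rest[0]).group(1)  # type: ignore[union-attr]
        rest = rest[1:]

    if not rest:
        return NotInSpec(relpath, "missing filename")

    if len(rest) == 1:
        # subject- or session-level inheritable sidecar
        try:
            es = parse_filename(rest[0])
        except FilenameParseError:
            return NotInSpec(relpath, "unparseable filename")
        if es.extension not in _SIDECAR_EXTENSIONS or es.suffix not in suffixes:
            return NotInSpec(relpath, "unknown file in subject folder")
        if es.get("sub") != sub_label:
            return NotInSpec(relpath, "folder_mismatch")
        if es.get("ses") != ses_label:
            return NotInSpec(relpath, "folder_mismatch")
        return BidsFile(relpath=relpath, entity_set=es, datatype="meta")

    if len(rest) != 2:
        return NotInSpec(relpath, "folder nesting too deep")
    datatype, name = rest
    if datatype not in dt_map:
        return NotInSpec(relpath, f"unknown datatype folder {datatype!r}")
    try:
        es = parse_filename(name)
    except FilenameParseError:
        return NotInSpec(relpath, "unparseable filename")
    if es.get("sub") != sub_label or es.get("ses") != ses_label:
        return NotInSpec(relpath, "folder_mismatch")
    allowed = dt_map[datatype].get(es.suffix)
    if allowed is None:
        return NotInSpec(relpath, f"suffix {es.suffix!r} not allowed in {datatype}/")
    if es.extension not in allowed:
        return NotInSpec(
            relpath, f"extension {es.extension!r} not allowed for {es.suffix}"
        )
    return BidsFile(relpath=relpath, entity_set=es, datatype=datatype)
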