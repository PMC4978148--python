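"""Metadata inheritance: resolve the effective metadata for a file.

Any metadata file (JSON sidecar, events TSV, physio/stim recording,
.bval/.bvec) may be defined at one of four levels, in hierarchical order:
dataset, subject, session, or MRI acquisition.  Values defined at a higher
level are inherited by all matching files below unless a file at a lower
level overrides them.  The merge is per-key: a lower-level sidecar
overrides only the keys it defines, so a dataset-level ``task-x_bold.json``
can carry TaskName for everyone while a subject-level sidecar corrects
just that subject's RepetitionTime.
"""
from __future__ import annotations

import posixpath
from typing import Optional

from .core_model import BidsFile, DatasetModel, MetadataMap
from .filename_grammar import compose_filename

__all__ = ["candidate_paths", "resolve_metadata", "find_companion"]


def _sidecar_name(f: BidsFile, drop: tuple[str, ...], suffix: Optional[str],
                  extension: str) -> str:
    es = f.entity_set.with_changes(drop=drop, suffix=suffix, extension=extension)
    return compose_filename(es)


def candidate_paths(
    f: BidsFile,
    model: Optional[DatasetModel] = None,
    *,
    suffix: Optional[str] = None,
    extension: str = ".json",
) -> list[tuple[str, str]]:
    """Enumerate (level, relpath) sidecar candidates for ``f``.

    Ordered dataset -> subject -> session -> acquisition (the merge order:
    later candidates override earlier ones key-wise).  Each level's
    candidate keeps the file's entities minus those implied by the level:
    the dataset-level name drops sub and ses, the subject-level name drops
    ses, session- and acquisition-level names keep everything.  ``suffix``
    and ``extension`` select the sidecar kind (``.json`` metadata by
    default; e.g. ``suffix="events", extension=".tsv"`` for event tables,
    ``extension=".bval"`` for b-values).

    The session level is vacuous when the file has no ses entity, so a
    sessionless dataset yields three candidates.
    """
    es = f.entity_set
    if es is None or "sub" not in es.entities:
        return []
    sub = es.entities["sub"]
    ses = es.entities.get("ses")

    out: list[tuple[str, str]] = []
    out.append(("dataset", _sidecar_name(f, ("sub", "ses"), suffix, extension)))
    out.append(("subject", f"sub-{sub}/" + _sidecar_name(f, ("ses",), suffix, extension)))
    if ses is not None:
        out.append(
            ("session", f"sub-{sub}/ses-{ses}/" + _sidecar_name(f, (), suffix, extension))
        )
    parent = posixpath.dirname(f.relpath)
    acq = _sidecar_name(f, (), suffix, extension)
    out.append(("acquisition", f"{parent}/{acq}" if parent else acq))
    return out


def resolve_metadata(f: BidsFile, model: DatasetModel) -> MetadataMap:
    """Resolve the effective :class:`MetadataMap` for an imaging or
    continuous-recording file by merging JSON sidecars across levels.

    Keys are merged from the dataset level downward; a key defined at a
    lower level replaces the higher-level value, and each key's provenance
    records the winning level.  A candidate that exists but fails to parse
    aborts resolution with that parse error.
    """
    from .sidecar_io import read_metadata_json  # local import to avoid cycle

    resolved = MetadataMap()
    for level, relpath in candidate_paths(f, model):
        path = model.root / relpath
        if not path.is_file():
            continue
        layer = read_metadata_json(path.read_bytes(), level=level)
        resolved = resolved.merged_with(layer)
    return resolved


def find_companion(
    f: BidsFile,
    model: DatasetModel,
    *,
    suffix: Optional[str] = None,
    extension: str,
) -> Optional[str]:
    """Return the most specific existing companion file path, or None.

    Companion files (.bval/.bvec, _events.tsv) follow the same four-level
    rule but replace whole files rather than merging keys, so only the
    lowest-level existing candidate matters.
    """
    found = None
    for _level, relpath in candidate_paths(f, model, suffix=suffix, extension=extension):
        if (model.root / relpath).is_file():
            found = relpath
    return found
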