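"""Walk a dataset tree on disk and build the in-memory DatasetModel."""
from __future__ import annotations

import os
import re
from pathlib import Path

from .core_model import BidsError, BidsFile, DatasetModel
from .filename_grammar import NotInSpec, classify_path
from .sidecar_io import MetadataError, read_metadata_json
from .tabular_io import TsvError, read_tsv

__all__ = ["DatasetError", "index_dataset"]

_SUB_DIR_RE = re.compile(r"^sub-([A-Za-z0-9]+)$")
_SES_DIR_RE = re.compile(r"^ses-([A-Za-z0-9]+)$")


class DatasetError(BidsError):
    """Fatal problem with the dataset root, distinct from validation Issues."""


def index_dataset(root: str | os.PathLike) -> DatasetModel:
    """Index every file under ``root`` into a :class:`DatasetModel`.

    Deterministic and idempotent: the walk order is sorted, so indexing
    the same tree twice yields identical models.  Files under
    ``derivatives/`` are recorded but kept out of the main index.
    """
    root = Path(root)
    if not root.exists():
        raise DatasetError(f"dataset root does not exist: {root}")
    if not root.is_dir():
        raise DatasetError(f"dataset root is not a directory: {root}")

    model = DatasetModel(root=root)
    for dirpath, dirnames, filenames in os.walk(root):
        dirnames.sort()
        rel_dir = Path(dirpath).relative_to(root).as_posix()
        for name in sorted(filenames):
            relpath = name if rel_dir == "." else f"{rel_dir}/{name}"
            cls = classify_path(relpath)
            if isinstance(cls, NotInSpec):
                model.not_in_spec.append((cls.relpath, cls.reason))
                continue
            if cls.datatype == "derivatives":
                model.derivative_paths.append(relpath)
                continue
            try:
                cls.size_bytes = (root / relpath).stat().st_size
            except OSError:
                cls.size_bytes = 0
            model.files[relpath] = cls

    for entry in sorted(p.name for p in root.iterdir() if p.is_dir()):
        m = _SUB_DIR_RE.match(entry)
        if not m:
            continue
        label = m.group(1)
        model.subjects.append(label)
        sessions = []
        for sub_entry in sorted(p.name for p in (root / entry).iterdir() if p.is_dir()):
            sm = _SES_DIR_RE.match(sub_entry)
            if sm:
                sessions.append(sm.group(1))
        model.sessions[label] = sessions

    dd = root / "dataset_description.json"
    if dd.is_file():
        try:
            model.dataset_description = read_metadata_json(dd.read_bytes(), level="dataset")
        except (MetadataError, BidsError):
            model.dataset_description = None
    pt = root / "participants.tsv"
    if pt.is_file():
        try:
            model.participants = read_tsv(pt.read_bytes())
        except (TsvError, BidsError):
            model.participants = None
    return model
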