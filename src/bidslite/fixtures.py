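"""Deterministic synthetic dataset generation and defect injection.

``generate_dataset`` writes a complete, valid dataset tree — tiny NIfTI-1
volumes, JSON sidecars, event/participant tables, diffusion gradients and
physiological recordings — that validates with zero issues.  Given the
same :class:`FixtureSpec` (including its seed) the output is byte-identical
across runs: randomness is confined to voxel values and event onsets, all
names and metadata are functions of the spec, and gzip streams are written
with a zeroed timestamp.

``inject_defect`` applies exactly one minimal, labeled violation to a
generated tree; the defect -> issue-code map is the oracle used to test
the validator's heuristics.

The NIfTI writer is native (struct-level) rather than delegated to an
imaging library, so the package's header reader can be cross-validated
against an independent implementation.
"""
from __future__ import annotations

import gzip
import io
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core_model import MISSING, BidsError, DatasetModel, EntitySet, Table
from .dataset import index_dataset
from .filename_grammar import compose_filename
from .tabular_io import write_tsv

__all__ = [
    "TaskSpec",
    "FixtureSpec",
    "DefectSpec",
    "DEFECT_KINDS",
    "FixtureError",
    "DefectError",
    "generate_dataset",
    "inject_defect",
    "ds000009_template",
    "write_nifti",
    "random_entity_set",
    "random_table",
]


class FixtureError(BidsError):
    pass


class DefectError(BidsError):
    pass


@dataclass(frozen=True)
class TaskSpec:
    """One functional task: name, number of runs, TR (s), volumes per run."""

    name: str
    n_runs: int = 1
    tr: float = 2.0
    n_volumes: int = 5


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic dataset.

    Defaults describe a small three-subject, single-task study; the
    ds000009-style layout used in worked examples is available via
    :func:`ds000009_template`.
    """

    n_subjects: int = 3
    sessions: tuple[str, ...] = ()
    tasks: tuple[TaskSpec, ...] = (TaskSpec("stopsignal", 1, 2.0, 5),)
    include_anat: bool = True
    include_inplane_t2: bool = False
    include_dwi: bool = False
    include_physio: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise FixtureError("n_subjects must be >= 1")
        self.tasks = tuple(
            t if isinstance(t, TaskSpec) else TaskSpec(*t) for t in self.tasks
        )
        self.sessions = tuple(self.sessions)
        for t in self.tasks:
            if t.tr <= 0 or t.n_volumes < 1 or t.n_runs < 1:
                raise FixtureError(f"invalid task spec {t}")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureSpec":
        with open(path, "rb") as fh:
            data = json.load(fh)
        if "tasks" in data:
            data["tasks"] = tuple(TaskSpec(**t) for t in data["tasks"])
        if "sessions" in data:
            data["sessions"] = tuple(data["sessions"])
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})

    def subject_labels(self) -> list[str]:
        width = max(2, len(str(self.n_subjects)))
        return [str(i + 1).zfill(width) for i in range(self.n_subjects)]


#: Defect kinds and the minimal edit each performs.
DEFECT_KINDS = (
    "drop_required_field",   # remove one required key from a bold sidecar
    "drop_required_file",    # delete dataset_description.json
    "na_uppercase",          # write 'NA' into an events trial_type cell
    "tr_milliseconds",       # multiply one sidecar's RepetitionTime by 1000
    "remove_scan",           # delete one subject's bold image
    "inconsistent_tr",       # shift one sidecar's RepetitionTime by +0.5 s
    "add_unknown_file",      # drop an out-of-standard file into a subject folder
    "nifti_json_mismatch",   # rewrite one image header's repetition interval
)


@dataclass
class DefectSpec:
    """One deliberately injected violation, aimed at a single target."""

    kind: str
    subject: str = "01"
    task: Optional[str] = None
    run: Optional[str] = None
    fld: str = "TaskName"

    def __post_init__(self) -> None:
        if self.kind not in DEFECT_KINDS:
            raise DefectError(f"unknown defect kind {self.kind!r}")


# ---------------------------------------------------------------------------
# native NIfTI-1 writer

_NIFTI_DT_INT16 = 4


def _pack_header(dim: Sequence[int], pixdim: Sequence[float], order: str) -> bytes:
    """Pack a 348-byte NIfTI-1 header (int16 data, mm + s units)."""
    hdr = bytearray(348)
    struct.pack_into(order + "i", hdr, 0, 348)          # sizeof_hdr
    hdr[38] = ord("r")                                   # regular
    struct.pack_into(order + "8h", hdr, 40, *dim)        # dim
    struct.pack_into(order + "h", hdr, 70, _NIFTI_DT_INT16)
    struct.pack_into(order + "h", hdr, 72, 16)           # bitpix
    struct.pack_into(order + "8f", hdr, 76, *pixdim)
    struct.pack_into(order + "f", hdr, 108, 352.0)       # vox_offset
    struct.pack_into(order + "f", hdr, 112, 1.0)         # scl_slope
    hdr[123] = 2 | 8                                     # xyzt_units: mm + s
    desc = b"bidslite synthetic fixture"
    hdr[148:148 + len(desc)] = desc
    hdr[344:348] = b"n+1\x00"
    return bytes(hdr)


def write_nifti(
    path: Path,
    data: np.ndarray,
    tr: float = 0.0,
    *,
    byte_order: str = "<",
) -> None:
    """Write a single-file NIfTI-1 image (int16, mm/s units).

    ``data`` is 3-D or 4-D; ``tr`` fills pixdim[4] for 4-D images.  Output
    is gzip-compressed iff the path ends in .gz, with a zeroed gzip
    timestamp so identical inputs yield identical bytes.  ``byte_order``
    selects little- or big-endian encoding ('<' or '>').
    """
    ndim = data.ndim
    dim = [ndim] + list(data.shape) + [1] * (7 - ndim)
    pixdim = [1.0, 1.0, 1.0, 1.0, tr if ndim >= 4 else 0.0, 0.0, 0.0, 0.0]
    payload = (
        _pack_header(dim, pixdim, byte_order)
        + b"\x00\x00\x00\x00"  # no extensions
        + np.asarray(data, dtype=byte_order + "i2").tobytes(order="F")
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith(".gz"):
        payload = gzip.compress(payload, mtime=0)
    path.write_bytes(payload)


# ---------------------------------------------------------------------------
# generation

def _dump_json(path: Path, pairs: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(pairs, indent=2, sort_keys=True) + "\n")


def _events_table(rng: np.random.Generator, tr: float, n_volumes: int) -> Table:
    duration = 0.5
    span = max(tr * n_volumes - duration, duration)
    n_events = max(2, n_volumes // 2)
    onsets = np.sort(rng.uniform(0.0, span, size=n_events))
    rows = [
        [f"{onset:.3f}", f"{duration:.3f}", ("go" if i % 2 == 0 else "stop")]
        for i, onset in enumerate(onsets)
    ]
    return Table(columns=["onset", "duration", "trial_type"], rows=rows)


def _bold_sidecar(task: TaskSpec, n_slices: int) -> dict:
    return {
        "TaskName": task.name,
        "RepetitionTime": task.tr,
        "SliceTiming": [round(i * task.tr / n_slices, 6) for i in range(n_slices)],
        "PhaseEncodingDirection": "j-",
        "EffectiveEchoSpacing": 0.00051,
        "EchoTime": 0.03,
        "Manufacturer": "Synthetic",
    }


def generate_dataset(spec: FixtureSpec, dest: str | Path) -> DatasetModel:
    """Write a complete valid dataset under ``dest`` and return its index.

    ``dest`` must be empty or absent.  The tree validates with zero issues
    and is byte-identical across runs for equal (spec, seed).
    """
    dest = Path(dest)
    if dest.exists() and any(dest.iterdir()):
        raise FixtureError(f"destination is not empty: {dest}")
    dest.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    _dump_json(dest / "dataset_description.json", {
        "Name": f"bidslite synthetic dataset (seed={spec.seed})",
        "BIDSVersion": "1.0.0",
        "Authors": ["bidslite fixture generator"],
    })

    subjects = spec.subject_labels()
    participants = Table(
        columns=["participant_id", "age", "sex"],
        rows=[[f"sub-{s}", str(20 + i), ("F" if i % 2 == 0 else "M")]
              for i, s in enumerate(subjects)],
    )
    (dest / "participants.tsv").write_bytes(write_tsv(participants))

    sessions: tuple[Optional[str], ...] = spec.sessions or (None,)
    for sub in subjects:
        for ses in sessions:
            base = {"sub": sub, **({"ses": ses} if ses else {})}
            subdir = dest / f"sub-{sub}" / (f"ses-{ses}" if ses else "")

            if spec.include_anat:
                anat_suffixes = ["T1w"] + (
                    ["inplaneT2"] if spec.include_inplane_t2 else []
                )
                for suffix in anat_suffixes:
                    es = EntitySet(dict(base), suffix, ".nii.gz")
                    vol = rng.integers(0, 1000, size=(4, 4, 4))
                    write_nifti(subdir / "anat" / compose_filename(es), vol)
                    _dump_json(
                        subdir / "anat" / compose_filename(
                            es.with_changes(extension=".json")
                        ),
                        {"Manufacturer": "Synthetic"},
                    )

            if spec.include_dwi:
                es = EntitySet(dict(base), "dwi", ".nii.gz")
                n_dirs = 4
                vol = rng.integers(0, 1000, size=(2, 2, 2, n_dirs))
                write_nifti(subdir / "dwi" / compose_filename(es), vol)
                _dump_json(
                    subdir / "dwi" / compose_filename(es.with_changes(extension=".json")),
                    {"Manufacturer": "Synthetic"},
                )
                bvals = "0 1000 1000 1000\n"
                bvecs = ("0 1 0 0\n"
                         "0 0 1 0\n"
                         "0 0 0 1\n")
                (subdir / "dwi" / compose_filename(
                    es.with_changes(extension=".bval"))).write_text(bvals)
                (subdir / "dwi" / compose_filename(
                    es.with_changes(extension=".bvec"))).write_text(bvecs)

            for task in spec.tasks:
                runs: list[Optional[str]] = (
                    [None] if task.n_runs == 1
                    else [str(r + 1).zfill(2) for r in range(task.n_runs)]
                )
                for run in runs:
                    ents = dict(base)
                    ents["task"] = task.name
                    if run:
                        ents["run"] = run
                    es = EntitySet(ents, "bold", ".nii.gz")
                    vol = rng.integers(0, 1000, size=(2, 2, 2, task.n_volumes))
                    write_nifti(subdir / "func" / compose_filename(es), vol, tr=task.tr)
                    _dump_json(
                        subdir / "func" / compose_filename(
                            es.with_changes(extension=".json")
                        ),
                        _bold_sidecar(task, n_slices=2),
                    )
                    if not task.name.lower().startswith("rest"):
                        events = _events_table(rng, task.tr, task.n_volumes)
                        (subdir / "func" / compose_filename(
                            es.with_changes(suffix="events", extension=".tsv")
                        )).write_bytes(write_tsv(events))
                    if spec.include_physio:
                        phys_es = es.with_changes(suffix="physio", extension=".tsv.gz")
                        n_samp = 10
                        phys = Table(
                            columns=["cardiac", "respiratory"],
                            rows=[[f"{0.1 * i:.1f}", f"{0.05 * i:.2f}"]
                                  for i in range(n_samp)],
                        )
                        (subdir / "func" / compose_filename(phys_es)).write_bytes(
                            write_tsv(phys, gz=True)
                        )
                        _dump_json(
                            subdir / "func" / compose_filename(
                                phys_es.with_changes(extension=".json")
                            ),
                            {"StartTime": 0.0, "SamplingFrequency": 100.0},
                        )

    return index_dataset(dest)


def ds000009_template(seed: int = 0) -> FixtureSpec:
    """Layout template mirroring the worked example: 29 subjects, tasks
    stopsignal/bart/discounting/emotionregulation, T1w + inplaneT2
    anatomy and one diffusion run per subject.  Only the naming scheme is
    reproduced; image content is synthetic and desk-scale."""
    return FixtureSpec(
        n_subjects=29,
        tasks=(
            TaskSpec("stopsignal", 1, 2.0, 5),
            TaskSpec("bart", 1, 2.0, 5),
            TaskSpec("discounting", 1, 2.0, 5),
            TaskSpec("emotionregulation", 1, 2.0, 5),
        ),
        include_anat=True,
        include_inplane_t2=True,
        include_dwi=True,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# defect injection

def _bold_stem(root: Path, d: DefectSpec, extension: str, suffix: str = "bold") -> Path:
    model = index_dataset(root)
    matches = model.files_matching(
        entities={k: v for k, v in
                  {"sub": d.subject, "task": d.task, "run": d.run}.items()
                  if v is not None},
        suffix=suffix,
        extension=extension,
    )
    if not matches:
        raise DefectError(
            f"no {suffix}{extension} target for subject {d.subject!r}, "
            f"task {d.task!r}, run {d.run!r}"
        )
    return root / matches[0].relpath


def _edit_sidecar(path: Path, edit) -> None:
    pairs = json.loads(path.read_text())
    edit(pairs)
    _dump_json(path, pairs)


def inject_defect(root: str | Path, d: DefectSpec) -> Path:
    """Apply the minimal edit for ``d`` to a generated tree.

    Returns the touched path; raises :class:`DefectError` when the target
    does not exist.
    """
    root = Path(root)
    if d.kind == "drop_required_file":
        target = root / "dataset_description.json"
        if not target.is_file():
            raise DefectError("dataset_description.json not found")
        target.unlink()
        return target

    if d.kind == "add_unknown_file":
        subdir = root / f"sub-{d.subject}"
        if not subdir.is_dir():
            raise DefectError(f"subject folder sub-{d.subject} not found")
        target = subdir / "eyetrack.edf"
        target.write_bytes(b"not a standard file\n")
        return target

    if d.kind == "drop_required_field":
        target = _bold_stem(root, d, ".json")
        def drop(pairs):
            if d.fld not in pairs:
                raise DefectError(f"field {d.fld!r} absent in {target}")
            del pairs[d.fld]
        _edit_sidecar(target, drop)
        return target

    if d.kind == "tr_milliseconds":
        target = _bold_stem(root, d, ".json")
        _edit_sidecar(target, lambda p: p.__setitem__(
            "RepetitionTime", p["RepetitionTime"] * 1000))
        return target

    if d.kind == "inconsistent_tr":
        target = _bold_stem(root, d, ".json")
        _edit_sidecar(target, lambda p: p.__setitem__(
            "RepetitionTime", p["RepetitionTime"] + 0.5))
        return target

    if d.kind == "remove_scan":
        target = _bold_stem(root, d, ".nii.gz")
        target.unlink()
        return target

    if d.kind == "na_uppercase":
        target = _bold_stem(root, d, ".tsv", suffix="events")
        from .tabular_io import read_tsv  # local import: io on demand
        t = read_tsv(target.read_bytes())
        col = t.columns.index("trial_type")
        if not t.rows:
            raise DefectError(f"events table {target} has no rows")
        t.rows[0][col] = "NA"
        target.write_bytes(write_tsv(t))
        return target

    if d.kind == "nifti_json_mismatch":
        target = _bold_stem(root, d, ".nii.gz")
        payload = gzip.decompress(target.read_bytes())
        (tr,) = struct.unpack_from("<f", payload, 76 + 4 * 4)
        mutated = bytearray(payload)
        struct.pack_into("<f", mutated, 76 + 4 * 4, tr + 0.5)
        target.write_bytes(gzip.compress(bytes(mutated), mtime=0))
        return target

    raise DefectError(f"unknown defect kind {d.kind!r}")  # pragma: no cover


#: Issue codes each defect adds when injected into the default
#: three-subject fixture (the test oracle).  Defects touching one
#: subject's TR also surface as cross-subject inconsistency and a
#: header/sidecar conflict, because the image header still carries the
#: original value.
DEFECT_ISSUE_ORACLE: dict[str, frozenset] = {
    "drop_required_field": frozenset({"MISSING_REQUIRED_FIELD"}),
    "drop_required_file": frozenset({"MISSING_REQUIRED_FILE"}),
    "na_uppercase": frozenset({"NA_NOT_LOWERCASE"}),
    "tr_milliseconds": frozenset(
        {"SUSPICIOUS_UNITS", "NIFTI_JSON_CONFLICT", "INCONSISTENT_PARAMETER"}
    ),
    "remove_scan": frozenset({"MISSING_SCAN"}),
    "inconsistent_tr": frozenset({"NIFTI_JSON_CONFLICT", "INCONSISTENT_PARAMETER"}),
    "add_unknown_file": frozenset({"NOT_IN_SPEC"}),
    "nifti_json_mismatch": frozenset({"NIFTI_JSON_CONFLICT"}),
}


# ---------------------------------------------------------------------------
# random instances for round-trip testing

_RAND_SUFFIXES = ("bold", "T1w", "dwi", "events", "physio", "stim", "inplaneT2")
_RAND_EXTENSIONS = (".nii.gz", ".nii", ".json", ".tsv", ".tsv.gz", ".bval", ".bvec")
_ALNUM = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


def random_entity_set(rng: np.random.Generator) -> EntitySet:
    """A random valid EntitySet in canonical entity order."""
    def label() -> str:
        n = int(rng.integers(1, 8))
        return "".join(_ALNUM[int(i)] for i in rng.integers(0, len(_ALNUM), n))

    entities: dict[str, str] = {}
    for key in ("sub", "ses", "task", "acq"):
        if rng.random() < (0.9 if key == "sub" else 0.4):
            entities[key] = label()
    if rng.random() < 0.4:
        entities["run"] = str(int(rng.integers(1, 100)))
    suffix = _RAND_SUFFIXES[int(rng.integers(0, len(_RAND_SUFFIXES)))]
    ext = _RAND_EXTENSIONS[int(rng.integers(0, len(_RAND_EXTENSIONS)))]
    return EntitySet(entities=entities, suffix=suffix, extension=ext)


def random_table(rng: np.random.Generator) -> Table:
    """A random Table exercising quoting, missing markers and odd cells."""
    n_cols = int(rng.integers(1, 5))
    n_rows = int(rng.integers(0, 6))
    columns = [f"col{i}" for i in range(n_cols)]
    charset = _ALNUM + "\t\" .-%/"

    def cell() -> object:
        r = rng.random()
        if r < 0.15:
            return MISSING
        n = int(rng.integers(0, 10))
        s = "".join(charset[int(i)] for i in rng.integers(0, len(charset), n))
        # literal 'n/a' reads back as the missing marker, so avoid emitting
        # it as a plain string in round-trip instances
        return s if s != "n/a" else "n|a"

    rows = [[cell() for _ in range(n_cols)] for _ in range(n_rows)]
    return Table(columns=columns, rows=rows)
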