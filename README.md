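# bidslite

A compact, dependency-light implementation of the Brain Imaging Data
Structure (BIDS 1.0.0) core for Python: parse and compose BIDS filenames,
read the standard's file formats, resolve metadata through the inheritance
principle, and validate whole dataset trees — plus a fully synthetic
fixture generator so everything is testable offline, with no real imaging
data required.

## Who this is for

Neuroimaging researchers and tool developers who need to check, index or
query MRI datasets organized under the BIDS convention: one folder per
subject (`sub-01/`, `sub-02/`, ...), datatype subfolders (`anat/`, `func/`,
`dwi/`, `fmap/`), filenames built from `key-value` entities plus a suffix
and extension (`sub-01_task-stopsignal_bold.nii.gz`), JSON sidecars for
acquisition metadata, TSV tables for events and participants, and
`.bval`/`.bvec` gradient tables for diffusion scans.

## What it implements

**Filename grammar.** `parse_filename` / `compose_filename` convert between
filenames and entity sets (`sub`, `ses`, `task`, `acq`, `run` + suffix +
extension); `classify_path` is a total function mapping any dataset-relative
path to a typed file record or an explicit "not in spec" marker.

**File formats.** The TSV dialect (header required, `n/a` as the missing
value, tab-containing cells escaped with double quotes), JSON key/value
sidecars (ASCII/UTF-8, duplicate keys rejected, key order irrelevant),
diffusion gradient tables, and a native reader for the 348-byte NIfTI-1
header (both endiannesses, gzipped or plain, no voxel data loaded).

**The inheritance principle.** Any metadata file may live at one of four
levels — dataset, subject, session, or MRI acquisition. Values from higher
levels are inherited below unless overridden lower down; `resolve_metadata`
performs the per-key merge and records which level won for each key.

**Validation.** `validate_dataset` applies three rule classes:

| class | examples | severity |
|---|---|---|
| required | TaskName + RepetitionTime for every functional run; events table unless the task is resting-state; `.bval`/`.bvec` for diffusion; `dataset_description.json`; `onset`/`duration` columns; at least one subject | ERROR |
| recommended | SliceTiming, PhaseEncodingDirection, EffectiveEchoSpacing, EchoTime | WARNING |
| heuristic | `NA` instead of `n/a`; a RepetitionTime of 2000 (milliseconds, not seconds); scans most subjects have but some lack; parameters inconsistent across subjects; files outside the standard; JSON/NIfTI-header conflicts | WARNING |

Rule tables are data (`bidslite/data/rules.json`), so vocabularies and
field lists can be extended without code changes. Validation is entirely
local: nothing is ever uploaded.

**Synthetic fixtures.** `generate_dataset(FixtureSpec(...), dest)` writes a
complete valid dataset — tiny NIfTI-1 volumes, sidecars, event tables,
gradients — byte-identical for a given seed. `inject_defect` applies one
labeled violation (8 kinds), giving a precise oracle for which issue codes
the validator must add.

## Worked example

```
$ bids-lite scaffold ds000009 demo --seed 3
wrote 582 files for 29 subjects under demo
$ bids-lite validate demo
0 errors, 0 warnings
```

The built-in template reproduces the 29-subject worked-example layout
(anatomical `T1w` + `inplaneT2`, a diffusion run, and four task-fMRI runs
per subject with their events tables). Now corrupt one sidecar — set
`RepetitionTime` to 2000 in `sub-01/func/sub-01_task-stopsignal_bold.json`
of a two-subject dataset — and validate again:

```
$ bids-lite validate demo2
WARNING INCONSISTENT_PARAMETER           .: RepetitionTime differs across subjects for func/bold (task stopsignal): sub-01=2000, sub-02=2.0
WARNING NIFTI_JSON_CONFLICT              sub-01/func/sub-01_task-stopsignal_bold.nii.gz: header repetition interval 2 s conflicts with sidecar RepetitionTime 2000 s
WARNING SUSPICIOUS_UNITS                 sub-01/func/sub-01_task-stopsignal_bold.nii.gz: RepetitionTime = 2000 is outside the plausible range [0.01, 100.0] — check the units
0 errors, 3 warnings
$ echo $?
0
```

One wrong number triggers three independent heuristics: the value is
implausible as seconds (a millisecond/second confusion), it no longer
matches the repetition interval recorded in the NIfTI header, and it now
differs from the other subject's value for the same task. Warnings do not
fail validation (exit 0); errors do (exit 1); fatal I/O problems exit 2.

The same surface is available as a library:

```python
from bidslite import FixtureSpec, generate_dataset, validate_dataset

model = generate_dataset(FixtureSpec(n_subjects=3, seed=0), "ds")
print(validate_dataset("ds"))   # -> []
```

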