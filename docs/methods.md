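# Methods

This note documents the model of a BIDS 1.0.0 dataset that bidslite
implements, the parameters and thresholds that matter, what the synthetic
generator does and does not emulate, and the design choices made where the
standard's prose left room.

## The dataset model

A dataset is a directory tree. Files are identified by an *entity set*:
an ordered mapping of entity keys (`sub`, `ses`, `task`, `acq`, `run`) to
alphanumeric labels, plus a suffix (`bold`, `T1w`, `dwi`, `events`,
`physio`, ...) and an extension, where `.nii.gz` and `.tsv.gz` count as
single extensions. The parser accepts entities in any order; the composer
always emits the canonical order `sub, ses, task, acq, run`. Whether
entity order in filenames is normative is not settled by the standard's
prose; we chose to normalize on output only, so any permutation parses
but everything we write is canonical. Labels are case-sensitive; run
labels are kept verbatim (`run-01` and `run-1` compose differently) but
compare numerically when matching queries, which keeps zero-padding a
cosmetic choice rather than a semantic one.

Path classification is total: every relative path maps either to a typed
file record (with its datatype folder: `anat`, `func`, `dwi`, `fmap`,
dataset-root files, or subject/session-level metadata) or to a
`NotInSpec` marker with a reason. Unknown files are surfaced as WARNINGs,
never errors, so datasets can carry extra material (e.g. eye-tracking
recordings) without failing validation. One exception is promoted to an
ERROR: a parseable filename whose `sub`/`ses` entities disagree with the
enclosing folder labels (`sub-01/func/sub-02_...`). The standard's
examples always agree but never state the rule; we treat disagreement as
an error because every downstream association (inheritance, scan
counting) would silently attach the file to the wrong subject.
`derivatives/` is recorded but exempt from all rules, since the standard
deliberately leaves derivative naming open.

## File formats

**TSV.** Header line mandatory; missing values are the exact lowercase
string `n/a`, which maps to a dedicated in-memory `MISSING` marker
distinct from any string. Matching is deliberately exact and
case-sensitive: `NA`, `N/A` and the empty string are ordinary cells,
because the validator's heuristic layer is specified to *flag* miscoded
missing values rather than silently absorb them, and a coercing reader
would destroy the evidence. Cells are quoted iff they contain a tab or a
double quote (internal quotes doubled, CSV-style); the standard only
specifies the tab case, and this is the minimal unambiguous extension.
Newlines inside quoted cells are rejected with a structured error rather
than guessed at. The reader is lossless, so read∘write is the identity
on tables (the only unrepresentable string cell is a literal `n/a`,
which by construction reads back as the missing marker). The dialect is
implemented directly rather than through a generic CSV library because
the error contract (reject embedded newlines, report the row number,
exact quoting rule) is part of the validator's specification.

**JSON sidecars.** ASCII/UTF-8 only (UTF-16/32 byte-order marks
rejected); duplicate keys are errors; key order carries no meaning;
unknown keys are preserved so converter-extracted extras are never lost.

**Gradient tables.** `.bval` is n whitespace-separated b-values, `.bvec`
three rows of n components. Direction norms are accepted as unit within
±0.01 or exactly zero within 1e-6 (a b=0 volume): printed gradient
tables typically carry ~4 significant digits, so 0.01 accepts rounding
while still catching un-normalized vectors. Norm violations warn
(heuristic class); structural problems (row count ≠ 3, length mismatch)
are parse errors.

**NIfTI-1.** Only the 348-byte header of single-file `.nii`/`.nii.gz` is
read — never voxel data, and `.hdr`/`.img` pairs are rejected.
Endianness is detected from the header-size field; the temporal unit
code is honored, so a header that stores the repetition interval in
milliseconds is converted to seconds before any comparison. The reader
and the fixture writer are independent code paths, and the test suite
additionally cross-checks both against nibabel.

## The inheritance principle

Metadata files may live at four levels, in hierarchical order: dataset
root, subject folder, session folder, acquisition (next to the image).
The candidate name at each level keeps the file's entities minus those
implied by the level: dataset-level drops `sub` and `ses`, subject-level
drops `ses`, session- and acquisition-level keep all. Resolution merges
candidates top-down **per key**: a lower file overrides only the keys it
defines, and each key's provenance records the winning level. The
standard's wording ("values ... are inherited ... unless they are
overridden") is genuinely ambiguous between per-key and whole-file
override; per-key is chosen because the standard's own motivating
example overrides only the repetition time at the subject level while
dataset-level values like the task name clearly remain in force. For
whole-file sidecars (`.bval`, `.bvec`, events tables) the same four-level
search applies but the most specific existing file replaces higher ones
outright — there is nothing meaningful to merge line-wise.

Consequences that the property tests pin down: resolution is
deterministic and independent of directory listing order; adding a
lower-level sidecar can never remove keys (the resolved set grows
monotonically down the hierarchy); with a single sidecar present,
resolution is the identity.

## Validation rules and thresholds

Severities are fixed per issue code: required-class rules always ERROR,
recommended and heuristic rules always WARNING. The catalogue is
enforced at construction time, so the partition is an invariant, not a
convention.

Heuristic thresholds (all configurable in `data/rules.json`):

- **Suspicious units.** RepetitionTime outside [0.01, 100] s; EchoTime
  outside (0, 1] s; StartTime outside ±1000 s; SamplingFrequency outside
  (0, 1e6] Hz. The 100 s cutoff cleanly separates any plausible TR
  expressed in seconds from the same TR expressed in milliseconds, the
  confusion this heuristic exists to catch.
- **Missing scans.** For each (datatype, suffix, task) combination
  present in more than 50% of subjects but absent in some, one WARNING
  names the missing subjects. Majority presence is the least surprising
  reading of "missing scans", and the threshold is a knob.
- **Inconsistent parameters.** Numeric scalar fields (and SliceTiming
  arrays, element-wise) from the required/recommended sets are compared
  across subjects per task with exact equality after unit normalization;
  any disagreement warns and lists the per-subject values.
- **Header/sidecar conflict.** The header's repetition interval
  (unit-normalized to seconds) must match the resolved RepetitionTime
  within 1e-3 s — loose enough for float32 storage of the header field,
  tight enough to catch any real discrepancy. A 4-D image reporting
  fewer than one volume also warns, since event/volume bookkeeping is
  then impossible.
- **Resting-state exemption.** A functional run whose TaskName begins
  with "rest" (case-insensitive) needs no events table.

Whether a missing events file for a non-rest task is an error or a
warning is not stated outright; since event timing is listed among the
*required* metadata for task fMRI, it is treated as an ERROR.

The fieldmap datatype is recognized structurally (`magnitude`,
`phasediff` in `fmap/`) but ships with no required-field set: the exact
per-fieldmap-type field lists live in the standard's full specification
document rather than its descriptor, so they are left as a data-file
extension slot rather than guessed.

## The synthetic generator

`generate_dataset` emulates the curation endpoint of a small MRI study:
per subject (and optionally per session) an anatomical `T1w` (optionally
`inplaneT2`), task-fMRI runs with complete sidecars (TaskName,
RepetitionTime, SliceTiming, PhaseEncodingDirection 'j-',
EffectiveEchoSpacing 0.51 ms, EchoTime 30 ms — typical 3T EPI values)
and events tables, optionally a 4-direction diffusion run with
unit-vector gradients and a physiological recording at 100 Hz. Defaults
are a 3-subject, single-task (`stopsignal`, TR 2 s, 5 volumes) study —
large enough to exercise cross-subject heuristics (2 of 3 subjects is
above the 50% missing-scan threshold), small enough that the full test
grid runs in seconds. The 29-subject/4-task template mirrors the
standard's worked-example layout; its image content is synthetic and
desk-scale (2×2×2 voxel grids, 5 volumes), because only the naming
scheme is being reproduced.

Randomness is confined to voxel values and event onsets; names and
metadata are pure functions of the spec, and gzip streams carry a zeroed
timestamp, so equal (spec, seed) pairs produce byte-identical trees.

What the generator does **not** emulate: realistic image content or
dimensions, scanner-specific metadata quirks, DICOM provenance,
multi-site heterogeneity, or malformed-but-plausible hand-edited files
beyond the eight defect kinds. Passing the generator grid therefore
shows the validator is *sound* on well-formed trees and *sensitive* to
each injected defect class in isolation; it does not show completeness
against the full variety of real-world curation mistakes.

Each defect kind maps to the exact set of issue codes it must add on the
default three-subject fixture. Defects that change one subject's
RepetitionTime sidecar value deliberately leave the image header
untouched, so they surface through up to three heuristics at once
(suspicious units, header conflict, cross-subject inconsistency) — that
coupling is physical, not incidental: the header still carries the
acquisition's true timing.

## Problem sizes

The shipped test grid uses 1 and 3 subjects, 0 and 2 sessions, and each
optional datatype toggled; round-trip identities run 1,000 seeded random
instances; the inheritance oracle enumerates all 256 assignments of two
keys to four levels; header agreement covers 3 shapes × 2 endiannesses ×
2 containers. These sizes fully exercise every code path and rule
interaction while keeping the whole suite in the seconds range.

## Known limitations

- BIDS 1.0.0 scope only: no post-1.0 entities (`echo`, `dir`, `ce`),
  no EEG/MEG/PET/ASL, no surface/CIFTI formats, no NIfTI-2.
- No DICOM conversion; the pipeline starts at NIfTI + sidecars.
- Derivative naming is not modeled (the folder is only exempted).
- The inheritance resolver generates exactly one candidate name per
  level; alternative same-level sidecars with coarser entity subsets are
  not searched.
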