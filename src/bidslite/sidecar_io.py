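"""Readers for sidecar metadata: JSON dictionaries, diffusion gradient
tables (.bval/.bvec) and the 348-byte NIfTI-1 header.

The NIfTI reader is deliberately self-contained (offset-based field
extraction, both endiannesses, optional gzip) so it can be cross-validated
against an independent NIfTI implementation; it reads no voxel data.
"""
from __future__ import annotations

import gzip
import json
import struct
from typing import Any, Mapping

from .core_model import (
    BidsError,
    GradientTable,
    MetadataMap,
    NiftiHeaderSummary,
)

__all__ = [
    "MetadataError",
    "GradientError",
    "NiftiError",
    "read_metadata_json",
    "serialize_metadata",
    "read_gradients",
    "read_nifti_header",
]


class MetadataError(BidsError):
    """JSON sidecar error; ``offset`` is the byte offset when known."""

    def __init__(self, message: str, offset: int = -1):
        super().__init__(message)
        self.offset = offset


class GradientError(BidsError):
    pass


class NiftiError(BidsError):
    pass


def _reject_duplicates(pairs: list[tuple[str, Any]]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in pairs:
        if k in out:
            raise MetadataError(f"duplicate key {k!r} in JSON sidecar")
        out[k] = v
    return out


def read_metadata_json(payload: bytes, level: str = "acquisition") -> MetadataMap:
    """Parse a JSON key/value sidecar into a :class:`MetadataMap`.

    The payload must be ASCII or UTF-8 (a UTF-16/32 byte-order mark is
    rejected); key order is ignored; duplicate keys are an error; unknown
    keys are preserved so converter-extracted extras are never lost.
    ``level`` tags every key's provenance (the inheritance resolver passes
    the hierarchy level the file was found at).
    """
    for bom in (b"\xff\xfe", b"\xfe\xff", b"\x00\x00\xfe\xff", b"\xff\xfe\x00\x00"):
        if payload.startswith(bom):
            raise MetadataError("JSON sidecars must be encoded in ASCII or UTF-8", 0)
    try:
        text = payload.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise MetadataError(f"not valid UTF-8: {exc.reason}", exc.start) from exc
    try:
        data = json.loads(text, object_pairs_hook=_reject_duplicates)
    except json.JSONDecodeError as exc:
        raise MetadataError(f"malformed JSON: {exc.msg}", exc.pos) from exc
    if not isinstance(data, dict):
        raise MetadataError("JSON sidecar must be a key/value object at top level")
    return MetadataMap.from_pairs(data, level=level)


def serialize_metadata(m: MetadataMap) -> bytes:
    """Deterministic JSON serialization; inverse of :func:`read_metadata_json`
    for JSON-representable values (provenance is not stored on disk)."""
    return (json.dumps(m.pairs, indent=2, sort_keys=True) + "\n").encode("utf-8")


def _parse_floats(text: str, what: str) -> list[float]:
    vals = []
    for tok in text.split():
        try:
            vals.append(float(tok))
        except ValueError:
            raise GradientError(f"non-numeric token {tok!r} in {what}") from None
    return vals


def read_gradients(bval_payload: bytes | str, bvec_payload: bytes | str) -> GradientTable:
    """Parse .bval/.bvec payloads into a matched :class:`GradientTable`.

    The .bval file holds n whitespace-separated b-values; the .bvec file
    holds three rows of n gradient components.  A row count other than 3
    or a length mismatch is a structured error.
    """
    if isinstance(bval_payload, bytes):
        bval_payload = bval_payload.decode("utf-8")
    if isinstance(bvec_payload, bytes):
        bvec_payload = bvec_payload.decode("utf-8")
    bvals = _parse_floats(bval_payload, ".bval")
    rows = [line for line in bvec_payload.splitlines() if line.strip()]
    if len(rows) != 3:
        raise GradientError(f".bvec must have exactly 3 rows, found {len(rows)}")
    bvecs = [_parse_floats(row, ".bvec") for row in rows]
    n = len(bvals)
    if any(len(r) != n for r in bvecs):
        raise GradientError(
            f"length mismatch: {n} b-values but bvec rows of lengths "
            f"{[len(r) for r in bvecs]}"
        )
    return GradientTable(bvals=bvals, bvecs=bvecs)


_HDR_SIZE = 348
_MAGICS = (b"n+1\x00", b"ni1\x00")


def read_nifti_header(payload: bytes, gz: bool = False) -> NiftiHeaderSummary:
    """Extract dim/pixdim/units/datatype from a NIfTI-1 header.

    Endianness is detected from the header-size field; gzip is detected
    from the payload magic when ``gz`` is not set.  Only single-file
    NIfTI-1 (.nii/.nii.gz, magic ``n+1``) and bare headers (``ni1``) are
    accepted; no voxel data is read.
    """
    if gz or payload[:2] == b"\x1f\x8b":
        try:
            payload = gzip.decompress(payload)
        except (OSError, EOFError) as exc:
            raise NiftiError(f"bad gzip container: {exc}") from exc
    if len(payload) < _HDR_SIZE:
        raise NiftiError(f"truncated header: {len(payload)} bytes < {_HDR_SIZE}")
    for order in ("<", ">"):
        (sizeof_hdr,) = struct.unpack_from(order + "i", payload, 0)
        if sizeof_hdr == _HDR_SIZE:
            break
    else:
        raise NiftiError("not a NIfTI-1 header (sizeof_hdr != 348 in either byte order)")
    magic = payload[344:348]
    if magic not in _MAGICS:
        raise NiftiError(f"bad NIfTI magic {magic!r}")
    dim = struct.unpack_from(order + "8h", payload, 40)
    (datatype_code,) = struct.unpack_from(order + "h", payload, 70)
    pixdim = struct.unpack_from(order + "8f", payload, 76)
    xyzt_units = payload[123]
    ndim = dim[0]
    if not 2 <= ndim <= 7:
        raise NiftiError(f"unsupported number of dimensions: {ndim}")
    return NiftiHeaderSummary(
        ndim=ndim,
        dim=tuple(dim[1 : 1 + ndim]),
        pixdim=tuple(float(p) for p in pixdim),
        time_unit_code=xyzt_units & 0x38,
        datatype_code=datatype_code,
    )
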