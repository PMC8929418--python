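"""Digest serialization: the canonical byte form of an identifiable object.

This is the serialization fed to the truncated digest that mints computed
identifiers.  It is deliberately *not* the display JSON form: nested
identifiable objects are collapsed to their digests, the ``_id`` slot and any
null-valued fields are removed, reference arrays are sorted, keys are ordered
by Unicode code point, and no insignificant whitespace is emitted.  Display
JSON (``obj.as_document()``) and digest serialization are not interchangeable
and yield different hashes by design.

Raw sequence strings serialize as their UTF-8 bytes, with no JSON wrapper.
"""

from __future__ import annotations

import json
from typing import Any, Union

from .models import IDENTIFIABLE_TYPES, _ValueObject

__all__ = ["digest_serialize", "replace_nested_identifiable", "SerializationError"]

# Fields whose values are references to identifiable objects (inline object,
# or a ga4gh CURIE).  Only these may hold CURIEs, and only arrays of these
# (members) are subject to the sort rule.
_REFERENCE_FIELDS = frozenset({"location", "subject", "sequence_id", "members"})


class SerializationError(ValueError):
    """Object cannot be digest-serialized (non-identifiable composite or
    reference outside the ga4gh namespace)."""


def _reduce_curie(curie: str) -> str:
    """Reduce a ga4gh CURIE reference to its bare digest."""
    if not curie.startswith("ga4gh:"):
        raise SerializationError(
            f"references must be identified in the ga4gh namespace, got {curie!r}"
        )
    reference = curie.split(":", 1)[1]
    # strip the type prefix ("SQ.", "VA.", ...) to leave the digest
    return reference.split(".", 1)[1] if "." in reference else reference


def _object_digest(obj: _ValueObject) -> str:
    from .identify import sha512t24u  # deferred: identify builds on this module

    return sha512t24u(digest_serialize(obj))


def _content(value: Any, *, in_reference: bool = False) -> Any:
    if isinstance(value, _ValueObject):
        if in_reference or type(value).__name__ in IDENTIFIABLE_TYPES:
            return _object_digest(value)
        return _object_content(value)
    if isinstance(value, (list, tuple)):
        return [_content(v, in_reference=in_reference) for v in value]
    if isinstance(value, str) and in_reference:
        return _reduce_curie(value)
    if isinstance(value, (str, bool, int)):
        return value
    raise SerializationError(f"cannot serialize value of type {type(value).__name__}")


def _object_content(obj: _ValueObject) -> dict:
    out: dict[str, Any] = {}
    for name, spec in type(obj).model_fields.items():
        key = spec.alias or name
        if key.startswith("_"):
            continue
        value = getattr(obj, name)
        if value is None:
            continue
        rendered = _content(value, in_reference=key in _REFERENCE_FIELDS)
        if isinstance(rendered, list) and key in _REFERENCE_FIELDS:
            # arrays of digests/ids are ordered by Unicode code point
            rendered = sorted(rendered)
        out[key] = rendered
    return out


def replace_nested_identifiable(obj: _ValueObject) -> dict:
    """Message content of an identifiable object: nested identifiable objects
    and ga4gh CURIE references collapsed to bare 32-character digests,
    underscore-prefixed and null fields dropped, reference arrays sorted."""
    if type(obj).__name__ not in IDENTIFIABLE_TYPES:
        raise SerializationError(
            f"{type(obj).__name__} objects are not identifiable"
        )
    return _object_content(obj)


def canonical_json(content: dict) -> bytes:
    """RFC 8259-constrained JSON: UTF-8, no insignificant whitespace, keys in
    code-point order, two-character escapes where the grammar provides them."""
    return json.dumps(
        content, sort_keys=True, separators=(",", ":"), ensure_ascii=False
    ).encode("utf-8")


def digest_serialize(obj: Union[_ValueObject, str]) -> bytes:
    """Canonical byte string of an identifiable object or a sequence string."""
    if isinstance(obj, str):
        return obj.encode("utf-8")
    return canonical_json(replace_nested_identifiable(obj))
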