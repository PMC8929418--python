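"""Machine-readable schema of the information model.

The schema is generated from the typed model itself (pydantic's JSON Schema
emission over every registered class) rather than hand-maintained, so the
validator and the schema cannot drift apart.  A small post-processing pass
adds the one constraint the type layer expresses only as a cross-field
check in a context where the schema dialect can still state it per-variant:
sequence interval endpoints given as plain Numbers must be non-negative.

``emit_schema`` is deterministic: the same model produces byte-identical
output under canonical dumping.
"""

from __future__ import annotations

import copy
import json
from typing import Any, Mapping, Optional

import jsonschema
from pydantic.json_schema import models_json_schema

from .models import TYPE_REGISTRY

__all__ = ["emit_schema", "schema_validate", "dump_schema"]

_DIALECT = "https://json-schema.org/draft/2020-12/schema"


def _nonnegative_number_def(number_def: dict) -> dict:
    refined = copy.deepcopy(number_def)
    refined["title"] = "SequenceCoordinate"
    refined["properties"]["value"]["minimum"] = 0
    return refined


def emit_schema() -> dict:
    """Deterministic JSON Schema document covering every released class."""
    _, defs_schema = models_json_schema(
        [(cls, "validation") for _, cls in sorted(TYPE_REGISTRY.items())],
        ref_template="#/$defs/{model}",
    )
    defs = dict(defs_schema["$defs"])

    # interval endpoints: a literal Number coordinate cannot be negative
    defs["SequenceCoordinate"] = _nonnegative_number_def(defs["Number"])
    coordinate_variants = {
        "anyOf": [
            {"$ref": "#/$defs/SequenceCoordinate"},
            {"$ref": "#/$defs/DefiniteRange"},
            {"$ref": "#/$defs/IndefiniteRange"},
        ]
    }
    interval = defs["SequenceInterval"]["properties"]
    interval["start"] = copy.deepcopy(coordinate_variants)
    interval["end"] = copy.deepcopy(coordinate_variants)

    return {
        "$schema": _DIALECT,
        "title": "vrskit information model",
        "$defs": defs,
        "anyOf": [
            {"$ref": f"#/$defs/{name}"} for name in sorted(TYPE_REGISTRY)
        ],
    }


def dump_schema(schema: Optional[dict] = None) -> bytes:
    """Canonical UTF-8 rendering of the schema document."""
    schema = emit_schema() if schema is None else schema
    return json.dumps(
        schema, sort_keys=True, indent=2, ensure_ascii=False
    ).encode("utf-8")


def schema_validate(
    document: Mapping[str, Any], schema: Optional[dict] = None
) -> list[str]:
    """Validate a document against the emitted schema.

    Returns a list of violation messages, empty when the document conforms.
    If the document names a known type, validation targets that definition
    so messages stay specific; otherwise the whole-model union applies.
    """
    schema = emit_schema() if schema is None else schema
    target: dict = schema
    type_name = document.get("type") if isinstance(document, Mapping) else None
    if isinstance(type_name, str) and type_name in schema["$defs"]:
        target = {
            "$schema": _DIALECT,
            "$defs": schema["$defs"],
            "$ref": f"#/$defs/{type_name}",
        }
    validator = jsonschema.Draft202012Validator(target)
    return [
        f"{'/'.join(str(p) for p in err.absolute_path) or '<root>'}: {err.message}"
        for err in validator.iter_errors(document)
    ]
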